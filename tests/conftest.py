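import numpy as np
import pytest

from gpsel.mixed_model import MixedModelSpec
from gpsel.sim_data import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_small():
    """Small end-to-end fixture: 200 individuals x 400 markers, 30 QTL."""
    cfg = SimConfig(n_individuals=200, n_markers_dense=400, n_markers_panel=120,
                    n_chromosomes=4, n_qtl=30, seed=11, n_cg=6, cg_sd=0.5)
    return simulate(cfg)


@pytest.fixture(scope="session")
def sim_medium():
    """Recovery-scale fixture: 800 individuals x 1500 markers."""
    cfg = SimConfig(n_individuals=800, n_markers_dense=1500, n_markers_panel=400,
                    n_chromosomes=5, n_qtl=80, seed=23, n_cg=10, cg_sd=0.8)
    return simulate(cfg)


@pytest.fixture(scope="session")
def base_spec():
    return MixedModelSpec(fixed_terms="C(cg_id) + dam_age + I(dam_age**2)")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
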