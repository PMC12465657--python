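# gpsel — genomic prediction with preselected sequence markers

`gpsel` is a desk-scale, fully tested implementation of a livestock
genomic-prediction workflow built around marker preselection: starting from a
dense ("whole-genome-sequence-like") SNP panel that contains a designated
medium-density array subset, it selects informative markers by LD pruning,
mixed-model GWAS thresholding, gene-set expansion, QTL-interval lookup, or
sequence-annotation class; fits GBLUP, two-GRM GBLUP, BayesR and BayesRC
models; and evaluates cross-validated prediction accuracy and dispersion
bias. Because real cattle genotype/phenotype panels of this kind are
proprietary, the package ships a first-class synthetic-data generator that
reproduces the statistical structure the analysis assumes (LD, mixture-
distributed QTL effects, contemporary groups, maternal effects, annotation
layers), so every stage is testable end to end.

It is aimed at quantitative geneticists and breeding-program analysts who
want a transparent, scriptable reference implementation of these methods.

## Models

**GBLUP / GREML.** The animal model

```
y = Xb + Z1 u1 [+ Z2 u2] [+ Zm m] + e,
u_k ~ N(0, G_k σ²_gk),   m ~ N(0, I σ²_m),   e ~ N(0, I σ²_e)
```

with `G = W W' / m` on centred, unit-variance genotypes. Variance components
are estimated by average-information REML with expectation–maximization
fallback; a one-component fit uses an exact spectral reformulation (one
eigendecomposition, O(n) per iteration). Two nested fits are compared by a
boundary likelihood-ratio test against the 50:50 χ²₀/χ²₁ mixture.

**BayesR / BayesRC.** Marker effects follow a four-component normal mixture
`N(0, 0)`, `N(0, 10⁻⁴σ²_g)`, `N(0, 10⁻³σ²_g)`, `N(0, 10⁻²σ²_g)` sampled by
single-site Gibbs; BayesRC gives each marker category its own Dirichlet
mixture proportions, so prior biology (e.g. "preselected" vs "array" markers)
can concentrate signal. Heritability is the posterior share of phenotypic
variance explained by all markers.

**Evaluation.** k-fold cross-validation with per-fold refitting;
`accuracy = cor(GEBV, y*) / sqrt(h²_ref)` against corrected phenotypes
`y* = y − X b̂` (training-estimated fixed effects), and dispersion bias as
the OLS slope of `y*` on GEBV (1 = unbiased).

## Worked example

```python
from gpsel import SimConfig, simulate, build_grm
from gpsel.mixed_model import MixedModelSpec, reml_fit
from gpsel.evaluate import cross_validate, reference_h2
from gpsel.ld_select import MarkerSet

cfg = SimConfig(n_individuals=900, n_markers_dense=2000, n_markers_panel=700,
                n_qtl=100, h2=0.35, n_founder_haplotypes=400, seed=54,
                n_cg=8, cg_sd=0.5)
out = simulate(cfg)

spec = MixedModelSpec(fixed_terms="C(cg_id) + dam_age + I(dam_age**2)")
h2_ref = reference_h2(out.phenotypes, out.genotypes, out.panel_ids, spec)
print(f"reference h2 (array panel): {h2_ref:.3f}")

import numpy as np
ids = out.genotypes.markers["id"].to_numpy(object)
causal = MarkerSet(np.array([i for i in ids[out.qtl_effects != 0]
                             if i not in set(out.panel_ids.ids)], object))
augmented = out.panel_ids.union(causal, label="panel+causal")

for name, panel in [("array panel", out.panel_ids), ("augmented", augmented)]:
    res = cross_validate(out.phenotypes, out.genotypes, panel, spec, h2_ref,
                         model="gblup", k=10, seed=60)
    print(f"{name}: accuracy {res.accuracy_mean:.3f} (SD {res.accuracy_sd:.3f}), "
          f"bias {res.bias_mean:.3f}")
```

Output:

```
reference h2 (array panel): 0.255
array panel: accuracy 0.675 (SD 0.132), bias 1.003
augmented: accuracy 0.735 (SD 0.137), bias 0.991
```

The reference heritability is the array-panel GREML estimate on the full
prediction set (true simulated h² is 0.35; the array panel tags most but not
all of it, and a single 900-animal sample estimates it with an SE of a few
points). Adding the causal markers to the panel raises 10-fold mean accuracy
from 0.68 to 0.74 — the directional benefit of informative preselection —
while the bias slope stays at ~1, i.e. predictions are correctly dispersed.

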