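"""Mixed-linear-model association scan with a polygenic GRM control.

The null model y = X b + g + e (g ~ N(0, G sigma2_g)) is fitted once by
GREML; each candidate marker is then tested by generalized least squares
with V = G sigma2_g + I sigma2_e held fixed — the standard MLMA shortcut
that avoids re-estimating variance components per marker. No
leave-one-chromosome-out correction is applied by default (proximal
contamination is a documented limitation); pass ``loco=True`` to exclude the
candidate's chromosome from the polygenic GRM.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2

from gpsel.geno_grm import GRM, GenotypeMatrix, allele_freq_and_maf, build_grm
from gpsel.mixed_model import MixedModelSpec, design_matrix, reml_fit


def _scan_block(y, X, calls, V_inv):
    """GLS effect/SE/Wald per marker with fixed V; missing mean-imputed."""
    ViX = V_inv @ X
    XtViX_inv = np.linalg.inv(X.T @ ViX)
    # projected inverse-V: P = Vi - ViX (X'ViX)^-1 X'Vi
    def project(M):
        return V_inv @ M - ViX @ (XtViX_inv @ (ViX.T @ M))

    W = calls.astype(np.float64)
    miss = calls < 0
    if miss.any():
        obs = ~miss
        means = np.where(obs, W, 0.0).sum(0) / np.maximum(obs.sum(0), 1)
        W = np.where(miss, means, W)
    PW = project(W)
    Py = project(y[:, None])[:, 0]
    xpx = np.einsum("ij,ij->j", W, PW)
    xpy = W.T @ Py
    with np.errstate(invalid="ignore", divide="ignore"):
        b = xpy / xpx
        se = np.sqrt(1.0 / xpx)
        wald = b * b * xpx
    return b, se, wald, xpx


def mlma_scan(pheno: pd.DataFrame, geno: GenotypeMatrix, grm: GRM,
              fixed_terms: str = "1", response: str = "trait",
              loco: bool = False) -> pd.DataFrame:
    """Association table (chrom, pos, id, a1, freq, b, se, p) over all markers.

    Variance components come from one null GREML fit; monomorphic or aliased
    markers are skipped with p recorded as missing.
    """
    ids = pheno["individual_id"].to_numpy(object)
    spec = MixedModelSpec(response=response, fixed_terms=fixed_terms)
    null = reml_fit(spec, pheno, grm)
    if not null.converged:
        warnings.warn("null-model REML did not converge; scan uses last iterate")
    sg = null.variance_components["sigma2_g1"]
    se_var = null.variance_components["sigma2_e"]

    lookup = pd.Index(grm.individual_ids)
    gi = lookup.get_indexer(ids)
    if (gi < 0).any():
        raise ValueError("GRM/phenotype id mismatch")
    glook = pd.Index(geno.individual_ids)
    xi = glook.get_indexer(ids)
    if (xi < 0).any():
        raise ValueError("genotype/phenotype id mismatch")

    y = pheno[response].to_numpy(float)
    X, _, _, _ = design_matrix(spec, pheno)
    freqs = allele_freq_and_maf(geno)
    n = len(ids)

    chroms = geno.markers["chrom"].to_numpy()
    out_b = np.full(geno.n_markers, np.nan)
    out_se = np.full(geno.n_markers, np.nan)
    out_w = np.full(geno.n_markers, np.nan)
    groups = [(None, np.arange(geno.n_markers))] if not loco else [
        (c, np.flatnonzero(chroms == c)) for c in np.unique(chroms)]
    for chrom, cols in groups:
        if loco:
            keep = geno.markers["id"].to_numpy(object)[chroms != chrom]
            g_loco = build_grm(geno, keep)
            gmat = _submatrix(g_loco, ids)
        else:
            gmat = grm.matrix[np.ix_(gi, gi)]
        V = sg * gmat + se_var * np.eye(n)
        V_inv = np.linalg.inv(V)
        b, se, wald, xpx = _scan_block(y, X, geno.calls[np.ix_(xi, cols)], V_inv)
        bad = ~np.isfinite(xpx) | (xpx <= 1e-10)
        if bad.any():
            warnings.warn(f"{int(bad.sum())} markers aliased/monomorphic; skipped")
        b[bad] = se[bad] = wald[bad] = np.nan
        out_b[cols], out_se[cols], out_w[cols] = b, se, wald
    mono = (freqs["maf"].to_numpy() == 0) | freqs["all_missing"].to_numpy()
    out_b[mono] = out_se[mono] = out_w[mono] = np.nan
    p = np.where(np.isfinite(out_w), chi2.sf(out_w, df=1), np.nan)
    result = pd.DataFrame({
        "chrom": geno.markers["chrom"],
        "pos": geno.markers["pos"],
        "id": geno.markers["id"],
        "a1": geno.markers["a1"],
        "freq": freqs["p"],
        "b": out_b,
        "se": out_se,
        "p": p,
    })
    result.attrs["n_used"] = n
    result.attrs["variance_components"] = dict(null.variance_components)
    return result


def _submatrix(grm: GRM, ids) -> np.ndarray:
    idx = pd.Index(grm.individual_ids).get_indexer(np.asarray(ids, object))
    return grm.matrix[np.ix_(idx, idx)]


def gc_lambda(result: pd.DataFrame) -> float:
    """Genomic-control inflation factor: median Wald chi2 over 0.4549."""
    p = result["p"].dropna().to_numpy()
    if len(p) < 100:
        raise ValueError("need >= 100 tested markers")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / chi2.isf(0.5, df=1))
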