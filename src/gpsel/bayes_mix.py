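"""BayesR and BayesRC Gibbs samplers for the four-component effect mixture.

Marker effects on centred, unit-variance genotypes are modelled as a mixture
of four normals: a null point mass N(0, 0) and N(0, c * sigma2_g) with
c in {1e-4, 1e-3, 1e-2}. Single-site Gibbs sampling draws, per iteration,
fixed effects (flat priors, coordinate-wise), each marker's mixture component
from its posterior odds and its effect conditionally, the genetic and
residual variances from scaled inverse-chi-square full conditionals, and the
mixture proportions from a Dirichlet(1,1,1,1) posterior — per marker category
for BayesRC, so BayesR is exactly the single-category case and shares the
sampler.

Priors not pinned down elsewhere: Dirichlet(1,1,1,1) on proportions and
scaled inverse-chi-square with nu = 4 and scale set from an initial
heritability guess of 0.5 for both variances. Effects start at zero; no
thinning is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from gpsel.geno_grm import GenotypeMatrix, allele_freq_and_maf, standardize
from gpsel.mixed_model import MixedModelSpec, design_matrix

DEFAULT_SCALES = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class BayesConfig:
    n_iterations: int = 20_000
    burn_in: int = 10_000
    n_chains: int = 5
    mixture_scales: tuple = DEFAULT_SCALES
    seed: int = 0
    nu0: float = 4.0
    h2_start: float = 0.5

    def validate(self) -> None:
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")
        s = self.mixture_scales
        if s[0] != 0.0 or any(a > b for a, b in zip(s, s[1:])) or any(x < 0 for x in s):
            raise ValueError("mixture_scales must be non-negative ascending with first 0")


@dataclass
class BayesFit:
    effects: pd.Series               # posterior-mean effect per marker (std scale)
    comp_probs: np.ndarray           # m x 4 posterior component memberships
    pi_mean: np.ndarray              # n_cat x 4 posterior mixture proportions
    sigma2_g: float
    sigma2_e: float
    h2: float
    gebv: pd.Series
    chain_h2: np.ndarray
    traces: list                     # per chain: dict of 1-D/2-D sample arrays
    categories: np.ndarray
    marker_ids: np.ndarray
    fixed_effects: pd.Series
    chain_effects: np.ndarray = None  # n_chains x m posterior-mean effects
    _design_info: object = None
    _keep_cols: np.ndarray = None


@njit(cache=True)
def _gibbs_chain(y, XT, WT, cats, n_cat, scales, n_iter, burn_in, seed,
                 nu0, sg0, se0):
    # XT: q x n fixed design (rows = effects); WT: m x n standardized markers
    np.random.seed(seed)
    q, n = XT.shape
    m = WT.shape[0]
    n_comp = len(scales)
    xtx = np.empty(q)
    for k in range(q):
        xtx[k] = XT[k] @ XT[k]
    wtw = np.empty(m)
    for j in range(m):
        wtw[j] = WT[j] @ WT[j]
    beta = np.zeros(q)
    g = np.zeros(m)
    comp = np.zeros(m, dtype=np.int64)
    pi = np.full((n_cat, n_comp), 1.0 / n_comp)
    sg = sg0
    ve = se0
    r = y.copy()

    tr_sg = np.empty(n_iter)
    tr_ve = np.empty(n_iter)
    tr_h2 = np.empty(n_iter)
    tr_pi = np.empty((n_iter, n_cat, n_comp))
    g_sum = np.zeros(m)
    comp_sum = np.zeros((m, n_comp))
    beta_sum = np.zeros(q)
    n_kept = 0
    logp = np.empty(n_comp)

    for it in range(n_iter):
        # fixed effects, coordinate-wise with flat priors
        for k in range(q):
            if xtx[k] <= 0:
                continue
            rhs = XT[k] @ r + xtx[k] * beta[k]
            new_b = rhs / xtx[k] + np.random.standard_normal() * np.sqrt(ve / xtx[k])
            r += XT[k] * (beta[k] - new_b)
            beta[k] = new_b
        # marker effects with component indicators
        counts = np.zeros((n_cat, n_comp))
        for j in range(m):
            cat = cats[j]
            rhs = WT[j] @ r + wtw[j] * g[j]
            best = -1e300
            for c in range(n_comp):
                if pi[cat, c] <= 0:
                    logp[c] = -1e300
                    continue
                if scales[c] == 0.0:
                    logp[c] = np.log(pi[cat, c])
                else:
                    vc = scales[c] * sg
                    lhs = wtw[j] + ve / vc
                    uhat = rhs / lhs
                    logp[c] = (np.log(pi[cat, c])
                               - 0.5 * np.log(wtw[j] * vc / ve + 1.0)
                               + 0.5 * rhs * uhat / ve)
                if logp[c] > best:
                    best = logp[c]
            tot = 0.0
            for c in range(n_comp):
                logp[c] = np.exp(logp[c] - best)
                tot += logp[c]
            u = np.random.random() * tot
            acc = 0.0
            c_new = n_comp - 1
            for c in range(n_comp):
                acc += logp[c]
                if u <= acc:
                    c_new = c
                    break
            g_old = g[j]
            if scales[c_new] == 0.0:
                g_new = 0.0
            else:
                vc = scales[c_new] * sg
                lhs = wtw[j] + ve / vc
                g_new = rhs / lhs + np.random.standard_normal() * np.sqrt(ve / lhs)
            if g_old != g_new:
                r += WT[j] * (g_old - g_new)
            g[j] = g_new
            comp[j] = c_new
            counts[cat, c_new] += 1.0
        # genetic variance: scaled inverse chi-square full conditional
        ssq = 0.0
        k_nn = 0
        for j in range(m):
            if comp[j] > 0:
                ssq += g[j] * g[j] / scales[comp[j]]
                k_nn += 1
        sg = (ssq + nu0 * sg0) / np.random.chisquare(nu0 + k_nn)
        # residual variance
        ve = (r @ r + nu0 * se0) / np.random.chisquare(nu0 + n)
        if not np.isfinite(ve) or ve <= 0:
            raise RuntimeError("divergent residual variance in Gibbs chain")
        # mixture proportions: Dirichlet(1 + counts) per category
        for cat in range(n_cat):
            tot = 0.0
            for c in range(n_comp):
                draw = np.random.gamma(1.0 + counts[cat, c], 1.0)
                pi[cat, c] = draw
                tot += draw
            for c in range(n_comp):
                pi[cat, c] /= tot
        # genetic values and sampled heritability
        gv = np.zeros(n)
        for j in range(m):
            if g[j] != 0.0:
                gv += WT[j] * g[j]
        var_gv = gv.var()
        tr_sg[it] = sg
        tr_ve[it] = ve
        tr_h2[it] = var_gv / (var_gv + ve)
        tr_pi[it] = pi
        if it >= burn_in:
            n_kept += 1
            g_sum += g
            beta_sum += beta
            for j in range(m):
                comp_sum[j, comp[j]] += 1.0
    return (tr_sg, tr_ve, tr_h2, tr_pi, g_sum / n_kept, comp_sum / n_kept,
            beta_sum / n_kept)


def _prepare(pheno: pd.DataFrame, geno: GenotypeMatrix, fixed_terms: str,
             response: str):
    ids = pheno["individual_id"].to_numpy(object)
    xi = pd.Index(geno.individual_ids).get_indexer(ids)
    if (xi < 0).any():
        raise ValueError("phenotyped individual absent from genotypes")
    freqs = allele_freq_and_maf(geno)
    poly = ((freqs["p"] > 0) & (freqs["p"] < 1)).to_numpy()
    if not poly.all():
        geno = geno.subset_markers(freqs.loc[poly, "id"])
        freqs = freqs[poly].reset_index(drop=True)
    W = standardize(geno, freqs)[xi]
    y = pheno[response].to_numpy(float)
    spec = MixedModelSpec(response=response, fixed_terms=fixed_terms)
    X, x_cols, dinfo, keep = design_matrix(spec, pheno)
    return y, X, x_cols, dinfo, keep, W, geno


def bayesrc_fit(pheno: pd.DataFrame, geno: GenotypeMatrix,
                fixed_terms: str = "1", cfg: BayesConfig | None = None,
                categories: pd.Series | np.ndarray | None = None,
                response: str = "trait") -> BayesFit:
    """BayesRC: per-category mixture proportions; BayesR when one category.

    ``categories`` maps every marker (by position in / index of the genotype
    matrix) to an integer or string label; every marker must be labelled and
    every category non-empty.
    """
    cfg = cfg or BayesConfig()
    cfg.validate()
    y, X, x_cols, dinfo, keep_cols, W, geno = _prepare(pheno, geno, fixed_terms,
                                                       response)
    m = W.shape[1]
    if categories is None:
        cats = np.zeros(m, dtype=np.int64)
        cat_labels = np.array(["all"], dtype=object)
    else:
        if isinstance(categories, pd.Series):
            categories = categories.reindex(geno.markers["id"]).to_numpy()
        categories = np.asarray(categories)
        if len(categories) != m or pd.isna(categories).any():
            raise ValueError("every marker needs exactly one category label")
        codes, cat_labels = pd.factorize(categories)
        cats = codes.astype(np.int64)
    n_cat = int(cats.max()) + 1
    counts = np.bincount(cats, minlength=n_cat)
    if (counts == 0).any():
        raise ValueError("category with zero markers")

    var_y = y.var()
    sg0 = cfg.h2_start * var_y
    se0 = (1 - cfg.h2_start) * var_y
    scales = np.asarray(cfg.mixture_scales, dtype=np.float64)

    traces, g_means, comp_means, beta_means = [], [], [], []
    for chain in range(cfg.n_chains):
        seed = (cfg.seed + 7919 * chain) % (2 ** 31)
        tr_sg, tr_ve, tr_h2, tr_pi, g_mean, comp_mean, beta_mean = _gibbs_chain(
            y, np.ascontiguousarray(X.T), np.ascontiguousarray(W.T), cats,
            n_cat, scales, cfg.n_iterations, cfg.burn_in, seed, cfg.nu0,
            sg0, se0)
        traces.append({"sigma2_g": tr_sg, "sigma2_e": tr_ve, "h2": tr_h2,
                       "pi": tr_pi})
        g_means.append(g_mean)
        comp_means.append(comp_mean)
        beta_means.append(beta_mean)

    keep = slice(cfg.burn_in, None)
    chain_h2 = np.array([t["h2"][keep].mean() for t in traces])
    effects = np.mean(g_means, axis=0)
    gebv = W @ effects
    gebv -= gebv.mean()
    return BayesFit(
        effects=pd.Series(effects, index=geno.markers["id"].to_numpy(object)),
        comp_probs=np.mean(comp_means, axis=0),
        pi_mean=np.mean([t["pi"][keep].mean(axis=0) for t in traces], axis=0),
        sigma2_g=float(np.mean([t["sigma2_g"][keep].mean() for t in traces])),
        sigma2_e=float(np.mean([t["sigma2_e"][keep].mean() for t in traces])),
        h2=float(chain_h2.mean()),
        gebv=pd.Series(gebv, index=pheno["individual_id"].to_numpy(object)),
        chain_h2=chain_h2,
        traces=traces,
        categories=cats,
        marker_ids=geno.markers["id"].to_numpy(object),
        fixed_effects=pd.Series(np.mean(beta_means, axis=0), index=x_cols),
        chain_effects=np.asarray(g_means),
        _design_info=dinfo,
        _keep_cols=keep_cols,
    )


def bayesr_fit(pheno: pd.DataFrame, geno: GenotypeMatrix,
               fixed_terms: str = "1", cfg: BayesConfig | None = None,
               response: str = "trait") -> BayesFit:
    """BayesR: the single-category case of the shared sampler."""
    return bayesrc_fit(pheno, geno, fixed_terms, cfg, categories=None,
                       response=response)


def gebv_from_effects(fit: BayesFit, geno: GenotypeMatrix) -> pd.Series:
    """GEBV = standardized genotypes times posterior-mean effects, centred."""
    sub = geno.subset_markers(fit.marker_ids)
    W = standardize(sub)
    gebv = W @ fit.effects.to_numpy()
    gebv -= gebv.mean()
    return pd.Series(gebv, index=geno.individual_ids)


def bayes_h2(fit: BayesFit) -> float:
    """Posterior-mean heritability: per-chain means of sampled h2, averaged."""
    return float(fit.chain_h2.mean())
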