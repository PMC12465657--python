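"""Cross-validated prediction accuracy and dispersion bias.

Ten-fold cross-validation over the prediction set: per fold the model is
refitted on the training individuals, validation animals receive GEBV
through their genomic covariance with training animals, and performance is
summarised as

    accuracy = cor(GEBV, y*) / sqrt(h2_ref)
    bias     = OLS slope of y* on GEBV   (1 = no dispersion bias)

where y* is the corrected phenotype — the phenotype minus the
training-estimated fixed effects — and h2_ref is the heritability from the
base-panel (50k-style) single-GRM analysis of the full prediction set,
frozen before cross-validation. For Bayesian fits, accuracy and bias are
computed per MCMC chain within each fold and chain-averaged before the
fold average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy

from gpsel import bayes_mix
from gpsel.geno_grm import GenotypeMatrix, build_grm, standardize, allele_freq_and_maf
from gpsel.ld_select import MarkerSet
from gpsel.mixed_model import MixedModelSpec, RemlFit, gblup_predict, reml_fit


@dataclass
class EvalResult:
    per_fold: pd.DataFrame  # fold, accuracy, bias, n_validation
    accuracy_mean: float
    accuracy_sd: float
    bias_mean: float
    bias_sd: float
    h2_ref: float


def make_folds(ids, k: int = 10, seed: int = 0) -> pd.Series:
    """Uniform random partition into k folds with sizes differing by <= 1."""
    ids = np.asarray(ids, dtype=object)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} individuals")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = np.empty(len(ids), dtype=int)
    assignment[perm] = np.arange(len(ids)) % k
    return pd.Series(assignment, index=ids, name="fold")


def corrected_phenotype(pheno: pd.DataFrame, fit: RemlFit,
                        response: str = "trait") -> pd.Series:
    """y* = y - X b-hat with fixed effects estimated on the training fold.

    Rows whose categorical levels (e.g. contemporary groups) were unseen in
    training cannot be adjusted and are dropped; the count is reported via
    the returned series' ``attrs['n_dropped']``.
    """
    di = fit._design_info
    keep_rows = np.ones(len(pheno), dtype=bool)
    for factor, fi in di.factor_infos.items():
        if fi.type != "categorical":
            continue
        values = factor.eval(fi.state, pheno)
        if hasattr(values, "data"):  # patsy wraps C(...) in a categorical box
            values = values.data
        ok = pd.Series(np.asarray(values)).isin(set(fi.categories)).to_numpy()
        keep_rows &= ok
    sub = pheno.loc[keep_rows]
    if len(sub) == 0:
        raise ValueError("all validation records dropped (no shared factor levels)")
    (X,) = patsy.build_design_matrices([di], sub)
    Xk = np.asarray(X)[:, fit._keep_cols]
    y = sub[response].to_numpy(float)
    out = pd.Series(y - Xk @ fit.fixed_effects.to_numpy(),
                    index=sub["individual_id"].to_numpy(object))
    out.attrs["n_dropped"] = int((~keep_rows).sum())
    return out


def accuracy(gebv: np.ndarray, y_star: np.ndarray, h2_ref: float) -> float:
    """Pearson cor(GEBV, corrected phenotype) scaled by 1/sqrt(h2_ref)."""
    if not 0 < h2_ref <= 1:
        raise ValueError("h2_ref must be in (0, 1]")
    gebv = np.asarray(gebv, float)
    y_star = np.asarray(y_star, float)
    if len(gebv) < 3:
        raise ValueError("need at least 3 validation records")
    if gebv.std() == 0 or y_star.std() == 0:
        return float("nan")
    return float(np.corrcoef(gebv, y_star)[0, 1] / np.sqrt(h2_ref))


def bias_slope(gebv: np.ndarray, y_star: np.ndarray) -> float:
    """OLS slope of corrected phenotype on GEBV; 1 = unbiased dispersion."""
    gebv = np.asarray(gebv, float)
    y_star = np.asarray(y_star, float)
    var = gebv.var()
    if var == 0:
        return float("nan")
    return float(np.cov(gebv, y_star, ddof=0)[0, 1] / var)


def aggregate(per_fold: pd.DataFrame) -> dict:
    """Unweighted mean/SD across folds, chain-averaged within fold first."""
    if len(per_fold) == 0:
        raise ValueError("no folds to aggregate")
    df = per_fold
    if "chain" in df.columns:
        df = df.groupby("fold", as_index=False)[["accuracy", "bias"]].mean()
    return {
        "accuracy_mean": float(df["accuracy"].mean()),
        "accuracy_sd": float(df["accuracy"].std(ddof=1)) if len(df) > 1 else 0.0,
        "bias_mean": float(df["bias"].mean()),
        "bias_sd": float(df["bias"].std(ddof=1)) if len(df) > 1 else 0.0,
    }


def reference_h2(pheno: pd.DataFrame, geno: GenotypeMatrix, panel: MarkerSet,
                 spec: MixedModelSpec) -> float:
    """Base-panel single-GRM GREML heritability on the full prediction set."""
    grm = build_grm(geno, panel)
    fit = reml_fit(spec, pheno, grm)
    return fit.h2_total


def cross_validate(pheno: pd.DataFrame, geno: GenotypeMatrix,
                   marker_sets: list[MarkerSet] | MarkerSet,
                   spec: MixedModelSpec, h2_ref: float,
                   model: str = "gblup", k: int = 10, seed: int = 0,
                   bayes_cfg: "bayes_mix.BayesConfig | None" = None,
                   categories: np.ndarray | None = None) -> EvalResult:
    """k-fold CV of a genotype-set / model combination on the prediction set.

    ``marker_sets``: one set for gblup/bayesr/bayesrc, two for the two-GRM
    model ("gblup2", base panel first). Variance components are refitted per
    fold.
    """
    if isinstance(marker_sets, MarkerSet):
        marker_sets = [marker_sets]
    ids = pheno["individual_id"].to_numpy(object)
    folds = make_folds(ids, k=k, seed=seed)
    rows = []
    if model in ("gblup", "gblup2"):
        grms = [build_grm(geno, ms) for ms in marker_sets]
        if model == "gblup" and len(grms) != 1:
            raise ValueError("gblup takes one marker set")
        if model == "gblup2" and len(grms) != 2:
            raise ValueError("gblup2 takes two marker sets")
        for fold in range(k):
            val_mask = (folds.loc[ids] == fold).to_numpy()
            train = pheno.loc[~val_mask]
            val = pheno.loc[val_mask]
            fit = reml_fit(spec, train, grms)
            y_star = corrected_phenotype(val, fit)
            gebv = gblup_predict(fit, spec, train, grms,
                                 predict_ids=y_star.index.to_numpy())
            rows.append({"fold": fold,
                         "accuracy": accuracy(gebv.to_numpy(), y_star.to_numpy(), h2_ref),
                         "bias": bias_slope(gebv.to_numpy(), y_star.to_numpy()),
                         "n_validation": len(y_star)})
    elif model in ("bayesr", "bayesrc"):
        cfg = bayes_cfg or bayes_mix.BayesConfig()
        union = marker_sets[0]
        for ms in marker_sets[1:]:
            union = union.union(ms)
        sub = geno.subset_markers(union.ids)
        freqs = allele_freq_and_maf(sub)
        poly = ((freqs["p"] > 0) & (freqs["p"] < 1)).to_numpy()
        sub = sub.subset_markers(freqs.loc[poly, "id"])
        W_all = standardize(sub)
        # the GBLUP spec's CG factor doubles as the Bayes fixed design
        for fold in range(k):
            val_mask = (folds.loc[ids] == fold).to_numpy()
            train = pheno.loc[~val_mask]
            val = pheno.loc[val_mask]
            cats = categories if model == "bayesrc" else None
            if cats is not None and isinstance(cats, pd.Series):
                cats = cats.reindex(sub.markers["id"]).to_numpy()
            fit = bayes_mix.bayesrc_fit(train, sub, spec.fixed_terms, cfg,
                                        categories=cats, response=spec.response)
            y_star = corrected_phenotype(val, fit)
            vi = pd.Index(sub.individual_ids).get_indexer(y_star.index.to_numpy())
            W_val = W_all[vi][:, sub.marker_index(fit.marker_ids)]
            for chain in range(cfg.n_chains):
                gebv = W_val @ fit.chain_effects[chain]
                rows.append({"fold": fold, "chain": chain,
                             "accuracy": accuracy(gebv, y_star.to_numpy(), h2_ref),
                             "bias": bias_slope(gebv, y_star.to_numpy()),
                             "n_validation": len(y_star)})
    else:
        raise ValueError(f"unknown model '{model}'")
    per_fold = pd.DataFrame(rows)
    agg = aggregate(per_fold)
    return EvalResult(per_fold=per_fold, h2_ref=h2_ref, **agg)
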