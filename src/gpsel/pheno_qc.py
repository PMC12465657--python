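"""Phenotype editing, contemporary groups, AIC model choice, forward split.

Contemporary groups (CG) are the concatenation herd | birth year | sex |
management group | measurement date, further subdivided by age at measurement
in fixed-width day bins; groups below a trait-specific minimum size are
dropped together with their records. Fixed-effect candidates are compared by
ordinary-least-squares AIC.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

CG_COMPONENTS = ["herd", "birth_year", "sex", "management_group", "measurement_date"]

#: default fixed-effect candidate formulas per trait archetype; the retained
#: covariates mirror common practice for growth / reproduction / carcass traits
TRAIT_FORMULA_PRESETS = {
    "growth": ["trait ~ dam_age + I(dam_age**2)"],
    "reproduction": ["trait ~ age_days + I(age_days**2)"],
    "carcass": ["trait ~ age_days + I(age_days**2) + dam_age + I(dam_age**2)"],
}


def remove_outliers(tbl: pd.DataFrame, k_sd: float = 4.0,
                    column: str = "trait") -> pd.DataFrame:
    """Drop records more than ``k_sd`` standard deviations from the mean.

    The mean and SD are computed once on the input (not iteratively); a value
    exactly at the boundary is kept (strict inequality).
    """
    if len(tbl) < 2:
        raise ValueError("need at least 2 records")
    vals = tbl[column].to_numpy(float)
    mu, sd = vals.mean(), vals.std(ddof=0)
    if sd == 0:
        if k_sd > 0:
            warnings.warn("zero variance: no outliers removable")
        return tbl.copy()
    keep = np.abs(vals - mu) <= k_sd * sd
    return tbl.loc[keep].reset_index(drop=True)


def build_contemporary_groups(tbl: pd.DataFrame, age_bin_days: int = 60,
                              min_size: int = 40) -> pd.DataFrame:
    """CG labels from the component concatenation plus an age-day bin.

    Duplicated records are dropped first; groups with fewer than ``min_size``
    members are removed together with their records. Returns the filtered
    table with a ``cg_label`` column.
    """
    missing = [c for c in CG_COMPONENTS + ["age_days"] if c not in tbl.columns]
    if missing:
        raise KeyError(f"missing CG component columns: {missing}")
    out = tbl.drop_duplicates().copy()
    age_bin = (out["age_days"].to_numpy(int) // age_bin_days).astype(str)
    parts = [out[c].astype(str) for c in CG_COMPONENTS] + [pd.Series(age_bin, index=out.index)]
    out["cg_label"] = parts[0].str.cat(parts[1:], sep="|")
    sizes = out["cg_label"].value_counts()
    keep = sizes[sizes >= min_size].index
    return out[out["cg_label"].isin(keep)].reset_index(drop=True)


def _aliased_terms(tbl: pd.DataFrame, formula: str) -> bool:
    """True if the design for this formula is rank-deficient."""
    import patsy

    try:
        _, X = patsy.dmatrices(formula, tbl, return_type="dataframe")
    except Exception:
        return True
    return np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]


def select_fixed_effects(tbl: pd.DataFrame, candidate_terms: list[str]) -> str:
    """Smallest-AIC candidate among OLS fits; ties favour fewer parameters.

    Rank-deficient designs (aliased columns, e.g. zero-variance covariates)
    are fitted on the reduced design with a warning, as OLS with a
    pseudo-inverse does.
    """
    if not candidate_terms:
        raise ValueError("no candidate formulas")
    results = []
    for formula in candidate_terms:
        fit = smf.ols(formula, data=tbl).fit()
        k = int(np.linalg.matrix_rank(fit.model.exog)) + 1  # + sigma^2
        if k - 1 < fit.model.exog.shape[1]:
            warnings.warn(f"aliased columns dropped in '{formula}'")
        aic = 2 * k - 2 * fit.llf
        results.append((aic, k, formula))
    results.sort(key=lambda t: (t[0], t[1]))
    return results[0][2]


def forward_split(tbl: pd.DataFrame, split_year: int):
    """Split by birth year: discovery = born <= split_year, prediction after.

    Imitates forward prediction; both sides must be non-empty.
    """
    if "birth_year" not in tbl.columns:
        raise KeyError("birth_year column required")
    disc = tbl[tbl["birth_year"] <= split_year].reset_index(drop=True)
    pred = tbl[tbl["birth_year"] > split_year].reset_index(drop=True)
    if len(disc) == 0 or len(pred) == 0:
        raise ValueError(f"split_year={split_year} leaves an empty side "
                         f"(discovery={len(disc)}, prediction={len(pred)})")
    return disc, pred
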