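"""GREML variance components and GBLUP prediction.

Implements restricted maximum likelihood for an animal model with one or more
genomic relationship matrices plus an optional maternal effect with identity
covariance keyed by dam:

    y = X b + Z1 u1 [+ Z2 u2] [+ Zm m] + e,
    u_k ~ N(0, G_k * sigma2_gk),  m ~ N(0, I * sigma2_m),  e ~ N(0, I * sigma2_e).

Estimation is average-information (AI) REML with expectation-maximization
fallback steps whenever an AI update would leave the parameter space or
decrease the restricted likelihood, and a small positive floor on every
variance. Single-random-component fits use an exact spectral reformulation
(one eigendecomposition of the GRM, O(n) per iteration); the estimates are
identical to the dense path.

Breeding values are BLUPs from the mixed-model equations at the REML
estimates; for a two-GRM model the genomic value of an individual is the sum
u1 + u2. Individuals present in the GRM but without phenotype (a validation
fold) receive GEBV through their genomic covariance with the training
individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.stats import chi2

from gpsel.geno_grm import GRM


@dataclass
class MixedModelSpec:
    response: str = "trait"
    fixed_terms: str = "C(cg_id) + dam_age + I(dam_age**2)"
    maternal: str | None = None  # column holding dam ids, or None


@dataclass
class RemlFit:
    variance_components: dict
    fixed_effects: pd.Series
    gebv: pd.Series
    log_likelihood: float
    h2_components: dict
    h2_total: float
    converged: bool
    n_iterations: int
    spec: MixedModelSpec
    _py: np.ndarray = field(repr=False, default=None)
    _ids: np.ndarray = field(repr=False, default=None)
    _design_info: object = field(repr=False, default=None)
    _keep_cols: np.ndarray = field(repr=False, default=None)


def design_matrix(spec: MixedModelSpec, data: pd.DataFrame):
    """Fixed-effect design with deterministic removal of aliased columns."""
    import patsy

    X = patsy.dmatrix(spec.fixed_terms, data, return_type="dataframe")
    arr = X.to_numpy(float)
    _, r, piv = sla.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(arr.shape) * np.finfo(float).eps * (diag[0] if len(diag) else 1.0)
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    if rank < arr.shape[1]:
        dropped = [X.columns[i] for i in sorted(set(range(arr.shape[1])) - set(keep))]
        warnings.warn(f"dropping aliased fixed-effect columns: {dropped[:5]}")
    return arr[:, keep], [X.columns[i] for i in keep], X.design_info, keep


def _logdet_chol(c) -> float:
    return 2.0 * np.sum(np.log(np.diag(c)))


def _reml_spectral(y, X, A, max_iter=100, tol=1e-6, ltol=1e-8, start=None):
    """Exact REML for V = s_g A + s_e I via eigendecomposition of A."""
    n = len(y)
    d, U = np.linalg.eigh(A)
    d = np.maximum(d, 0.0)
    yt, Xt = U.T @ y, U.T @ X
    var_p = np.var(y - X @ np.linalg.lstsq(X, y, rcond=None)[0])
    floor = max(1e-8 * var_p, 1e-12)
    theta = np.array(start) if start is not None else np.array([0.5 * var_p, 0.5 * var_p])
    a_diags = [d, np.ones(n)]

    def core(theta):
        v = theta[0] * d + theta[1]
        vi = 1.0 / v
        ViX = Xt * vi[:, None]
        XtViX = Xt.T @ ViX
        cf = sla.cho_factor(XtViX)
        beta = sla.cho_solve(cf, ViX.T @ yt)
        py = vi * (yt - Xt @ beta)
        logl = -0.5 * (np.sum(np.log(v)) + _logdet_chol(cf[0]) + yt @ py)
        return v, vi, ViX, cf, py, logl

    v, vi, ViX, cf, py, logl = core(theta)
    n_iter, converged = 0, False
    for n_iter in range(1, max_iter + 1):
        qs = [ad * py for ad in a_diags]  # A_k P y in rotated basis
        pqs = []
        for q in qs:
            pq = vi * q - ViX @ sla.cho_solve(cf, ViX.T @ q)
            pqs.append(pq)
        tr_pa = []
        for ad in a_diags:
            t = np.sum(ad * vi) - np.trace(sla.cho_solve(cf, (ViX * ad[:, None]).T @ ViX))
            tr_pa.append(t)
        score = np.array([-0.5 * (tr_pa[k] - py @ qs[k]) for k in range(2)])
        ai = 0.5 * np.array([[qs[k] @ pqs[l] for l in range(2)] for k in range(2)])
        theta_new, ok = _propose(theta, score, ai, floor)
        v2 = theta_new[0] * d + theta_new[1]
        if ok and np.all(v2 > 0):
            out = core(theta_new)
            if out[-1] >= logl - 1e-10:
                delta = np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), floor))
                dll = out[-1] - logl
                theta, (v, vi, ViX, cf, py, logl) = theta_new, out
                if delta < tol or dll < ltol:
                    converged = True
                    break
                continue
        # EM fallback
        theta_em = np.array([
            max(theta[k] + theta[k] ** 2 * (py @ qs[k] - tr_pa[k]) / n, floor)
            for k in range(2)])
        out = core(theta_em)
        prev = logl
        theta, (v, vi, ViX, cf, py, logl) = theta_em, out
        if abs(logl - prev) < ltol:
            converged = True
            break
    beta = sla.cho_solve(cf, ViX.T @ yt)
    py_orig = U @ py
    return {"theta": theta, "beta": beta, "logl": float(logl),
            "py": py_orig, "converged": converged, "n_iter": n_iter}


def _propose(theta, score, ai, floor):
    try:
        step = np.linalg.solve(ai + 1e-12 * np.eye(len(ai)), score)
    except np.linalg.LinAlgError:
        return theta, False
    theta_new = theta + step
    if np.any(theta_new < floor):
        theta_new = np.maximum(theta_new, floor)
    return theta_new, True


def _reml_dense(y, X, covs, max_iter=100, tol=1e-6, ltol=1e-8, start=None):
    """AI-REML with EM fallback for V = sum_k theta_k A_k + theta_e I."""
    n = len(y)
    K = len(covs)
    mats = list(covs) + [np.eye(n)]
    var_p = np.var(y - X @ np.linalg.lstsq(X, y, rcond=None)[0])
    floor = max(1e-8 * var_p, 1e-12)
    if start is not None:
        theta = np.array(start, dtype=float)
    else:
        theta = np.full(K + 1, var_p / (K + 1))

    def core(theta):
        V = theta[-1] * np.eye(n)
        for k in range(K):
            V += theta[k] * covs[k]
        cv = sla.cho_factor(V, lower=True)
        Vi = sla.cho_solve(cv, np.eye(n))
        ViX = Vi @ X
        XtViX = X.T @ ViX
        cf = sla.cho_factor(XtViX)
        beta = sla.cho_solve(cf, ViX.T @ y)
        py = Vi @ y - ViX @ beta
        logl = -0.5 * (_logdet_chol(cv[0]) + _logdet_chol(cf[0]) + y @ py)
        return Vi, ViX, cf, py, logl

    Vi, ViX, cf, py, logl = core(theta)
    n_iter, converged = 0, False
    for n_iter in range(1, max_iter + 1):
        qs = [m @ py for m in mats]
        pqs = [Vi @ q - ViX @ sla.cho_solve(cf, ViX.T @ q) for q in qs]
        tr_pa = []
        for m in mats:
            via = Vi @ m if m is not mats[-1] else Vi
            t = np.trace(via) - np.trace(sla.cho_solve(cf, ViX.T @ (m @ ViX)))
            tr_pa.append(t)
        score = np.array([-0.5 * (tr_pa[k] - py @ qs[k]) for k in range(K + 1)])
        ai = 0.5 * np.array([[qs[k] @ pqs[l] for l in range(K + 1)]
                             for k in range(K + 1)])
        theta_new, ok = _propose(theta, score, ai, floor)
        if ok:
            try:
                out = core(theta_new)
            except np.linalg.LinAlgError:
                out = None
            if out is not None and out[-1] >= logl - 1e-10:
                delta = np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), floor))
                dll = out[-1] - logl
                theta, (Vi, ViX, cf, py, logl) = theta_new, out
                if delta < tol or dll < ltol:
                    converged = True
                    break
                continue
        theta_em = np.array([
            max(theta[k] + theta[k] ** 2 * (py @ qs[k] - tr_pa[k]) / n, floor)
            for k in range(K + 1)])
        prev = logl
        try:
            out = core(theta_em)
        except np.linalg.LinAlgError:
            break
        theta, (Vi, ViX, cf, py, logl) = theta_em, out
        if abs(logl - prev) < ltol:
            converged = True
            break
    beta = sla.cho_solve(cf, ViX.T @ y)
    return {"theta": theta, "beta": beta, "logl": float(logl),
            "py": py, "converged": converged, "n_iter": n_iter}


def _align_grm(grm: GRM, ids: np.ndarray) -> np.ndarray:
    lookup = pd.Index(grm.individual_ids)
    idx = lookup.get_indexer(ids)
    if (idx < 0).any():
        missing = ids[idx < 0][:5]
        raise ValueError(f"individuals absent from GRM: {list(missing)}")
    return grm.matrix[np.ix_(idx, idx)]


def _maternal_cov(dams: np.ndarray) -> np.ndarray:
    codes = pd.Categorical(dams).codes
    return (codes[:, None] == codes[None, :]).astype(float)


def _component_names(n_grm: int, maternal: bool) -> list[str]:
    names = [f"sigma2_g{k + 1}" for k in range(n_grm)]
    if maternal:
        names.append("sigma2_m")
    return names + ["sigma2_e"]


def reml_fit(spec: MixedModelSpec, data: pd.DataFrame, grms: list[GRM] | GRM,
             max_iter: int = 100, start=None, check_psd: bool = True) -> RemlFit:
    """GREML fit of the animal model; returns components, BLUEs, BLUPs, logL.

    ``data`` rows are the phenotyped (training) individuals; every id must be
    present in each GRM. Non-convergence within ``max_iter`` is flagged on the
    result, not raised.
    """
    if isinstance(grms, GRM):
        grms = [grms]
    ids = data["individual_id"].to_numpy(object)
    y = data[spec.response].to_numpy(float)
    X, x_cols, dinfo, keep_cols = design_matrix(spec, data)
    covs = [_align_grm(g, ids) for g in grms]
    if check_psd:
        for g, c in zip(grms, covs):
            ev = np.linalg.eigvalsh(c)[0]
            if ev < -1e-6:
                raise ValueError(f"GRM not PSD (min eigenvalue {ev:.2e})")
    if spec.maternal:
        covs.append(_maternal_cov(data[spec.maternal].to_numpy(object)))
    if len(covs) == 1:
        res = _reml_spectral(y, X, covs[0], max_iter=max_iter, start=start)
    else:
        res = _reml_dense(y, X, covs, max_iter=max_iter, start=start)
    names = _component_names(len(grms), bool(spec.maternal))
    comps = dict(zip(names, res["theta"]))
    total = float(np.sum(res["theta"]))
    h2c = {f"h2_g{k + 1}": comps[f"sigma2_g{k + 1}"] / total for k in range(len(grms))}
    if spec.maternal:
        h2c["h2_dam"] = comps["sigma2_m"] / total
    h2_total = float(sum(h2c[f"h2_g{k + 1}"] for k in range(len(grms))))
    gebv = np.zeros(len(ids))
    for k in range(len(grms)):
        gebv += comps[f"sigma2_g{k + 1}"] * (covs[k] @ res["py"])
    return RemlFit(
        variance_components=comps,
        fixed_effects=pd.Series(res["beta"], index=x_cols),
        gebv=pd.Series(gebv, index=ids),
        log_likelihood=res["logl"],
        h2_components=h2c,
        h2_total=h2_total,
        converged=res["converged"],
        n_iterations=res["n_iter"],
        spec=spec,
        _py=res["py"],
        _ids=ids,
        _design_info=dinfo,
        _keep_cols=keep_cols,
    )


def gblup_predict(fit: RemlFit, spec: MixedModelSpec, data: pd.DataFrame,
                  grms: list[GRM] | GRM, predict_ids=None) -> pd.Series:
    """GEBV for arbitrary individuals present in the GRM(s).

    Training individuals get their in-sample BLUP; others (a validation fold)
    get sigma2_gk * G_k[new, train] @ P y summed over genetic components —
    the genomic covariance route of forward prediction.
    """
    if isinstance(grms, GRM):
        grms = [grms]
    if not fit.converged:
        warnings.warn("predicting from a non-converged REML fit")
    train_ids = fit._ids
    if predict_ids is None:
        predict_ids = grms[0].individual_ids
    predict_ids = np.asarray(predict_ids, dtype=object)
    gebv = np.zeros(len(predict_ids))
    for k, grm in enumerate(grms):
        lookup = pd.Index(grm.individual_ids)
        ti = lookup.get_indexer(train_ids)
        pi = lookup.get_indexer(predict_ids)
        if (ti < 0).any() or (pi < 0).any():
            raise ValueError("individual absent from GRM")
        block = grm.matrix[np.ix_(pi, ti)]
        gebv += fit.variance_components[f"sigma2_g{k + 1}"] * (block @ fit._py)
    return pd.Series(gebv, index=predict_ids)


def lrt_compare(fit_single: RemlFit, fit_two: RemlFit):
    """Boundary likelihood-ratio test for one extra variance component.

    statistic = 2 (logL_two - logL_single); p from the 50:50 mixture of
    chi2(0) and chi2(1) appropriate when the null pins a variance at zero.
    """
    if list(fit_single.fixed_effects.index) != list(fit_two.fixed_effects.index):
        raise ValueError("fits are not nested: fixed designs differ")
    stat = 2.0 * (fit_two.log_likelihood - fit_single.log_likelihood)
    stat = max(stat, 0.0)
    p = 1.0 if stat == 0.0 else 0.5 * float(chi2.sf(stat, df=1))
    return stat, 1, p
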