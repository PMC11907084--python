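"""Multivariable MR estimators: IVW, Egger and heterogeneity-minimising QHET.

These supply the mediator-adjusted effect used as the second step of
two-step mediation. All fits weight SNPs by the inverse outcome variance
and use multiplicative overdispersion floored at 1 for coefficient SEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .exceptions import EstimationError
from .mr_core import Z95
from .sumstats import HarmonizedSet


@dataclass(frozen=True)
class MVMREstimate:
    """Per-exposure causal effects conditional on the other exposures."""

    method: str
    exposure_names: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_snp: int
    q: float
    df: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def beta_for(self, name: str) -> tuple[float, float]:
        i = self.exposure_names.index(name)
        return float(self.betas[i]), float(self.ses[i])


def _finalize(method, names, betas, ses, n, q, df, intercept=None, i_se=None, i_p=None):
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(ses > 0, betas / ses, 0.0)
    pvals = np.where(np.isinf(ses), 1.0, np.minimum(1.0, 2.0 * norm.sf(np.abs(z))))
    return MVMREstimate(
        method=method,
        exposure_names=list(names),
        betas=betas,
        ses=ses,
        pvals=pvals,
        ci_low=betas - Z95 * ses,
        ci_high=betas + Z95 * ses,
        n_snp=n,
        q=float(q),
        df=int(df),
        intercept=intercept,
        intercept_se=i_se,
        intercept_p=i_p,
    )


def _active_columns(X: np.ndarray, names: list[str]) -> np.ndarray:
    """Columns with any signal; identically-zero exposures are dropped from
    the fit and reported as beta 0 with infinite SE."""
    active = np.abs(X).max(axis=0) > 0
    return active


def _check_rank(Xw: np.ndarray, names: list[str]) -> None:
    s = np.linalg.svd(Xw, compute_uv=False)
    if s.size and s.min() < 1e-10 * s.max():
        corr = np.corrcoef(Xw, rowvar=False)
        pairs = [
            f"{names[i]}~{names[j]}"
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 0.999
        ]
        raise EstimationError(
            "rank-deficient design; collinear exposures: " + (", ".join(pairs) or "unidentified")
        )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, dof: int):
    a = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(a, X.T @ (w * y))
    resid = y - X @ coef
    q = float((w * resid**2).sum())
    cov = max(1.0, q / dof) * np.linalg.inv(a)
    return coef, np.sqrt(np.diag(cov)), q


def mvmr_ivw(h: HarmonizedSet) -> MVMREstimate:
    """Multivariable IVW: WLS of by on the K exposure-effect columns, no intercept."""
    X, y, w = h.bx, h.by, 1.0 / h.sey**2
    n, k = X.shape
    if n <= k:
        raise EstimationError(f"multivariable IVW needs n_snp > K ({n} <= {k})")
    active = _active_columns(X, h.exposure_names)
    Xa = X[:, active]
    ka = int(active.sum())
    if ka == 0:
        raise EstimationError("all exposure-effect columns are zero")
    _check_rank(np.sqrt(w)[:, None] * Xa, [n_ for n_, a in zip(h.exposure_names, active) if a])
    coef_a, ses_a, q = _wls(Xa, y, w, n - ka)
    betas = np.zeros(k)
    ses = np.full(k, np.inf)
    betas[active] = coef_a
    ses[active] = ses_a
    return _finalize("MV_IVW", h.exposure_names, betas, ses, n, q, n - ka)


def mvmr_egger(h: HarmonizedSet, orient_to: int = 0) -> MVMREstimate:
    """Multivariable MR-Egger: adds an intercept, orienting SNPs so the
    chosen exposure's effects are non-negative; the intercept p is the
    multivariable pleiotropy test."""
    X, y = h.bx.copy(), h.by.copy()
    n, k = X.shape
    if n <= k + 1:
        raise EstimationError(f"multivariable Egger needs n_snp > K+1 ({n} <= {k + 1})")
    sgn = np.where(X[:, orient_to] < 0, -1.0, 1.0)
    X = X * sgn[:, None]
    y = y * sgn
    w = 1.0 / h.sey**2
    active = _active_columns(X, h.exposure_names)
    Xa = X[:, active]
    ka = int(active.sum())
    design = np.column_stack([np.ones(n), Xa])
    _check_rank(np.sqrt(w)[:, None] * design, ["intercept"] + [
        n_ for n_, a in zip(h.exposure_names, active) if a
    ])
    coef, ses_all, q = _wls(design, y, w, n - ka - 1)
    betas = np.zeros(k)
    ses = np.full(k, np.inf)
    betas[active] = coef[1:]
    ses[active] = ses_all[1:]
    i_z = coef[0] / ses_all[0]
    return _finalize(
        "MV_EGGER",
        h.exposure_names,
        betas,
        ses,
        n,
        q,
        n - ka - 1,
        intercept=float(coef[0]),
        i_se=float(ses_all[0]),
        i_p=float(min(1.0, 2.0 * norm.sf(abs(i_z)))),
    )


def qhet_objective(theta: np.ndarray, X: np.ndarray, y: np.ndarray, sex2: np.ndarray, sey2: np.ndarray) -> float:
    """Heterogeneity statistic with weak-instrument-robust weights:
    Q(theta) = sum_j (by_j - X_j . theta)^2 / (sey_j^2 + sum_k theta_k^2 sex_jk^2)."""
    resid = y - X @ theta
    denom = sey2 + sex2 @ (np.asarray(theta) ** 2)
    return float((resid**2 / denom).sum())


def qhet(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MVMREstimate:
    """Q-minimising MVMR estimator with nonparametric bootstrap CIs over SNPs."""
    X, y = h.bx, h.by
    sex2, sey2 = h.sex**2, h.sey**2
    n, k = X.shape
    if n <= k:
        raise EstimationError(f"QHET needs n_snp > K ({n} <= {k})")

    def _fit(Xs, ys, s2x, s2y) -> np.ndarray:
        w = 1.0 / s2y
        a = Xs.T @ (w[:, None] * Xs)
        x0 = np.linalg.solve(a, Xs.T @ (w * ys))
        res = minimize(
            qhet_objective,
            x0,
            args=(Xs, ys, s2x, s2y),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000, "maxfev": 10000},
        )
        if not res.success:
            raise EstimationError(f"QHET optimiser failed: {res.message} (nit={res.nit})")
        return res.x

    theta = _fit(X, y, sex2, sey2)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, k))
    b = 0
    attempts = 0
    while b < n_boot:
        attempts += 1
        if attempts > 20 * n_boot:
            raise EstimationError("QHET bootstrap: too many singular resamples")
        idx = rng.integers(0, n, n)
        try:
            boots[b] = _fit(X[idx], y[idx], sex2[idx], sey2[idx])
        except (EstimationError, np.linalg.LinAlgError):
            continue
        b += 1
    ses = boots.std(axis=0, ddof=1)
    ci_low = np.percentile(boots, 2.5, axis=0)
    ci_high = np.percentile(boots, 97.5, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(ses > 0, theta / ses, 0.0)
    pvals = np.minimum(1.0, 2.0 * norm.sf(np.abs(z)))
    return MVMREstimate(
        method="QHET",
        exposure_names=list(h.exposure_names),
        betas=np.asarray(theta, dtype=float),
        ses=ses,
        pvals=pvals,
        ci_low=ci_low,
        ci_high=ci_high,
        n_snp=n,
        q=qhet_objective(theta, X, y, sex2, sey2),
        df=n - k,
    )


def conditional_f(h: HarmonizedSet) -> np.ndarray:
    """Heuristic conditional instrument-strength F per exposure: the mean
    squared standardised residual of that exposure's effects after weighted
    regression on the other exposures' effect columns. Reported as a
    diagnostic; not used as a hard filter."""
    X = h.bx
    n, k = X.shape
    out = np.empty(k)
    for j in range(k):
        xj = X[:, j]
        sj2 = h.sex[:, j] ** 2
        others = np.delete(X, j, axis=1)
        if others.shape[1] == 0 or np.abs(others).max() == 0:
            resid = xj
        else:
            w = 1.0 / sj2
            a = others.T @ (w[:, None] * others)
            try:
                coef = np.linalg.solve(a, others.T @ (w * xj))
            except np.linalg.LinAlgError:
                coef = np.zeros(others.shape[1])
            resid = xj - others @ coef
        out[j] = float((resid**2 / sj2).sum() / max(1, n - (k - 1)))
    return out
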