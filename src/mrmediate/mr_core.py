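"""Univariable two-sample MR estimators, diagnostics, sensitivity analyses and power.

All estimators consume a K = 1 :class:`~mrmediate.sumstats.HarmonizedSet` and
return an :class:`MREstimate` whose 95% confidence interval is Wald-type,
``beta +/- 1.96 * se``. P-values are two-sided from the normal distribution,
except Cochran's Q which uses the upper chi-square tail.

Random-effects IVW uses the multiplicative overdispersion form: the
fixed-effect standard error is scaled by ``max(1, sqrt(Q / df))``. Ratio
variances are first order (``sey^2 / bx^2``) everywhere except the radial
IVW, which uses modified second-order weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm

from .exceptions import ConfigurationError, EstimationError, UndefinedRatioError
from .sumstats import HarmonizedSet

Z95 = 1.96  # Wald-type 95% CI multiplier used throughout


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds or per-unit scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snp: int) -> "MREstimate":
        if not (se > 0 and np.isfinite(se)):
            raise EstimationError(f"{method}: standard error must be positive, got {se}")
        z = beta / se
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - Z95 * se),
            ci_high=float(beta + Z95 * se),
            pval=float(min(1.0, 2.0 * norm.sf(abs(z)))),
            n_snp=int(n_snp),
        )

    @property
    def odds_ratio(self) -> float:
        """exp(beta): the OR per unit exposure for a binary outcome."""
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its degrees of freedom, p-value and I-squared."""

    Q: float
    df: int
    pval: float
    i2: float


@dataclass(frozen=True)
class PleiotropyResult:
    """The Egger intercept test for directional horizontal pleiotropy."""

    intercept: float
    se: float
    pval: float


@dataclass(frozen=True)
class LeaveOneOutResult:
    full: MREstimate
    estimates: list[tuple[str, MREstimate]]
    max_abs_deviation: float


@dataclass(frozen=True)
class MRPressoResult:
    global_rss: float
    global_p: float
    outlier_ids: list[str]
    outlier_pvals: dict[str, float]
    distortion_p: float | None
    raw: MREstimate
    corrected: MREstimate | None


def wald_ratio(bx: float, sex: float, by: float, sey: float) -> MREstimate:
    """Single-SNP causal estimate ``by / bx`` with first-order SE ``sey / |bx|``."""
    if bx == 0:
        raise UndefinedRatioError("Wald ratio undefined for bx = 0")
    return MREstimate.from_beta_se("WALD", by / bx, sey / abs(bx), 1)


def ivw(h: HarmonizedSet, mode: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate: WLS of by on bx through the origin.

    ``mode='random'`` applies multiplicative overdispersion, scaling the
    fixed-effect SE by ``max(1, sqrt(Q/df))``; it requires >= 2 SNPs.
    """
    if mode not in ("fixed", "random"):
        raise ConfigurationError(f"ivw mode must be 'fixed' or 'random', got {mode!r}")
    bx, _, by, sey = h.univariable()
    n = h.n_snp
    if mode == "random" and n < 2:
        raise EstimationError("random-effects IVW needs at least 2 SNPs")
    w = 1.0 / sey**2
    s2 = float((w * bx**2).sum())
    if s2 == 0:
        raise EstimationError("IVW undefined: all exposure effects are zero")
    beta = float((w * bx * by).sum()) / s2
    se = 1.0 / np.sqrt(s2)
    method = "IVW_FIXED"
    if mode == "random":
        q = cochran_q(h, beta)
        se *= max(1.0, np.sqrt(q.Q / q.df))
        method = "IVW_RANDOM"
    return MREstimate.from_beta_se(method, beta, se, n)


def cochran_q(h: HarmonizedSet, beta: float) -> HeterogeneityResult:
    """Cochran's Q of the per-SNP ratios around ``beta``, with I-squared."""
    bx, _, by, sey = h.univariable()
    n = h.n_snp
    if n < 2:
        raise EstimationError("Cochran's Q needs at least 2 SNPs")
    if np.any(bx == 0):
        raise UndefinedRatioError("Cochran's Q undefined when any bx is zero")
    w = bx**2 / sey**2
    q = float((w * (by / bx - beta) ** 2).sum())
    df = n - 1
    i2 = 0.0 if q == 0 else max(0.0, (q - df) / q)
    return HeterogeneityResult(Q=q, df=df, pval=float(chi2.sf(q, df)), i2=i2)


def _oriented(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flip SNP signs so all exposure effects are non-negative."""
    bx, _, by, sey = h.univariable()
    sgn = np.where(bx < 0, -1.0, 1.0)
    return bx * sgn, by * sgn, sey


def egger(h: HarmonizedSet) -> tuple[MREstimate, PleiotropyResult]:
    """MR-Egger: WLS of by on bx with an intercept, SNPs oriented to bx >= 0.

    The slope is the pleiotropy-adjusted causal estimate; the intercept and
    its two-sided p form the directional-pleiotropy test. The coefficient
    covariance uses multiplicative overdispersion floored at 1.
    """
    n = h.n_snp
    if n < 3:
        raise EstimationError("MR-Egger needs at least 3 SNPs")
    x, y, sey = _oriented(h)
    w = 1.0 / sey**2
    X = np.column_stack([np.ones(n), x])
    a = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    coef = np.linalg.solve(a, b)
    resid = y - X @ coef
    phi = float((w * resid**2).sum()) / (n - 2)
    cov = max(1.0, phi) * np.linalg.inv(a)
    slope_se = float(np.sqrt(cov[1, 1]))
    int_se = float(np.sqrt(cov[0, 0]))
    est = MREstimate.from_beta_se("EGGER", float(coef[1]), slope_se, n)
    z0 = coef[0] / int_se
    pleio = PleiotropyResult(
        intercept=float(coef[0]),
        se=int_se,
        pval=float(min(1.0, 2.0 * norm.sf(abs(z0)))),
    )
    return est, pleio


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w)
    p = 100.0 * (s - w / 2.0)  # midpoint-rule cumulative percentile
    return float(np.interp(50.0, p, r))


def _median_point(bx, by, sey, penalized: bool) -> float:
    if np.any(bx == 0):
        raise UndefinedRatioError("weighted median undefined when any bx is zero")
    ratios = by / bx
    w = bx**2 / sey**2  # inverse first-order ratio variance
    est = _weighted_median(ratios, w)
    if penalized:
        qc = w * (ratios - est) ** 2  # per-SNP Q contribution at the unpenalised estimate
        qp = chi2.sf(qc, 1)
        est = _weighted_median(ratios, w * np.minimum(1.0, 20.0 * qp))
    return est


def weighted_median(
    h: HarmonizedSet, penalized: bool = False, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """(Penalised) weighted median of per-SNP ratios; SE by parametric bootstrap.

    Consistent when at least half of the weight comes from valid
    instruments. The penalised variant downweights each SNP by
    ``min(1, 20 * q_j)`` where ``q_j`` is the chi-square p of its
    heterogeneity contribution at the unpenalised estimate.
    """
    bx, sex, by, sey = h.univariable()
    n = h.n_snp
    if n < 3:
        raise EstimationError("weighted median needs at least 3 SNPs")
    est = _median_point(bx, by, sey, penalized)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sex * rng.standard_normal(n)
        byb = by + sey * rng.standard_normal(n)
        bxb[bxb == 0] = np.finfo(float).tiny
        boots[b] = _median_point(bxb, byb, sey, penalized)
    se = float(boots.std(ddof=1))
    return MREstimate.from_beta_se("PWMEDIAN" if penalized else "WMEDIAN", est, se, n)


def max_likelihood(h: HarmonizedSet, xtol: float = 1e-12, max_iter: int = 500) -> MREstimate:
    """Profile maximum likelihood under the bivariate normal measurement model.

    (bx_j, by_j) are independent normals with means (xi_j, theta * xi_j);
    profiling out the xi_j reduces -2 log L to
    ``sum (by - theta*bx)^2 / (sey^2 + theta^2 * sex^2)``, minimised
    numerically. The SE comes from the observed information of the profile.
    """
    bx, sex, by, sey = h.univariable()
    n = h.n_snp

    def negll(theta: float) -> float:
        return float(((by - theta * bx) ** 2 / (sey**2 + theta**2 * sex**2)).sum())

    w0 = 1.0 / sey**2
    s2 = float((w0 * bx**2).sum())
    if s2 == 0:
        raise EstimationError("maximum likelihood undefined: all exposure effects are zero")
    start = float((w0 * bx * by).sum()) / s2
    span = 10.0 * (abs(start) + 1.0)
    res = minimize_scalar(
        negll,
        method="bounded",
        bounds=(start - span, start + span),
        options={"xatol": xtol, "maxiter": max_iter},
    )
    if not res.success:
        raise EstimationError(
            f"maximum likelihood failed to converge (xatol={xtol}, maxiter={max_iter}): {res.message}"
        )
    theta = float(res.x)
    step = 1e-5 * (1.0 + abs(theta))
    qpp = (negll(theta + step) - 2.0 * negll(theta) + negll(theta - step)) / step**2
    if not np.isfinite(qpp) or qpp <= 0:
        raise EstimationError(
            f"maximum likelihood information not positive (xatol={xtol}, maxiter={max_iter})"
        )
    se = float(np.sqrt(2.0 / qpp))
    return MREstimate.from_beta_se("ML", theta, se, n)


def radial_ivw(h: HarmonizedSet) -> MREstimate:
    """Radial IVW with modified second-order weights.

    ``w_j = 1 / (sey^2/bx^2 + by^2 sex^2 / bx^4)``; the square-root-weighted
    ratio is regressed on the square-root weight without intercept, whose
    slope is the causal estimate.
    """
    bx, sex, by, sey = h.univariable()
    n = h.n_snp
    if np.any(bx == 0):
        raise UndefinedRatioError("radial IVW undefined when any bx is zero")
    ratio = by / bx
    w = 1.0 / (sey**2 / bx**2 + by**2 * sex**2 / bx**4)
    beta = float((w * ratio).sum() / w.sum())
    if n == 1:
        se = float(1.0 / np.sqrt(w.sum()))
    else:
        resid = np.sqrt(w) * ratio - beta * np.sqrt(w)
        sigma2 = float((resid**2).sum()) / (n - 1)
        se = float(np.sqrt(max(1.0, sigma2) / w.sum()))
    return MREstimate.from_beta_se("RADIAL_IVW", beta, se, n)


#: estimator registry used by leave-one-out, the pipeline and the CLI
ESTIMATORS = {
    "IVW_FIXED": lambda h, **kw: ivw(h, "fixed"),
    "IVW_RANDOM": lambda h, **kw: ivw(h, "random"),
    "EGGER": lambda h, **kw: egger(h)[0],
    "WMEDIAN": lambda h, **kw: weighted_median(h, penalized=False, **kw),
    "PWMEDIAN": lambda h, **kw: weighted_median(h, penalized=True, **kw),
    "ML": lambda h, **kw: max_likelihood(h),
    "RADIAL_IVW": lambda h, **kw: radial_ivw(h),
}


def leave_one_out(h: HarmonizedSet, method: str = "IVW_FIXED", **kwargs) -> LeaveOneOutResult:
    """Re-estimate with each SNP omitted in turn; flags influential variants."""
    if h.n_snp < 3:
        raise EstimationError("leave-one-out needs at least 3 SNPs")
    if method not in ESTIMATORS:
        raise ConfigurationError(f"unknown estimator {method!r}; choose from {sorted(ESTIMATORS)}")
    fn = ESTIMATORS[method]
    full = fn(h, **kwargs)
    out: list[tuple[str, MREstimate]] = []
    max_dev = 0.0
    for i in range(h.n_snp):
        sub = h.subset([j for j in range(h.n_snp) if j != i])
        est = fn(sub, **kwargs)
        out.append((h.snp_ids[i], est))
        max_dev = max(max_dev, abs(est.beta - full.beta))
    return LeaveOneOutResult(full=full, estimates=out, max_abs_deviation=max_dev)


def _loo_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorised leave-one-out fixed-effect IVW betas (last axis = SNPs)."""
    s1 = (w * bx * by).sum(axis=-1, keepdims=True)
    s2 = (w * bx**2).sum(axis=-1, keepdims=True)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


def mr_presso(
    h: HarmonizedSet, n_sim: int = 1000, outlier_alpha: float = 0.05, seed: int = 0
) -> MRPressoResult:
    """Residual-sum-of-squares pleiotropy test with outlier and distortion tests.

    The observed weighted RSS around leave-one-out IVW fits is compared to
    its parametric null distribution (``n_sim`` simulations). Per-SNP
    outlier tests use Bonferroni-corrected ``outlier_alpha`` and are only
    reported when the global test is significant at 0.05. The corrected
    estimate is fixed-effect IVW on the retained SNPs; the distortion test
    compares the observed shift against removal of random same-size subsets.
    """
    bx, sex, by, sey = h.univariable()
    n = h.n_snp
    if n < 4:
        raise EstimationError("MR-PRESSO needs at least 4 SNPs")
    rng = np.random.default_rng(seed)
    w = 1.0 / sey**2
    loo = _loo_betas(bx, by, w)
    obs_r = w * (by - loo * bx) ** 2
    rss_obs = float(obs_r.sum())

    bx_s = bx + sex * rng.standard_normal((n_sim, n))
    by_s = loo * bx + sey * rng.standard_normal((n_sim, n))
    loo_s = _loo_betas(bx_s, by_s, w)
    r_s = w * (by_s - loo_s * bx_s) ** 2
    rss_s = r_s.sum(axis=1)
    global_p = float((1 + (rss_s >= rss_obs).sum()) / (n_sim + 1))

    outlier_p = (r_s >= obs_r).mean(axis=0)
    raw = ivw(h, "fixed")
    outlier_ids: list[str] = []
    corrected: MREstimate | None = None
    distortion_p: float | None = None
    if global_p < 0.05:
        flagged = outlier_p < outlier_alpha / n
        outlier_ids = [s for s, f in zip(h.snp_ids, flagged) if f]
        if outlier_ids and not flagged.all():
            keep = ~flagged
            corrected = ivw(h.subset(keep), "fixed")
            d_obs = 100.0 * (raw.beta - corrected.beta) / abs(corrected.beta)
            n_out = int(flagged.sum())
            d_null = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(n, size=n_out, replace=False)
                mask = np.ones(n, dtype=bool)
                mask[drop] = False
                b_sub = float((w[mask] * bx[mask] * by[mask]).sum() / (w[mask] * bx[mask] ** 2).sum())
                d_null[s] = 100.0 * (raw.beta - b_sub) / abs(b_sub)
            distortion_p = float((np.abs(d_null) >= abs(d_obs)).mean())
    return MRPressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outlier_ids=outlier_ids,
        outlier_pvals={s: float(p) for s, p in zip(h.snp_ids, outlier_p)},
        distortion_p=distortion_p,
        raw=raw,
        corrected=corrected,
    )


def _ivw_beta_rows(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    return (w * bx * by).sum(axis=-1) / (w * bx**2).sum(axis=-1)


def simex_ivw(
    h: HarmonizedSet,
    lambdas: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0),
    n_boot: int = 200,
    seed: int = 0,
    n_boot_se: int = 100,
) -> MREstimate:
    """Simulation-extrapolation correction of IVW for exposure measurement error.

    For each lambda in the grid, noise with variance ``lambda * sex^2`` is
    added to bx ``n_boot`` times and the IVW estimate averaged; a quadratic
    in lambda is extrapolated back to lambda = -1, undoing the violation of
    the no-measurement-error (NOME) assumption. SE by nonparametric
    bootstrap over SNPs of the whole procedure.
    """
    lam = sorted({float(v) for v in lambdas})
    if 0.0 not in lam:
        raise ConfigurationError("the SIMEX lambda grid must include 0")
    bx, sex, by, sey = h.univariable()
    n = h.n_snp
    if n < 3:
        raise EstimationError("IVW-SIMEX needs at least 3 SNPs")
    plain = ivw(h, "fixed")
    if len(lam) == 1:
        return MREstimate.from_beta_se("IVW_SIMEX", plain.beta, plain.se, n)
    rng = np.random.default_rng(seed)

    def simex_point(bxv, sexv, byv, seyv) -> float:
        w = 1.0 / seyv**2
        means = []
        for lv in lam:
            if lv == 0.0:
                means.append(float(_ivw_beta_rows(bxv, byv, w)))
            else:
                noisy = bxv + np.sqrt(lv) * sexv * rng.standard_normal((n_boot, bxv.size))
                means.append(float(_ivw_beta_rows(noisy, byv, w).mean()))
        coef = np.polyfit(lam, means, deg=min(2, len(lam) - 1))
        return float(np.polyval(coef, -1.0))

    point = simex_point(bx, sex, by, sey)
    boots = np.empty(n_boot_se)
    for b in range(n_boot_se):
        idx = rng.integers(0, n, n)
        boots[b] = simex_point(bx[idx], sex[idx], by[idx], sey[idx])
    se = float(boots.std(ddof=1))
    return MREstimate.from_beta_se("IVW_SIMEX", point, se, n)


def power_binary(
    n: float, case_fraction: float, r2_gx: float, or_alt: float, alpha: float = 0.05
) -> float:
    """Normal-approximation power of two-sample MR with a binary outcome.

    Non-centrality ``sqrt(n * r2_gx * cf * (1 - cf)) * |log OR|`` against a
    two-sided level-``alpha`` z-test.
    """
    if not (0 < case_fraction < 1):
        raise ConfigurationError("case_fraction must be in (0, 1)")
    if not (0 <= r2_gx <= 1):
        raise ConfigurationError("r2_gx must be in [0, 1]")
    if not (0 < alpha < 1) or or_alt <= 0 or n <= 0:
        raise ConfigurationError("invalid power parameters")
    ncp = np.sqrt(n * r2_gx * case_fraction * (1.0 - case_fraction)) * abs(np.log(or_alt))
    zcrit = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.sf(zcrit - ncp) + norm.cdf(-zcrit - ncp))
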