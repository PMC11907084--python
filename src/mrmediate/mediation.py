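"""Two-step MR mediation: total effect, step effects, delta-method inference.

Notation follows the standard product-of-coefficients decomposition:

* ``beta_c`` — total effect of the exposure on the outcome (univariable MR);
* ``beta_a`` — effect of the exposure on the mediator (univariable MR);
* ``beta_b`` — effect of the mediator on the outcome adjusted for the
  exposure (multivariable MR, mediator coefficient);
* indirect (mediation) effect = ``beta_a * beta_b`` with delta-method SE
  ``sqrt(beta_b^2 se_a^2 + beta_a^2 se_b^2)`` and Sobel normal test;
* proportion mediated = 100 * indirect / total, with a delta-method ratio
  CI assuming independence of the two estimates ("delta-ratio").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm

from .exceptions import EmptyInstrumentError, UndefinedRatioError
from .mr_core import HeterogeneityResult, MREstimate, Z95, cochran_q, egger, ivw
from .mvmr import MVMREstimate, mvmr_egger, mvmr_ivw, qhet
from .pipeline import MethodChoice, MRSettings, select_mvmr_method, select_univariable_method
from .sumstats import (
    ExclusionReport,
    HarmonizedSet,
    VariantAssociation,
    apply_exclusions,
    f_statistics,
    harmonize_multi,
    harmonize_pair,
    select_instruments,
)


@dataclass(frozen=True)
class UnivariableResult:
    """A univariable MR fit plus the diagnostics that selected its method."""

    estimate: MREstimate
    choice: MethodChoice
    heterogeneity: HeterogeneityResult | None
    pleiotropy: object | None
    harmonized: HarmonizedSet
    report: ExclusionReport
    f_mean: float


@dataclass(frozen=True)
class MVStepResult:
    """The multivariable step: mediator effect adjusted for the exposure."""

    estimate: MVMREstimate
    choice: MethodChoice
    harmonized: HarmonizedSet
    beta_b: float
    se_b: float
    beta_direct: float
    se_direct: float


@dataclass(frozen=True)
class MediationEffect:
    mediation: float
    se: float
    ci_low: float
    ci_high: float
    sobel_p: float


@dataclass(frozen=True)
class ProportionMediated:
    proportion: float
    se: float
    ci_low: float
    ci_high: float
    exceeds_total: bool


@dataclass(frozen=True)
class MediationResult:
    """Everything a two-step mediation analysis produces for one triple."""

    exposure: str
    mediator: str
    outcome: str
    beta_c: float
    se_c: float
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    mediation: float
    mediation_se: float
    mediation_ci: tuple[float, float]
    sobel_p: float
    proportion: float
    proportion_ci: tuple[float, float]
    methods: dict[str, str]

    def to_row(self) -> dict:
        def ci(lo, hi):
            return f"({lo:.3f}, {hi:.3f})"

        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "beta_c": self.beta_c,
            "beta_c_ci": ci(self.beta_c - Z95 * self.se_c, self.beta_c + Z95 * self.se_c),
            "beta_a": self.beta_a,
            "beta_a_ci": ci(self.beta_a - Z95 * self.se_a, self.beta_a + Z95 * self.se_a),
            "beta_b": self.beta_b,
            "beta_b_ci": ci(self.beta_b - Z95 * self.se_b, self.beta_b + Z95 * self.se_b),
            "mediation": self.mediation,
            "mediation_ci": ci(*self.mediation_ci),
            "sobel_p": self.sobel_p,
            "proportion_pct": self.proportion,
            "proportion_ci": ci(*self.proportion_ci),
            "method_total": self.methods.get("total", ""),
            "method_step1": self.methods.get("step1", ""),
            "method_step2": self.methods.get("step2", ""),
        }


def analyze_pair(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    settings: MRSettings | None = None,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> UnivariableResult:
    """Instrument selection, exclusions, harmonisation and the decision-tree
    univariable estimate for one exposure-outcome pair."""
    settings = settings or MRSettings()
    ivs = select_instruments(
        exposure,
        p_threshold=settings.p_threshold,
        ld=settings.ld,
        r2_max=settings.effective_r2_max,
        window_bp=settings.effective_window_bp,
    )
    outcome_ids = {a.snp_id for a in outcome}
    retained, report = apply_exclusions(
        ivs, settings.blacklist, outcome_ids, settings.eaf_band
    )
    if not retained:
        raise EmptyInstrumentError(
            f"{exposure_name}->{outcome_name}: no instrument survived exclusions"
        )
    h = harmonize_pair(retained, outcome, settings.eaf_band, exposure_name)
    _, f_mean = f_statistics(h)
    n = h.n_snp
    het = cochran_q(h, ivw(h, "fixed").beta) if n >= 2 else None
    est_egger, pleio = egger(h) if n >= 3 else (None, None)
    choice = select_univariable_method(pleio, het)
    if choice.chosen == "EGGER":
        est = est_egger
    elif choice.chosen == "IVW_RANDOM":
        est = ivw(h, "random")
    else:
        est = ivw(h, "fixed")
    return UnivariableResult(
        estimate=est,
        choice=choice,
        heterogeneity=het,
        pleiotropy=pleio,
        harmonized=h,
        report=report,
        f_mean=f_mean,
    )


def total_effect(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    settings: MRSettings | None = None,
    **names,
) -> UnivariableResult:
    """beta_c: the exposure's total effect on the outcome."""
    return analyze_pair(exposure, outcome, settings, **names)


def step1_effect(
    exposure: Sequence[VariantAssociation],
    mediator: Sequence[VariantAssociation],
    settings: MRSettings | None = None,
    **names,
) -> UnivariableResult:
    """beta_a: the exposure's effect on the mediator (univariable MR)."""
    return analyze_pair(exposure, mediator, settings, **names)


def step2_effect(
    exposure: Sequence[VariantAssociation],
    mediator: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    settings: MRSettings | None = None,
    exposure_name: str = "exposure",
    mediator_name: str = "mediator",
    outcome_name: str = "outcome",
) -> MVStepResult:
    """beta_b: the mediator's effect on the outcome adjusted for the exposure.

    Instruments are the union of the univariable IV sets for exposure and
    mediator, harmonised across all three studies; the MVMR method follows
    the multivariable decision tree.
    """
    settings = settings or MRSettings()
    kw = dict(
        p_threshold=settings.p_threshold,
        ld=settings.ld,
        r2_max=settings.effective_r2_max,
        window_bp=settings.effective_window_bp,
    )
    iv_x = [a for a in select_instruments(exposure, **kw) if a.snp_id not in settings.blacklist]
    iv_m = [a for a in select_instruments(mediator, **kw) if a.snp_id not in settings.blacklist]
    h = harmonize_multi(
        exposure,
        mediator,
        outcome,
        (iv_x, iv_m),
        ld=settings.ld,
        r2_max=settings.effective_r2_max,
        eaf_ambiguity_band=settings.eaf_band,
        exposure_names=(exposure_name, mediator_name),
    )
    base = mvmr_ivw(h)
    het = HeterogeneityResult(
        Q=base.q,
        df=base.df,
        pval=float(chi2.sf(base.q, base.df)) if base.df > 0 else 1.0,
        i2=max(0.0, (base.q - base.df) / base.q) if base.q > 0 else 0.0,
    )
    mv_e = mvmr_egger(h) if h.n_snp > h.k + 1 else None
    choice = select_mvmr_method(mv_e.intercept_p if mv_e is not None else None, het)
    if choice.chosen == "MV_EGGER":
        est = mv_e
    elif choice.chosen == "QHET":
        est = qhet(h, n_boot=settings.qhet_boot, seed=settings.seed)
    else:
        est = base
    beta_b, se_b = est.beta_for(mediator_name)
    beta_d, se_d = est.beta_for(exposure_name)
    return MVStepResult(
        estimate=est,
        choice=choice,
        harmonized=h,
        beta_b=beta_b,
        se_b=se_b,
        beta_direct=beta_d,
        se_direct=se_d,
    )


def mediation_effect(beta_a: float, se_a: float, beta_b: float, se_b: float) -> MediationEffect:
    """Indirect effect ``beta_a * beta_b`` with delta-method SE and Sobel test.

    SE = sqrt(beta_b^2 se_a^2 + beta_a^2 se_b^2); the CI is Wald-type and
    the Sobel p is the two-sided normal tail of mediation / SE.
    """
    if se_a <= 0 or se_b <= 0:
        raise UndefinedRatioError("mediation_effect requires positive SEs")
    med = beta_a * beta_b
    se = float(np.sqrt(beta_b**2 * se_a**2 + beta_a**2 * se_b**2))
    if se == 0:
        sobel_p = 1.0 if med == 0 else 0.0
    else:
        sobel_p = float(min(1.0, 2.0 * norm.sf(abs(med / se))))
    return MediationEffect(
        mediation=float(med),
        se=se,
        ci_low=float(med - Z95 * se),
        ci_high=float(med + Z95 * se),
        sobel_p=sobel_p,
    )


def proportion_mediated(
    mediation: float, mediation_se: float, beta_c: float, se_c: float
) -> ProportionMediated:
    """Proportion mediated, in percent, with a delta-method ratio CI.

    Independence of the indirect and total estimates is assumed
    ("delta-ratio"). Proportions outside [0, 100] are allowed but flagged.
    """
    if beta_c == 0:
        raise UndefinedRatioError("proportion mediated undefined for a zero total effect")
    prop = 100.0 * mediation / beta_c
    if mediation == 0:
        se_prop = 100.0 * mediation_se / abs(beta_c)
    else:
        se_prop = abs(prop) * float(
            np.sqrt(mediation_se**2 / mediation**2 + se_c**2 / beta_c**2)
        )
    return ProportionMediated(
        proportion=float(prop),
        se=float(se_prop),
        ci_low=float(prop - Z95 * se_prop),
        ci_high=float(prop + Z95 * se_prop),
        exceeds_total=abs(prop) > 100.0,
    )


def run_mediation(
    exposure: Sequence[VariantAssociation],
    mediator: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    settings: MRSettings | None = None,
    exposure_name: str = "exposure",
    mediator_name: str = "mediator",
    outcome_name: str = "outcome",
) -> MediationResult:
    """Compose the full two-step mediation analysis for one triple."""
    settings = settings or MRSettings()
    steps = {}
    try:
        tot = total_effect(
            exposure, outcome, settings, exposure_name=exposure_name, outcome_name=outcome_name
        )
        steps["total"] = tot.estimate.method
    except Exception as exc:
        raise type(exc)(f"total-effect step failed: {exc}") from exc
    try:
        s1 = step1_effect(
            exposure, mediator, settings, exposure_name=exposure_name, outcome_name=mediator_name
        )
        steps["step1"] = s1.estimate.method
    except Exception as exc:
        raise type(exc)(f"step-1 (exposure->mediator) failed: {exc}") from exc
    try:
        s2 = step2_effect(
            exposure,
            mediator,
            outcome,
            settings,
            exposure_name=exposure_name,
            mediator_name=mediator_name,
            outcome_name=outcome_name,
        )
        steps["step2"] = s2.estimate.method
    except Exception as exc:
        raise type(exc)(f"step-2 (multivariable) failed: {exc}") from exc
    med = mediation_effect(s1.estimate.beta, s1.estimate.se, s2.beta_b, s2.se_b)
    prop = proportion_mediated(med.mediation, med.se, tot.estimate.beta, tot.estimate.se)
    return MediationResult(
        exposure=exposure_name,
        mediator=mediator_name,
        outcome=outcome_name,
        beta_c=tot.estimate.beta,
        se_c=tot.estimate.se,
        beta_a=s1.estimate.beta,
        se_a=s1.estimate.se,
        beta_b=s2.beta_b,
        se_b=s2.se_b,
        mediation=med.mediation,
        mediation_se=med.se,
        mediation_ci=(med.ci_low, med.ci_high),
        sobel_p=med.sobel_p,
        proportion=prop.proportion,
        proportion_ci=(prop.ci_low, prop.ci_high),
        methods=steps,
    )
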