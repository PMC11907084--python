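"""Synthetic two-sample GWAS summary statistics under a mediation DAG.

The generator emulates the data a two-step MR mediation study consumes:
three independent GWAS studies (exposure X, mediator M, outcome Y) whose
per-SNP effects derive from the causal chain

    X --theta_direct--> Y,   X --beta_a--> M --beta_b--> Y

so the total exposure effect is ``theta_direct + beta_a * beta_b``.
Two families of independent instruments are generated: ``n_snp`` exposure
instruments (true effects ``xi`` on X, hence ``beta_a * xi`` on M and
``theta_total * xi`` on Y) and ``n_snp_mediator`` mediator-specific
instruments (effects ``xi_m`` on M, ``beta_b * xi_m`` on Y, none on X) —
without the latter the mediator coefficient in multivariable MR is not
identified. Per-study standard errors follow the GWAS formula
``1 / sqrt(2 * maf * (1 - maf) * n)`` and observed effects are the true
effects plus independent study-specific noise (no sample overlap).

Invalid instruments (horizontal pleiotropy) receive extra direct effects:
``alpha`` on the mediator (exposure instruments only; it propagates to the
outcome through the mediator) and ``gamma`` on the outcome. Balanced
pleiotropy centres these at zero, directional at ``pleiotropy_mean``;
directional draws are oriented to the trait-increasing allele so the bias
survives the arbitrary effect-allele orientation of each SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .exceptions import ConfigurationError, EmptyInstrumentError
from .sumstats import VariantAssociation, write_sumstats

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of a synthetic mediation dataset.

    Defaults emulate a consortium-scale triple: exposure and mediator GWAS
    of a few hundred thousand participants, a binary outcome GWAS, an
    exposure whose effect on the outcome runs mostly directly with a small
    mediated component, and per-SNP instrument strength around F = 30.
    """

    n_snp: int = 100
    n_snp_mediator: int = 100
    n_exposure: int = 237_627
    n_mediator: int = 173_005
    n_outcome: int = 184_305
    maf_range: tuple[float, float] = (0.05, 0.5)
    theta_direct: float = 0.346
    beta_a_true: float = 0.73
    beta_b_true: float = 0.05
    pleiotropy_mode: str = "NONE"  # NONE | BALANCED | DIRECTIONAL
    pleiotropy_sd: float = 0.002
    pleiotropy_mean: float = 0.002
    prop_invalid: float = 0.3
    palindrome_fraction: float = 0.15
    selection_p: float | None = None
    mean_f_target: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp <= 0 or self.n_snp_mediator < 0:
            raise ConfigurationError("SNP counts must be positive")
        if min(self.n_exposure, self.n_mediator, self.n_outcome) <= 0:
            raise ConfigurationError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie inside (0, 0.5], got {self.maf_range}")
        if self.pleiotropy_mode not in ("NONE", "BALANCED", "DIRECTIONAL"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        for name in ("prop_invalid", "palindrome_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.mean_f_target <= 1.0:
            raise ConfigurationError("mean_f_target must exceed 1")
        if self.selection_p is not None and not (0.0 < self.selection_p <= 1.0):
            raise ConfigurationError("selection_p must be in (0, 1]")

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name}={list(v) if isinstance(v, tuple) else v}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    theta_total: float
    proportion_true: float
    xi: np.ndarray
    xi_m: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    invalid: np.ndarray
    seed: int
    config: SimulationConfig

    def to_text(self) -> str:
        return (
            f"theta_total={self.theta_total}\n"
            f"proportion_true={self.proportion_true}\n"
            f"theta_direct={self.config.theta_direct}\n"
            f"beta_a_true={self.config.beta_a_true}\n"
            f"beta_b_true={self.config.beta_b_true}\n"
            f"n_invalid={int(self.invalid.sum())}\n"
            f"seed={self.seed}\n"
        )


@dataclass(frozen=True)
class SimulatedStudies:
    """Three summary-statistics tables plus the generating truth."""

    exposure: list[VariantAssociation]
    mediator: list[VariantAssociation]
    outcome: list[VariantAssociation]
    truth: SimulationTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sumstats(self.exposure, outdir / "exposure.tsv")
        write_sumstats(self.mediator, outdir / "mediator.tsv")
        write_sumstats(self.outcome, outdir / "outcome.tsv")
        (outdir / "truth.txt").write_text(self.truth.to_text())
        (outdir / "config.txt").write_text(self.truth.config.to_text())


def _se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pval(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(beta / se)
    return np.maximum(2.0 * norm.sf(z), 5e-324)


def simulate_mediation_dag(cfg: SimulationConfig) -> SimulatedStudies:
    """Draw one synthetic dataset; fully deterministic given ``cfg.seed``.

    Instruments sit on alternating chromosomes 20 Mb apart so that distance
    clumping never merges them (instruments are simulated LD-free).
    """
    rng = np.random.default_rng(cfg.seed)
    n_tot = cfg.n_snp + cfg.n_snp_mediator
    maf = rng.uniform(*cfg.maf_range, size=n_tot)
    sex = _se(maf, cfg.n_exposure)
    sem = _se(maf, cfg.n_mediator)
    sey = _se(maf, cfg.n_outcome)

    # true instrument effects scaled so E[(b/se)^2] = mean_f_target per SNP
    scale = np.sqrt(cfg.mean_f_target - 1.0)
    is_exp = np.arange(n_tot) < cfg.n_snp
    xi = np.where(is_exp, sex * scale * rng.standard_normal(n_tot), 0.0)
    xi_m = np.where(~is_exp, sem * scale * rng.standard_normal(n_tot), 0.0)

    invalid = np.zeros(n_tot, dtype=bool)
    alpha = np.zeros(n_tot)
    gamma = np.zeros(n_tot)
    if cfg.pleiotropy_mode != "NONE" and cfg.prop_invalid > 0:
        invalid = rng.random(n_tot) < cfg.prop_invalid
        mean = 0.0 if cfg.pleiotropy_mode == "BALANCED" else cfg.pleiotropy_mean
        # directional pleiotropy is defined relative to the trait-increasing
        # allele: orient the draws by the sign of the instrument's true effect
        orient = np.where(is_exp, np.sign(xi), np.sign(xi_m))
        orient[orient == 0] = 1.0
        alpha = np.where(
            invalid & is_exp,
            orient * (mean + cfg.pleiotropy_sd * rng.standard_normal(n_tot)),
            0.0,
        )
        gamma = np.where(
            invalid, orient * (mean + cfg.pleiotropy_sd * rng.standard_normal(n_tot)), 0.0
        )

    m_true = cfg.beta_a_true * xi + alpha + xi_m
    y_true = cfg.theta_direct * xi + cfg.beta_b_true * m_true + gamma

    bx = xi + sex * rng.standard_normal(n_tot)
    bm = m_true + sem * rng.standard_normal(n_tot)
    by = y_true + sey * rng.standard_normal(n_tot)

    # shared variant annotations across the three studies
    palin = rng.random(n_tot) < cfg.palindrome_fraction
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), n_tot)
    non_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), n_tot)
    flip = rng.random(n_tot) < 0.5
    eaf = np.where(flip, 1.0 - maf, maf)
    chrom = [str(1 + (i % 22)) for i in range(n_tot)]
    pos = [1_000_000 + 20_000_000 * (i // 22) for i in range(n_tot)]
    ids = [f"rs{i + 1:06d}" for i in range(n_tot)]

    def _study(beta: np.ndarray, se: np.ndarray, n_samp: float) -> list[VariantAssociation]:
        pv = _pval(beta, se)
        recs = []
        for i in range(n_tot):
            ea, oa = (_PALINDROMIC_PAIRS[pal_idx[i]] if palin[i]
                      else _NONPALINDROMIC_PAIRS[non_idx[i]])
            recs.append(
                VariantAssociation(
                    snp_id=ids[i],
                    effect_allele=ea,
                    other_allele=oa,
                    beta=float(beta[i]),
                    se=float(se[i]),
                    pval=float(pv[i]),
                    chrom=chrom[i],
                    pos=pos[i],
                    eaf=float(eaf[i]),
                    n=float(n_samp),
                )
            )
        return recs

    exposure = _study(bx, sex, cfg.n_exposure)
    mediator = _study(bm, sem, cfg.n_mediator)
    outcome = _study(by, sey, cfg.n_outcome)
    if cfg.selection_p is not None:
        exposure = [a for a in exposure if a.pval < cfg.selection_p]
        if not exposure:
            raise EmptyInstrumentError(
                "no SNP survives exposure selection; increase effects, F target or sample size"
            )
    theta_total = cfg.theta_direct + cfg.beta_a_true * cfg.beta_b_true
    proportion_true = (
        100.0 * cfg.beta_a_true * cfg.beta_b_true / theta_total if theta_total != 0 else np.nan
    )
    truth = SimulationTruth(
        theta_total=theta_total,
        proportion_true=proportion_true,
        xi=xi[is_exp],
        xi_m=xi_m[~is_exp],
        alpha=alpha,
        gamma=gamma,
        invalid=invalid,
        seed=cfg.seed,
        config=cfg,
    )
    return SimulatedStudies(exposure=exposure, mediator=mediator, outcome=outcome, truth=truth)


def benchmark(
    configs: dict[str, SimulationConfig] | Sequence[tuple[str, SimulationConfig]],
    estimators: Sequence[str] = ("IVW_FIXED", "EGGER"),
    n_reps: int = 100,
    seed: int = 0,
):
    """Monte-Carlo estimator comparison over a grid of generating conditions.

    Each cell repeats simulate -> harmonise -> estimate ``n_reps`` times and
    tabulates mean bias against the true total effect, empirical SE, mean
    model SE, 95% CI coverage and rejection rate at alpha = 0.05. Failures
    are counted per cell and the run continues.
    """
    import pandas as pd
    from dataclasses import replace

    from .mr_core import ESTIMATORS
    from .sumstats import harmonize_pair

    if isinstance(configs, dict):
        configs = list(configs.items())
    unknown = [e for e in estimators if e not in ESTIMATORS]
    if unknown:
        raise ConfigurationError(f"unknown estimators {unknown}")
    ss = np.random.SeedSequence(seed)
    rows = []
    for label, cfg in configs:
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]
        results: dict[str, list] = {e: [] for e in estimators}
        failures = {e: 0 for e in estimators}
        for rep_seed in child_seeds:
            sim = simulate_mediation_dag(replace(cfg, seed=rep_seed))
            try:
                h = harmonize_pair(sim.exposure, sim.outcome)
            except Exception:
                for e in estimators:
                    failures[e] += 1
                continue
            for e in estimators:
                try:
                    results[e].append(ESTIMATORS[e](h))
                except Exception:
                    failures[e] += 1
        theta = cfg.theta_direct + cfg.beta_a_true * cfg.beta_b_true
        for e in estimators:
            ests = results[e]
            if not ests:
                rows.append({"cell": label, "estimator": e, "n_reps": 0, "failures": failures[e]})
                continue
            betas = np.array([r.beta for r in ests])
            ses = np.array([r.se for r in ests])
            cover = np.mean([(r.ci_low <= theta <= r.ci_high) for r in ests])
            reject = np.mean([r.pval < 0.05 for r in ests])
            rows.append(
                {
                    "cell": label,
                    "estimator": e,
                    "n_reps": len(ests),
                    "failures": failures[e],
                    "true_effect": theta,
                    "bias": float(betas.mean() - theta),
                    "empirical_se": float(betas.std(ddof=1)) if len(ests) > 1 else np.nan,
                    "mean_model_se": float(ses.mean()),
                    "coverage": float(cover),
                    "rejection": float(reject),
                }
            )
    return pd.DataFrame(rows)
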