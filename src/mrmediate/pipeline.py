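"""Method-selection decision tree, FDR tiering, run settings and the grid runner.

The univariable decision rule: a significant Egger intercept (p < 0.05)
selects MR-Egger; otherwise significant heterogeneity (I-squared > 25% and
Cochran p < 0.05) selects random-effects IVW; otherwise fixed-effect IVW.
The multivariable rule is analogous with MV-Egger / QHET / MV-IVW.

Evidence tiers over a family of tests: q < 0.05 (Benjamini-Hochberg) is
significant; uncorrected p < 0.05 with q >= 0.05 is suggestive; else null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError
from .mr_core import HeterogeneityResult, PleiotropyResult

SIGNIFICANT = "SIGNIFICANT"
SUGGESTIVE = "SUGGESTIVE"
NULL = "NULL"

I2_THRESHOLD = 0.25
ALPHA = 0.05


@dataclass(frozen=True)
class MethodChoice:
    """The decision-tree outcome with an ordered trace of the comparisons."""

    chosen: str
    pleiotropy_p: float | None
    q: float | None
    q_pval: float | None
    i2: float | None
    rationale: tuple[str, ...]


@dataclass(frozen=True)
class EvidenceTier:
    pval: float
    qval: float
    tier: str


@dataclass(frozen=True)
class MRSettings:
    """Knobs shared by every pipeline run.

    ``strict`` switches to the replication clumping mode (r2 0.001 within
    10 Mb instead of 0.01 within 1 Mb at the same p threshold).
    """

    p_threshold: float = 5e-8
    r2_max: float = 0.01
    window_bp: int = 1_000_000
    strict: bool = False
    eaf_band: tuple[float, float] = (0.42, 0.58)
    blacklist: frozenset[str] = frozenset()
    mediation_trigger_p: float = 0.05
    qhet_boot: int = 200
    wm_boot: int = 200
    seed: int = 0
    sensitivity: bool = False
    ld: object | None = None  # optional pandas r2 matrix, never serialised

    @property
    def effective_r2_max(self) -> float:
        return 0.001 if self.strict else self.r2_max

    @property
    def effective_window_bp(self) -> int:
        return 10_000_000 if self.strict else self.window_bp

    def replace(self, **kw) -> "MRSettings":
        return replace(self, **kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "MRSettings":
        """Load settings from YAML/nested or flat key=value plain text."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, val = line.split("=", 1)
                parsed = yaml.safe_load(val.strip())
                if isinstance(parsed, str):
                    try:
                        parsed = float(parsed)  # YAML misses bare forms like 5e-8
                    except ValueError:
                        pass
                data[key.strip()] = parsed
        known = {f for f in cls.__dataclass_fields__ if f != "ld"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown settings {sorted(unknown)}")
        if "blacklist" in data:
            data["blacklist"] = frozenset(data["blacklist"])
        if "eaf_band" in data:
            data["eaf_band"] = tuple(data["eaf_band"])
        return cls(**data)

    def to_text(self) -> str:
        lines = []
        for name in self.__dataclass_fields__:
            if name == "ld":
                continue
            val = getattr(self, name)
            if isinstance(val, frozenset):
                val = sorted(val)
            if isinstance(val, tuple):
                val = list(val)
            lines.append(f"{name}={val}")
        return "\n".join(lines) + "\n"


def select_univariable_method(
    pleiotropy: PleiotropyResult | None, het: HeterogeneityResult | None
) -> MethodChoice:
    """Choose EGGER, IVW_RANDOM or IVW_FIXED from the diagnostics.

    ``pleiotropy=None`` (fewer than 3 SNPs) makes the intercept test
    unavailable and falls through to the IVW branch; ``het=None`` (a single
    SNP) forces fixed-effect IVW.
    """
    trace: list[str] = []
    p_pleio = pleiotropy.pval if pleiotropy is not None else None
    if pleiotropy is None:
        trace.append("egger intercept test unavailable (<3 SNPs); pleiotropy assumed absent")
    else:
        trace.append(
            f"egger intercept p={p_pleio:.4g} {'<' if p_pleio < ALPHA else '>='} {ALPHA}"
        )
        if p_pleio < ALPHA:
            trace.append("directional pleiotropy detected -> MR-Egger")
            return MethodChoice("EGGER", p_pleio, het.Q if het else None,
                                het.pval if het else None, het.i2 if het else None, tuple(trace))
    if het is None:
        trace.append("heterogeneity untestable (<2 SNPs) -> fixed-effect IVW")
        return MethodChoice("IVW_FIXED", p_pleio, None, None, None, tuple(trace))
    trace.append(
        f"I2={het.i2:.3f} {'>' if het.i2 > I2_THRESHOLD else '<='} {I2_THRESHOLD} "
        f"and Q p={het.pval:.4g} {'<' if het.pval < ALPHA else '>='} {ALPHA}"
    )
    if het.i2 > I2_THRESHOLD and het.pval < ALPHA:
        trace.append("significant heterogeneity -> random-effects IVW")
        return MethodChoice("IVW_RANDOM", p_pleio, het.Q, het.pval, het.i2, tuple(trace))
    trace.append("no significant pleiotropy or heterogeneity -> fixed-effect IVW")
    return MethodChoice("IVW_FIXED", p_pleio, het.Q, het.pval, het.i2, tuple(trace))


def select_mvmr_method(
    mv_pleiotropy_p: float | None, het: HeterogeneityResult | None
) -> MethodChoice:
    """Choose MV_EGGER, QHET or MV_IVW from the multivariable diagnostics."""
    trace: list[str] = []
    if mv_pleiotropy_p is None:
        trace.append("multivariable egger intercept test unavailable; pleiotropy assumed absent")
    else:
        trace.append(
            f"mv egger intercept p={mv_pleiotropy_p:.4g} "
            f"{'<' if mv_pleiotropy_p < ALPHA else '>='} {ALPHA}"
        )
        if mv_pleiotropy_p < ALPHA:
            trace.append("multivariable pleiotropy detected -> MV-Egger")
            return MethodChoice("MV_EGGER", mv_pleiotropy_p, het.Q if het else None,
                                het.pval if het else None, het.i2 if het else None, tuple(trace))
    if het is None:
        trace.append("heterogeneity untestable -> multivariable IVW")
        return MethodChoice("MV_IVW", mv_pleiotropy_p, None, None, None, tuple(trace))
    trace.append(
        f"I2={het.i2:.3f} {'>' if het.i2 > I2_THRESHOLD else '<='} {I2_THRESHOLD} "
        f"and Q p={het.pval:.4g} {'<' if het.pval < ALPHA else '>='} {ALPHA}"
    )
    if het.i2 > I2_THRESHOLD and het.pval < ALPHA:
        trace.append("significant heterogeneity -> QHET")
        return MethodChoice("QHET", mv_pleiotropy_p, het.Q, het.pval, het.i2, tuple(trace))
    trace.append("no significant pleiotropy or heterogeneity -> multivariable IVW")
    return MethodChoice("MV_IVW", mv_pleiotropy_p, het.Q, het.pval, het.i2, tuple(trace))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ConfigurationError("p-values must be in (0, 1]")
    return multipletests(p, alpha=ALPHA, method="fdr_bh")[1]


def classify_evidence(pvals: Sequence[float]) -> list[EvidenceTier]:
    """Tier each test jointly over the family: significant / suggestive / null."""
    p = np.asarray(list(pvals), dtype=float)
    q = bh_fdr(p)
    tiers = []
    for pi, qi in zip(p, q):
        if qi < ALPHA:
            tier = SIGNIFICANT
        elif pi < ALPHA:
            tier = SUGGESTIVE
        else:
            tier = NULL
        tiers.append(EvidenceTier(pval=float(pi), qval=float(qi), tier=tier))
    return tiers


@dataclass
class GridResult:
    """Tables produced by a full exposure-by-outcome run."""

    effects: pd.DataFrame
    mediation: pd.DataFrame
    failures: list[tuple[str, str, str]]
    log: list[dict]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.effects.to_csv(outdir / "effects.tsv", sep="\t", index=False, na_rep="NA")
        self.mediation.to_csv(outdir / "mediation.tsv", sep="\t", index=False, na_rep="NA")
        with open(outdir / "run_log.tsv", "w") as fh:
            if self.log:
                keys = list(self.log[0])
                fh.write("\t".join(keys) + "\n")
                for entry in self.log:
                    fh.write("\t".join(str(entry.get(k, "")) for k in keys) + "\n")
        if self.failures:
            with open(outdir / "failures.tsv", "w") as fh:
                fh.write("exposure\toutcome\terror\n")
                for e, o, msg in self.failures:
                    fh.write(f"{e}\t{o}\t{msg}\n")


def run_grid(
    exposures: Mapping[str, Sequence],
    outcomes: Mapping[str, Sequence],
    mediator: Sequence | None = None,
    mediator_name: str = "mediator",
    settings: MRSettings | None = None,
) -> GridResult:
    """Total effects for every exposure-outcome pair with the decision-tree
    method, FDR tiering over the whole family, and full mediation for pairs
    whose total-effect p is below the trigger (when a mediator is given).

    Per-pair failures are recorded and the run continues. The mediation
    Sobel tests form their own FDR family.
    """
    from . import mediation as med_mod  # local import to avoid a cycle

    settings = settings or MRSettings()
    rows: list[dict] = []
    log: list[dict] = []
    failures: list[tuple[str, str, str]] = []
    results: dict[tuple[str, str], object] = {}
    for en, ex in exposures.items():
        for on, out in outcomes.items():
            try:
                res = med_mod.analyze_pair(ex, out, settings, exposure_name=en, outcome_name=on)
            except Exception as exc:  # recorded, run continues
                failures.append((en, on, f"{type(exc).__name__}: {exc}"))
                continue
            est = res.estimate
            results[(en, on)] = res
            rows.append(
                {
                    "exposure": en,
                    "outcome": on,
                    "method": est.method,
                    "n_snp": est.n_snp,
                    "beta": est.beta,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "or": round(est.odds_ratio, 2),
                    "or_ci_low": round(np.exp(est.ci_low), 2),
                    "or_ci_high": round(np.exp(est.ci_high), 2),
                    "pval": est.pval,
                    "egger_intercept_p": res.choice.pleiotropy_p,
                    "Q": res.choice.q,
                    "q_pval": res.choice.q_pval,
                    "i2": res.choice.i2,
                    "mean_f": res.f_mean,
                }
            )
            log.append(
                {
                    "exposure": en,
                    "outcome": on,
                    "chosen_method": est.method,
                    "rationale": " | ".join(res.choice.rationale),
                    "n_input": res.report.n_input,
                    "n_blacklisted": res.report.n_blacklisted,
                    "n_missing_in_outcome": res.report.n_missing_in_outcome,
                    "n_palindromic_dropped": res.report.n_palindromic_dropped,
                    "n_retained": res.report.n_retained,
                }
            )
    effects = pd.DataFrame(rows)
    if len(effects):
        tiers = classify_evidence(effects["pval"].to_numpy())
        effects["qval"] = [t.qval for t in tiers]
        effects["tier"] = [t.tier for t in tiers]

    med_rows: list[dict] = []
    if mediator is not None and len(effects):
        trigger = effects["pval"] < settings.mediation_trigger_p
        for _, row in effects[trigger].iterrows():
            en, on = row["exposure"], row["outcome"]
            try:
                mres = med_mod.run_mediation(
                    exposures[en],
                    mediator,
                    outcomes[on],
                    settings,
                    exposure_name=en,
                    mediator_name=mediator_name,
                    outcome_name=on,
                )
            except Exception as exc:
                failures.append((en, on, f"mediation {type(exc).__name__}: {exc}"))
                continue
            med_rows.append(mres.to_row())
    mediation_df = pd.DataFrame(med_rows)
    if len(mediation_df):
        sobel_tiers = classify_evidence(mediation_df["sobel_p"].to_numpy())
        mediation_df["sobel_q"] = [t.qval for t in sobel_tiers]
        mediation_df["tier"] = [t.tier for t in sobel_tiers]
    return GridResult(effects=effects, mediation=mediation_df, failures=failures, log=log)
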