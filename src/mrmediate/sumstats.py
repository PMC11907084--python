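"""GWAS summary statistics: records, I/O, instrument selection and allele harmonisation.

Conventions used throughout the package:

* effect sizes are per copy of the effect allele — log-odds for binary
  traits, trait units otherwise;
* coordinates are 1-based and distance pruning uses closed windows;
* every estimator consumes a :class:`HarmonizedSet` in which all studies
  are aligned to the exposure study's effect allele. Strand flips are
  resolved by complementing alleles; palindromic (A/T, C/G) variants are
  resolved by allele-frequency concordance or dropped when the frequency
  is ambiguous (inside the configured band) or missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import (
    ConfigurationError,
    EmptyInstrumentError,
    HarmonizationError,
    RowError,
)

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical field -> default column name in tab-separated input
DEFAULT_COLUMNS: Mapping[str, str] = {
    "snp_id": "snp",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

_MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association record in one GWAS."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        ea = str(self.effect_allele).upper()
        oa = str(self.other_allele).upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
            raise RowError(f"{self.snp_id}: alleles must be A/C/G/T, got {ea}/{oa}")
        if ea == oa:
            raise RowError(f"{self.snp_id}: effect and other allele are identical ({ea})")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise RowError(f"{self.snp_id}: standard error must be > 0, got {self.se}")
        if not (0.0 < self.pval <= 1.0):
            raise RowError(f"{self.snp_id}: p-value must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise RowError(f"{self.snp_id}: eaf must be strictly inside (0, 1), got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is label-ambiguous."""
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass
class ExclusionReport:
    """Counts of SNPs dropped by each exclusion rule, in precedence order."""

    n_input: int
    n_blacklisted: int = 0
    n_missing_in_outcome: int = 0
    n_palindromic_dropped: int = 0
    n_outlier_dropped: int = 0

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.n_blacklisted
            - self.n_missing_in_outcome
            - self.n_palindromic_dropped
            - self.n_outlier_dropped
        )

    def to_text(self) -> str:
        lines = [
            f"n_input={self.n_input}",
            f"n_blacklisted={self.n_blacklisted}",
            f"n_missing_in_outcome={self.n_missing_in_outcome}",
            f"n_palindromic_dropped={self.n_palindromic_dropped}",
            f"n_outlier_dropped={self.n_outlier_dropped}",
            f"n_retained={self.n_retained}",
        ]
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


@dataclass
class HarmonizedSet:
    """Per-SNP effects for K exposures and one outcome on a common effect allele.

    ``bx``/``sex`` have shape ``(n_snp, K)``; ``by``/``sey`` shape ``(n_snp,)``.
    ``provenance_flags`` records the harmonisation action per retained SNP and
    ``dropped`` the reason per discarded SNP.
    """

    snp_ids: list[str]
    exposure_names: list[str]
    bx: np.ndarray
    sex: np.ndarray
    by: np.ndarray
    sey: np.ndarray
    effect_alleles: list[str] = field(default_factory=list)
    other_alleles: list[str] = field(default_factory=list)
    eaf: np.ndarray | None = None
    provenance_flags: dict[str, str] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        self.sex = np.atleast_2d(np.asarray(self.sex, dtype=float))
        if self.bx.shape[0] == 1 and len(self.snp_ids) != 1:
            self.bx = self.bx.T
            self.sex = self.sex.T
        self.by = np.asarray(self.by, dtype=float).ravel()
        self.sey = np.asarray(self.sey, dtype=float).ravel()
        n = len(self.snp_ids)
        if n < 1:
            raise HarmonizationError("a HarmonizedSet needs at least one SNP")
        if self.bx.shape != (n, self.k) or self.sex.shape != self.bx.shape:
            raise HarmonizationError(
                f"shape mismatch: bx {self.bx.shape}, sex {self.sex.shape}, n_snp {n}"
            )
        if self.by.shape != (n,) or self.sey.shape != (n,):
            raise HarmonizationError("outcome vectors must match the SNP count")
        if not (self.sex > 0).all() or not (self.sey > 0).all():
            raise HarmonizationError("all standard errors must be > 0")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @property
    def k(self) -> int:
        return len(self.exposure_names)

    @classmethod
    def from_arrays(
        cls,
        bx,
        sex,
        by,
        sey,
        snp_ids: Sequence[str] | None = None,
        exposure_names: Sequence[str] = ("exposure",),
    ) -> "HarmonizedSet":
        """Build a set directly from effect arrays (testing and simulation)."""
        by = np.asarray(by, dtype=float).ravel()
        n = by.shape[0]
        if snp_ids is None:
            snp_ids = [f"rs{i + 1}" for i in range(n)]
        bx = np.asarray(bx, dtype=float)
        if bx.ndim == 1:
            bx = bx[:, None]
        sex = np.asarray(sex, dtype=float)
        if sex.ndim == 1:
            sex = sex[:, None]
        return cls(
            snp_ids=list(snp_ids),
            exposure_names=list(exposure_names),
            bx=bx,
            sex=sex,
            by=by,
            sey=np.asarray(sey, dtype=float).ravel(),
        )

    def univariable(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        if self.k != 1:
            raise ConfigurationError(f"operation requires a single exposure, got K={self.k}")
        return self.bx[:, 0], self.sex[:, 0], self.by, self.sey

    def subset(self, idx) -> "HarmonizedSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        ids = [self.snp_ids[i] for i in idx]
        return HarmonizedSet(
            snp_ids=ids,
            exposure_names=list(self.exposure_names),
            bx=self.bx[idx],
            sex=self.sex[idx],
            by=self.by[idx],
            sey=self.sey[idx],
            effect_alleles=[self.effect_alleles[i] for i in idx] if self.effect_alleles else [],
            other_alleles=[self.other_alleles[i] for i in idx] if self.other_alleles else [],
            eaf=self.eaf[idx] if self.eaf is not None else None,
            provenance_flags={s: self.provenance_flags.get(s, "ok") for s in ids},
            dropped=dict(self.dropped),
        )

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"snp": self.snp_ids}
        if self.effect_alleles:
            data["effect_allele"] = self.effect_alleles
            data["other_allele"] = self.other_alleles
        for j, name in enumerate(self.exposure_names):
            data[f"beta_{name}"] = self.bx[:, j]
            data[f"se_{name}"] = self.sex[:, j]
        data["beta_outcome"] = self.by
        data["se_outcome"] = self.sey
        if self.eaf is not None:
            data["eaf"] = self.eaf
        data["flag"] = [self.provenance_flags.get(s, "ok") for s in self.snp_ids]
        return pd.DataFrame(data)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def _associations(self, beta: np.ndarray, se: np.ndarray) -> list[VariantAssociation]:
        out = []
        for i, snp in enumerate(self.snp_ids):
            z = abs(beta[i] / se[i])
            out.append(
                VariantAssociation(
                    snp_id=snp,
                    effect_allele=self.effect_alleles[i] if self.effect_alleles else "A",
                    other_allele=self.other_alleles[i] if self.other_alleles else "G",
                    beta=float(beta[i]),
                    se=float(se[i]),
                    pval=float(max(2.0 * norm.sf(z), 5e-324)),
                    eaf=float(self.eaf[i]) if self.eaf is not None else None,
                )
            )
        return out

    def exposure_associations(self, k: int = 0) -> list[VariantAssociation]:
        """Rebuild the exposure-study records implied by the aligned set."""
        return self._associations(self.bx[:, k], self.sex[:, k])

    def outcome_associations(self) -> list[VariantAssociation]:
        """Rebuild the outcome-study records implied by the aligned set."""
        return self._associations(self.by, self.sey)


# ---------------------------------------------------------------------------
# I/O


def read_sumstats(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[VariantAssociation]:
    """Read tab-separated summary statistics into association records.

    ``column_map`` remaps canonical field names (see :data:`DEFAULT_COLUMNS`)
    to the file's column names. Unmapped extra columns are ignored (logged).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for fld in _MANDATORY_FIELDS:
        if colmap[fld] not in df.columns:
            raise ConfigurationError(
                f"{path}: mandatory column '{colmap[fld]}' (field '{fld}') not found"
            )
    mapped = set(colmap.values())
    extras = [c for c in df.columns if c not in mapped]
    if extras:
        logger.info("%s: ignoring unmapped columns %s", path, extras)

    def _get(row_i: int, fld: str, cast, optional: bool = False):
        col = colmap[fld]
        if col not in df.columns:
            return None
        raw = df.iloc[row_i][col]
        if raw in ("", "NA", "NaN", "nan", "."):
            if optional:
                return None
            raise RowError(f"{path}: row {row_i}: missing value for '{col}'")
        try:
            return cast(raw)
        except (TypeError, ValueError) as exc:
            raise RowError(f"{path}: row {row_i}: cannot parse '{raw}' in column '{col}'") from exc

    records: list[VariantAssociation] = []
    for i in range(len(df)):
        se = _get(i, "se", float)
        if se is not None and se <= 0:
            raise RowError(f"{path}: row {i}: non-positive standard error {se}")
        try:
            rec = VariantAssociation(
                snp_id=_get(i, "snp_id", str),
                effect_allele=_get(i, "effect_allele", str),
                other_allele=_get(i, "other_allele", str),
                beta=_get(i, "beta", float),
                se=se,
                pval=_get(i, "pval", float),
                chrom=_get(i, "chrom", str, optional=True),
                pos=_get(i, "pos", lambda v: int(float(v)), optional=True),
                eaf=_get(i, "eaf", float, optional=True),
                n=_get(i, "n", float, optional=True),
            )
        except RowError as exc:
            raise RowError(f"{path}: row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_sumstats(assocs: Iterable[VariantAssociation], path: str | Path) -> None:
    """Write records as a tab-separated table in the default column dialect."""
    rows = []
    for a in assocs:
        rows.append(
            {
                "snp": a.snp_id,
                "chr": a.chrom,
                "pos": a.pos,
                "effect_allele": a.effect_allele,
                "other_allele": a.other_allele,
                "eaf": a.eaf,
                "beta": a.beta,
                "se": a.se,
                "pval": a.pval,
                "n": a.n,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square tab-separated r-squared matrix with SNP ids on both axes."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    if list(ld.index) != list(ld.columns):
        raise ConfigurationError(f"{path}: LD matrix row and column ids differ")
    return ld


def read_blacklist(path: str | Path) -> set[str]:
    """Read a confounder-associated SNP blacklist, one id per line."""
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }


# ---------------------------------------------------------------------------
# Instrument selection and exclusion filtering


def _r2(ld: pd.DataFrame, a: str, b: str) -> float:
    try:
        return float(ld.at[a, b])
    except KeyError:
        return 0.0


def select_instruments(
    assocs: Sequence[VariantAssociation],
    p_threshold: float = 5e-8,
    ld: pd.DataFrame | None = None,
    r2_max: float = 0.01,
    window_bp: int = 1_000_000,
) -> list[VariantAssociation]:
    """Greedy p-value clumping of genome-wide-significant SNPs.

    SNPs with ``pval < p_threshold`` are sorted by ascending p (ties broken
    by id, so the result is invariant to input order) and kept unless in LD
    (``r2 >= r2_max``) with an already-kept SNP, or — when no LD matrix is
    given but positions exist — within ``window_bp`` (closed window) of a
    kept SNP on the same chromosome.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ConfigurationError(f"p_threshold must be in (0, 1), got {p_threshold}")
    passed = [a for a in assocs if a.pval < p_threshold]
    if not passed:
        raise EmptyInstrumentError(f"no SNP passes p < {p_threshold:g}")
    kept: list[VariantAssociation] = []
    for a in sorted(passed, key=lambda r: (r.pval, r.snp_id)):
        if ld is not None:
            conflict = any(_r2(ld, a.snp_id, k.snp_id) >= r2_max for k in kept)
        elif a.pos is not None:
            conflict = any(
                k.pos is not None
                and k.chrom == a.chrom
                and abs(k.pos - a.pos) <= window_bp
                for k in kept
            )
        else:
            conflict = False
        if not conflict:
            kept.append(a)
    return kept


def _in_band(eaf: float, band: tuple[float, float]) -> bool:
    return band[0] < eaf < band[1]


def apply_exclusions(
    assocs: Sequence[VariantAssociation],
    blacklist: set[str] | frozenset[str] = frozenset(),
    outcome_ids: set[str] | frozenset[str] = frozenset(),
    eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> tuple[list[VariantAssociation], ExclusionReport]:
    """Drop confounder-blacklisted, outcome-missing and ambiguous palindromic SNPs.

    Precedence is fixed (blacklist, then missing-in-outcome, then palindrome)
    so each SNP is counted exactly once and reports are deterministic.
    Palindromic SNPs are dropped when their effect-allele frequency is
    missing or lies strictly inside the ambiguity band.
    """
    lo, hi = eaf_ambiguity_band
    if not (0.0 < lo < hi < 1.0):
        raise ConfigurationError(f"eaf band must satisfy 0 < lo < hi < 1, got {eaf_ambiguity_band}")
    report = ExclusionReport(n_input=len(assocs))
    retained: list[VariantAssociation] = []
    for a in assocs:
        if a.snp_id in blacklist:
            report.n_blacklisted += 1
        elif a.snp_id not in outcome_ids:
            report.n_missing_in_outcome += 1
        elif a.is_palindromic and (a.eaf is None or _in_band(a.eaf, eaf_ambiguity_band)):
            report.n_palindromic_dropped += 1
        else:
            retained.append(a)
    return retained, report


# ---------------------------------------------------------------------------
# Harmonisation


def _align_record(
    ref: VariantAssociation,
    other: VariantAssociation,
    band: tuple[float, float],
) -> tuple[int | None, str]:
    """Sign to apply to ``other``'s beta so it refers to ``ref``'s effect allele.

    Returns ``(sign, flag)`` or ``(None, reason)`` when the SNP must be dropped.
    """
    ea_r, oa_r = ref.effect_allele, ref.other_allele
    ea, oa = other.effect_allele, other.other_allele
    if ref.is_palindromic:
        if {ea, oa} != {ea_r, oa_r}:
            return None, "incompatible_alleles"
        if ref.eaf is None or other.eaf is None:
            return None, "palindromic_missing_eaf"
        sign_label = 1 if ea == ea_r else -1
        eaf_aligned = other.eaf if sign_label == 1 else 1.0 - other.eaf
        if _in_band(ref.eaf, band) or _in_band(eaf_aligned, band):
            return None, "palindromic_ambiguous"
        # frequency discordance after label alignment implies opposite strands
        if (eaf_aligned < 0.5) == (ref.eaf < 0.5):
            sign = sign_label
        else:
            sign = -sign_label
        return sign, "palindromic_flipped" if sign == -1 else "palindromic"
    if (ea, oa) == (ea_r, oa_r):
        return 1, "ok"
    if (ea, oa) == (oa_r, ea_r):
        return -1, "flipped"
    ea_c, oa_c = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (ea_c, oa_c) == (ea_r, oa_r):
        return 1, "strand_complement"
    if (ea_c, oa_c) == (oa_r, ea_r):
        return -1, "strand_complement_flipped"
    return None, "incompatible_alleles"


def harmonize_pair(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58),
    exposure_name: str = "exposure",
) -> HarmonizedSet:
    """Align one outcome study to the exposure's effect alleles (K = 1)."""
    out_by_id = {a.snp_id: a for a in outcome}
    shared = [a for a in exposure if a.snp_id in out_by_id]
    if not shared:
        raise HarmonizationError("exposure and outcome share no SNPs")
    ids, bx, sex, by, sey, eas, oas, eafs = [], [], [], [], [], [], [], []
    flags: dict[str, str] = {}
    dropped: dict[str, str] = {}
    for x in shared:
        y = out_by_id[x.snp_id]
        sign, flag = _align_record(x, y, eaf_ambiguity_band)
        if sign is None:
            dropped[x.snp_id] = flag
            continue
        ids.append(x.snp_id)
        bx.append(x.beta)
        sex.append(x.se)
        by.append(sign * y.beta)
        sey.append(y.se)
        eas.append(x.effect_allele)
        oas.append(x.other_allele)
        eafs.append(np.nan if x.eaf is None else x.eaf)
        flags[x.snp_id] = flag
    if not ids:
        raise EmptyInstrumentError("all shared SNPs were dropped during harmonisation")
    return HarmonizedSet(
        snp_ids=ids,
        exposure_names=[exposure_name],
        bx=np.asarray(bx)[:, None],
        sex=np.asarray(sex)[:, None],
        by=np.asarray(by),
        sey=np.asarray(sey),
        effect_alleles=eas,
        other_alleles=oas,
        eaf=np.asarray(eafs),
        provenance_flags=flags,
        dropped=dropped,
    )


def harmonize_multi(
    exposure: Sequence[VariantAssociation],
    mediator: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    univariable_ivs: tuple[Sequence[VariantAssociation], Sequence[VariantAssociation]],
    ld: pd.DataFrame | None = None,
    r2_max: float = 0.01,
    eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58),
    exposure_names: tuple[str, str] = ("exposure", "mediator"),
) -> HarmonizedSet:
    """Build the K = 2 set for multivariable MR from two univariable IV lists.

    The instrument set is the deduplicated union of the two lists, re-pruned
    for mutual LD when an LD matrix is given, then aligned across all three
    full studies to the exposure study's effect allele. SNPs missing from
    any study are dropped with a flag.
    """
    seen: set[str] = set()
    union: list[VariantAssociation] = []
    for lst in univariable_ivs:
        for a in lst:
            if a.snp_id not in seen:
                seen.add(a.snp_id)
                union.append(a)
    if not union:
        raise EmptyInstrumentError("the union of instrument lists is empty")
    if ld is not None:
        pruned: list[VariantAssociation] = []
        for a in sorted(union, key=lambda r: (r.pval, r.snp_id)):
            if not any(_r2(ld, a.snp_id, k.snp_id) >= r2_max for k in pruned):
                pruned.append(a)
        union = pruned
    exp_map = {a.snp_id: a for a in exposure}
    med_map = {a.snp_id: a for a in mediator}
    out_map = {a.snp_id: a for a in outcome}

    ids, bx, sex, by, sey, eas, oas = [], [], [], [], [], [], []
    flags: dict[str, str] = {}
    dropped: dict[str, str] = {}
    for iv in union:
        snp = iv.snp_id
        x = exp_map.get(snp)
        m = med_map.get(snp)
        y = out_map.get(snp)
        if x is None or m is None or y is None:
            missing = [
                name
                for name, rec in (("exposure", x), ("mediator", m), ("outcome", y))
                if rec is None
            ]
            dropped[snp] = "missing_in_" + "+".join(missing)
            continue
        sign_m, flag_m = _align_record(x, m, eaf_ambiguity_band)
        if sign_m is None:
            dropped[snp] = f"mediator:{flag_m}"
            continue
        sign_y, flag_y = _align_record(x, y, eaf_ambiguity_band)
        if sign_y is None:
            dropped[snp] = f"outcome:{flag_y}"
            continue
        ids.append(snp)
        bx.append([x.beta, sign_m * m.beta])
        sex.append([x.se, m.se])
        by.append(sign_y * y.beta)
        sey.append(y.se)
        eas.append(x.effect_allele)
        oas.append(x.other_allele)
        flags[snp] = f"mediator:{flag_m};outcome:{flag_y}"
    if not ids:
        raise EmptyInstrumentError("no instrument survived multivariable harmonisation")
    return HarmonizedSet(
        snp_ids=ids,
        exposure_names=list(exposure_names),
        bx=np.asarray(bx),
        sex=np.asarray(sex),
        by=np.asarray(by),
        sey=np.asarray(sey),
        effect_alleles=eas,
        other_alleles=oas,
        provenance_flags=flags,
        dropped=dropped,
    )


def f_statistics(h: HarmonizedSet) -> tuple[np.ndarray, float]:
    """Per-SNP instrument-strength F statistics, ``F_j = (bx_j / se_j)^2``, and their mean."""
    bx, sex, _, _ = h.univariable()
    f = (bx / sex) ** 2
    return f, float(f.mean())
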