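"""GWAS summary-statistics I/O, instrument selection and allele harmonization.

Two-sample Mendelian randomization works entirely from per-SNP association
records (effect allele, beta, SE, p). This module provides:

* :class:`SnpRecord` / :class:`SummaryStats` — validated containers for one
  trait's summary statistics;
* :func:`read_summary_stats` / :func:`write_summary_stats` — delimited-text
  readers/writers with a configurable column map;
* :func:`select_instruments` — significance filtering, confounder blocklist
  exclusion, and greedy LD clumping (ascending p, r² < threshold within a
  physical window);
* :func:`harmonize` — alignment of outcome effects to the exposure's effect
  allele, with strand-flip resolution and palindromic-SNP exclusion.

Instruments must satisfy the three IV assumptions: relevance (genome-wide
significance), independence (the blocklist stands in for a confounder screen),
and exclusion restriction (probed downstream by the pleiotropy diagnostics).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyHarmonizationError,
    EmptyInputError,
    EmptyInstrumentError,
    FormatError,
)

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default header names for delimited summary-statistics files.
DEFAULT_COLUMNS = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}
_MANDATORY = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "se", "pval")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for binary
    traits, SD units for quantitative ones); ``eaf`` is the effect-allele
    frequency when the source GWAS reports it.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def invalid_reason(self) -> str | None:
        """Return why this record violates the invariants, or None if valid."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not (self.se > 0):
            return "nonpositive_se"
        if not (0 < self.pval <= 1):
            return "pval_out_of_range"
        if self.eaf is not None and not (0 < self.eaf < 1):
            return "eaf_out_of_range"
        return None

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G allele pairs, whose strand cannot be told from alleles."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class SummaryStats:
    """Validated per-SNP association records for one trait."""

    records: list[SnpRecord]
    trait_label: str = ""
    n_total: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            reason = r.invalid_reason()
            if reason is not None:
                raise ValueError(f"invalid record {r.snp_id}: {reason}")
            if r.snp_id in seen:
                raise ValueError(f"duplicate SNP id {r.snp_id}")
            seen.add(r.snp_id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> SnpRecord:
        return self._index[snp_id]

    @property
    def _index(self) -> dict[str, SnpRecord]:
        return {r.snp_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": [r.snp_id for r in self.records],
                "CHR": [r.chrom for r in self.records],
                "POS": [r.pos for r in self.records],
                "EA": [r.effect_allele for r in self.records],
                "OA": [r.other_allele for r in self.records],
                "EAF": [r.eaf for r in self.records],
                "BETA": [r.beta for r in self.records],
                "SE": [r.se for r in self.records],
                "P": [r.pval for r in self.records],
                "N": [r.n for r in self.records],
            }
        )


@dataclass
class ParseReport:
    """Accounting of rows accepted and rejected by the reader."""

    n_read: int = 0
    n_kept: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


@dataclass(frozen=True)
class ClumpConfig:
    """Instrument-selection settings.

    Defaults follow the standard genome-wide pipeline: p < 5e-8 relevance
    threshold and greedy clumping at r² < 0.001 within a 10 000 kb window.
    """

    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    p_threshold: float = 5e-8

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold < 1):
            raise ConfigurationError("r2_threshold must be in (0, 1)")
        if not (self.window_kb > 0):
            raise ConfigurationError("window_kb must be positive")
        if not (0 < self.p_threshold <= 1):
            raise ConfigurationError("p_threshold must be in (0, 1]")


class PairwiseLD:
    """Symmetric pairwise r² lookup; unlisted pairs default to r² = 0."""

    def __init__(self, pairs: dict[frozenset, float] | None = None):
        self._pairs = dict(pairs or {})

    @classmethod
    def read(cls, path) -> "PairwiseLD":
        """Read a three-column delimited file (snp_a, snp_b, r2)."""
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         comment="#", names=["snp_a", "snp_b", "r2"])
        if df.shape[1] < 3:
            raise FormatError("LD table needs three columns: snp_a, snp_b, r2")
        pairs = {
            frozenset((str(a), str(b))): float(r)
            for a, b, r in df.itertuples(index=False)
        }
        return cls(pairs)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((a, b)), 0.0)


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome effect pairs, ready for estimation."""

    snp_ids: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)
    exposure_label: str = ""
    outcome_label: str = ""

    def __post_init__(self) -> None:
        self.bx = np.asarray(self.bx, dtype=float)
        self.sx = np.asarray(self.sx, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        n = len(self.snp_ids)
        if not (self.bx.shape == self.sx.shape == self.by.shape == self.sy.shape == (n,)):
            raise ValueError("bx, sx, by, sy must all have length |snp_ids|")
        if n and (np.any(self.sx <= 0) or np.any(self.sy <= 0)):
            raise ValueError("all standard errors must be positive")
        kept = set(self.snp_ids)
        if any(s in kept for s, _ in self.dropped):
            raise ValueError("a SNP cannot be both kept and dropped")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: np.ndarray) -> "HarmonizedSet":
        """Restrict to a boolean mask or index array over the kept SNPs."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in idx],
            bx=self.bx[idx], sx=self.sx[idx],
            by=self.by[idx], sy=self.sy[idx],
            dropped=list(self.dropped),
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp": self.snp_ids, "bx": self.bx, "sx": self.sx,
             "by": self.by, "sy": self.sy}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_drop_log(self, path) -> None:
        pd.DataFrame(self.dropped, columns=["snp", "reason"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path, exposure_label: str = "",
                 outcome_label: str = "") -> "HarmonizedSet":
        df = pd.read_csv(path, sep="\t")
        missing = {"snp", "bx", "sx", "by", "sy"} - set(df.columns)
        if missing:
            raise FormatError(f"harmonized TSV missing columns: {sorted(missing)}")
        return cls(
            snp_ids=[str(s) for s in df["snp"]],
            bx=df["bx"].to_numpy(), sx=df["sx"].to_numpy(),
            by=df["by"].to_numpy(), sy=df["sy"].to_numpy(),
            exposure_label=exposure_label, outcome_label=outcome_label,
        )


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    trait_label: str = "",
    n_total: int | None = None,
) -> tuple[SummaryStats, ParseReport]:
    """Read delimited summary statistics into a validated :class:`SummaryStats`.

    ``column_map`` maps field names (``snp_id``, ``chrom``, ``pos``,
    ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``,
    ``n``) to header names in the file; unspecified fields use
    :data:`DEFAULT_COLUMNS`. Rows violating the record invariants are dropped
    and accounted for in the returned :class:`ParseReport`; a duplicated rsID
    keeps the first occurrence.
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(column_map or {})
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise EmptyInputError(f"{path}: file is empty")
    sep = "\t" if "\t" in first else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    missing = [cols[f] for f in _MANDATORY if cols[f] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")

    has_eaf = cols["eaf"] in df.columns
    has_n = cols["n"] in df.columns
    report = ParseReport(n_read=len(df))
    records: list[SnpRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        snp_id = str(d[cols["snp_id"]])
        try:
            eaf = float(d[cols["eaf"]]) if has_eaf and pd.notna(d[cols["eaf"]]) else None
            n = int(d[cols["n"]]) if has_n and pd.notna(d[cols["n"]]) else None
            rec = SnpRecord(
                snp_id=snp_id,
                chrom=str(d[cols["chrom"]]),
                pos=int(d[cols["pos"]]),
                effect_allele=str(d[cols["effect_allele"]]).upper(),
                other_allele=str(d[cols["other_allele"]]).upper(),
                beta=float(d[cols["beta"]]),
                se=float(d[cols["se"]]),
                pval=float(d[cols["pval"]]),
                eaf=eaf,
                n=n,
            )
        except (TypeError, ValueError):
            report.rejections.append((snp_id, "unparseable"))
            continue
        if snp_id in seen:
            report.rejections.append((snp_id, "duplicate"))
            continue
        reason = rec.invalid_reason()
        if reason is not None:
            report.rejections.append((snp_id, reason))
            continue
        seen.add(snp_id)
        records.append(rec)
    report.n_kept = len(records)
    if not records:
        raise EmptyInputError(f"{path}: no valid rows after filtering")
    return SummaryStats(records, trait_label=trait_label, n_total=n_total), report


def write_summary_stats(stats: SummaryStats, path, sep: str = "\t") -> None:
    """Write a :class:`SummaryStats` in the default delimited layout."""
    stats.to_frame().to_csv(path, sep=sep, index=False)


def read_blocklist(path) -> frozenset[str]:
    """Read a one-SNP-per-line blocklist (confounder-associated variants)."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh
                         if line.strip() and not line.startswith("#"))


# ---------------------------------------------------------------------------
# Instrument selection (significance filter + greedy LD clumping)
# ---------------------------------------------------------------------------

def select_instruments(
    stats: SummaryStats,
    cfg: ClumpConfig | None = None,
    ld: PairwiseLD | None = None,
    blocklist: frozenset[str] = frozenset(),
) -> SummaryStats:
    """Select approximately independent genome-wide-significant instruments.

    SNPs with p below ``cfg.p_threshold`` and not on the confounder blocklist
    are clumped greedily: iterating in ascending p-value order (ties broken by
    snp_id), a SNP is kept unless it has r² ≥ ``cfg.r2_threshold`` with an
    already-kept SNP on the same chromosome within ``cfg.window_kb``. With no
    LD information the instruments are assumed independent (a warning is
    emitted), which matches clumping against an all-zero r² table.
    """
    if len(stats) == 0:
        raise EmptyInputError("no summary statistics to select from")
    cfg = cfg or ClumpConfig()
    candidates = [r for r in stats.records
                  if r.pval < cfg.p_threshold and r.snp_id not in blocklist]
    if not candidates:
        raise EmptyInstrumentError(
            f"{stats.trait_label or 'trait'}: no SNP passes p < {cfg.p_threshold:g}"
        )
    if ld is None:
        warnings.warn(
            "no LD table supplied; assuming instruments are independent",
            stacklevel=2,
        )
        ld = PairwiseLD()

    candidates.sort(key=lambda r: (r.pval, r.snp_id))
    window_bp = cfg.window_kb * 1000.0
    kept: list[SnpRecord] = []
    for rec in candidates:
        linked = any(
            k.chrom == rec.chrom
            and abs(k.pos - rec.pos) <= window_bp
            and ld.r2(k.snp_id, rec.snp_id) >= cfg.r2_threshold
            for k in kept
        )
        if not linked:
            kept.append(rec)
    logger.info(
        "%s: %d/%d significant SNPs kept after clumping",
        stats.trait_label or "trait", len(kept), len(candidates),
    )
    return SummaryStats(kept, trait_label=stats.trait_label, n_total=stats.n_total)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _orient(exp: SnpRecord, out: SnpRecord) -> str:
    """Classify the outcome record's allele orientation relative to exposure.

    Returns one of "same", "swap" (outcome effect allele is the exposure's
    other allele: negate the outcome beta) or "mismatch". Strand flips
    (complemented alleles) resolve to the same two cases for non-palindromic
    SNPs.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    pairs_same = {(ea, oa), (_COMPLEMENT[ea], _COMPLEMENT[oa])}
    pairs_swap = {(oa, ea), (_COMPLEMENT[oa], _COMPLEMENT[ea])}
    got = (out.effect_allele, out.other_allele)
    if got in pairs_same:
        return "same"
    if got in pairs_swap:
        return "swap"
    return "mismatch"


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    drop_palindromes: bool = True,
    infer_strand_from_eaf: bool = False,
    eaf_ambiguous: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    Matching is by rsID. Same-orientation records are kept as-is; swapped
    records have the outcome beta negated; palindromic (A/T, C/G) pairs are
    dropped by default because their strand cannot be determined from alleles.
    With ``infer_strand_from_eaf`` the strand of a palindromic SNP is inferred
    from allele frequencies when both are outside the ambiguous band
    ``eaf_ambiguous`` (frequencies on the same side of 0.5 mean aligned);
    otherwise the SNP is still dropped. Irreconcilable allele pairs drop with
    reason "mismatch".

    Exposure SNPs absent from the outcome are not part of the shared set; their
    count is logged (no proxy lookup is attempted).
    """
    out_index = outcome._index
    shared = [r for r in exposure.records if r.snp_id in out_index]
    n_missing = len(exposure) - len(shared)
    if n_missing:
        logger.info(
            "%d exposure instrument(s) missing from outcome GWAS were skipped",
            n_missing,
        )
    if not shared:
        raise EmptyHarmonizationError(
            f"no shared SNPs between {exposure.trait_label or 'exposure'} "
            f"and {outcome.trait_label or 'outcome'}"
        )

    snp_ids: list[str] = []
    bx, sx, by, sy = [], [], [], []
    dropped: list[tuple[str, str]] = []
    lo, hi = eaf_ambiguous
    for exp in shared:
        out = out_index[exp.snp_id]
        if exp.is_palindromic:
            if drop_palindromes:
                keep_sign = None
                if (infer_strand_from_eaf and exp.eaf is not None
                        and out.eaf is not None):
                    # Map the outcome effect allele onto exposure labels
                    # (complement is identity within a palindromic pair).
                    if out.effect_allele in (exp.effect_allele,
                                             _COMPLEMENT[exp.effect_allele]):
                        f_out = out.eaf
                    else:
                        f_out = 1.0 - out.eaf
                    unambiguous = not (lo <= exp.eaf <= hi) and not (lo <= f_out <= hi)
                    if unambiguous:
                        keep_sign = 1.0 if (exp.eaf < 0.5) == (f_out < 0.5) else -1.0
                if keep_sign is None:
                    dropped.append((exp.snp_id, "palindrome"))
                    continue
            else:
                orient = _orient(exp, out)
                if orient == "mismatch":
                    dropped.append((exp.snp_id, "mismatch"))
                    continue
                keep_sign = 1.0 if orient == "same" else -1.0
        else:
            orient = _orient(exp, out)
            if orient == "mismatch":
                dropped.append((exp.snp_id, "mismatch"))
                continue
            keep_sign = 1.0 if orient == "same" else -1.0
        snp_ids.append(exp.snp_id)
        bx.append(exp.beta)
        sx.append(exp.se)
        by.append(keep_sign * out.beta)
        sy.append(out.se)

    if not snp_ids:
        raise EmptyHarmonizationError(
            f"zero SNPs survived harmonization "
            f"({len(dropped)} dropped: "
            f"{dict(pd.Series([r for _, r in dropped]).value_counts())})"
        )
    return HarmonizedSet(
        snp_ids=snp_ids,
        bx=np.array(bx), sx=np.array(sx),
        by=np.array(by), sy=np.array(sy),
        dropped=dropped,
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
    )
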