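"""Parent–offspring mosaic transmission cases: parsing, validation, scoring.

This module handles the literature-derived case table of intergenerational
SMC/SV transmissions in which the offspring is mosaic.  Each row pairs an
offspring mosaic ratio (abnormal metaphases / metaphases scored) with the
parental carrier status — either a constitutional (100%) carrier, a mosaic
fraction, a fraction range, or "mosaic, proportion not recorded".  The key
summary statistic is the retention fraction: the share of usable
parent–offspring pairs in which the offspring ratio is lower than, or
comparable to, the parental ratio.

Karyotype strings are treated as opaque clone labels with bracketed cell
counts (ISCN mosaic notation ``karyotype[n]/karyotype[m]``); no cytogenetic
interpretation is attempted.
"""

from __future__ import annotations

import csv
import enum
import io
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "CaseTableError",
    "RatioKind",
    "RatioValue",
    "MosaicObservation",
    "Origin",
    "TransmissionCase",
    "TransmissionClass",
    "RetentionSummary",
    "parse_ratio_cell",
    "parse_case_table",
    "load_reference_table",
    "cases_to_csv",
    "parse_iscn_mosaic",
    "ratio_from_counts",
    "effective_ratio",
    "classify_transmission",
    "retention_summary",
]

# Slack for float comparisons of ratios expressed at percent precision.
# 0.80 - 0.70 > 0.10 in binary floating point; without slack a pair sitting
# exactly at the comparability tolerance would be misclassified as HIGHER.
_EPS = 1e-9


class CaseTableError(ValueError):
    """Raised for malformed or inconsistent case-table content."""


class RatioKind(enum.Enum):
    POINT = "point"
    RANGE = "range"
    UNRECORDED = "unrecorded"


@dataclass(frozen=True)
class RatioValue:
    """A mosaic ratio as reported: a point value, a range, or unrecorded."""

    kind: RatioKind
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.kind is RatioKind.UNRECORDED:
            if self.low is not None or self.high is not None:
                raise CaseTableError("UNRECORDED ratio must carry no bounds")
            return
        if self.low is None or self.high is None:
            raise CaseTableError(f"{self.kind.name} ratio requires bounds")
        for v in (self.low, self.high):
            if not 0.0 <= v <= 1.0:
                raise CaseTableError(f"ratio bound {v} outside [0, 1]")
        if self.kind is RatioKind.POINT and self.low != self.high:
            raise CaseTableError("POINT ratio must have low == high")
        if self.kind is RatioKind.RANGE and not self.low < self.high:
            raise CaseTableError("RANGE ratio requires low < high")

    @classmethod
    def point(cls, value: float) -> "RatioValue":
        return cls(RatioKind.POINT, value, value)

    @classmethod
    def range(cls, low: float, high: float) -> "RatioValue":
        return cls(RatioKind.RANGE, low, high)

    @classmethod
    def unrecorded(cls) -> "RatioValue":
        return cls(RatioKind.UNRECORDED)


@dataclass(frozen=True)
class MosaicObservation:
    """Clone counts from one karyotyped sample (e.g. 17 abnormal of 30)."""

    sample_label: str
    abnormal_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count <= 0:
            raise CaseTableError("total_count must be positive")
        if not 0 <= self.abnormal_count <= self.total_count:
            raise CaseTableError("abnormal_count must lie in [0, total_count]")

    @property
    def ratio(self) -> float:
        return self.abnormal_count / self.total_count


class Origin(enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    FAMILIAL = "familial"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "Origin":
        try:
            return cls(text.strip().lower())
        except ValueError:
            return cls.UNKNOWN


@dataclass(frozen=True)
class TransmissionCase:
    """One documented parent→offspring SMC/SV transmission with mosaicism."""

    case_id: str
    smc_type: str
    offspring_ratio: RatioValue
    parent_ratio: RatioValue
    origin: Origin
    offspring_phenotype: str = ""
    parent_phenotype: str = ""
    mechanism: str = ""
    source: str = ""


class TransmissionClass(enum.Enum):
    LOWER = "lower"
    COMPARABLE = "comparable"
    HIGHER = "higher"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class RetentionSummary:
    """Counts of usable pairs by direction of the offspring−parent change."""

    n_usable: int
    n_lower: int
    n_comparable: int
    n_higher: int

    def __post_init__(self) -> None:
        if self.n_lower + self.n_comparable + self.n_higher != self.n_usable:
            raise CaseTableError("retention counts must partition n_usable")

    @property
    def lower_or_comparable_fraction(self) -> float:
        return (self.n_lower + self.n_comparable) / self.n_usable

    def to_dict(self) -> dict:
        return {
            "n_usable": self.n_usable,
            "n_lower": self.n_lower,
            "n_comparable": self.n_comparable,
            "n_higher": self.n_higher,
            "lower_or_comparable_fraction": self.lower_or_comparable_fraction,
        }


# Percent cells appear as "75%", "42.5%", "100%", "90%–97%", "4%–10% Mosaic",
# "90% Mosaic", or a phrase containing "not recorded".  Ranges accept the
# en dash, em dash, or hyphen.
_RANGE_RE = re.compile(r"(\d+(?:\.\d+)?)\s*%\s*[–—-]\s*(\d+(?:\.\d+)?)\s*%")
_POINT_RE = re.compile(r"(\d+(?:\.\d+)?)\s*%")


def parse_ratio_cell(cell: str, *, row: object = "?", column: str = "?") -> RatioValue:
    """Parse one ratio cell of the case table into a :class:`RatioValue`.

    Raises :class:`CaseTableError` naming the offending row and column when
    the cell contains neither a percentage nor a "not recorded" phrase.
    """
    text = cell.strip()
    if "not recorded" in text.lower():
        return RatioValue.unrecorded()
    m = _RANGE_RE.search(text)
    if m:
        lo, hi = float(m.group(1)) / 100.0, float(m.group(2)) / 100.0
        try:
            return RatioValue.range(lo, hi)
        except CaseTableError as exc:
            raise CaseTableError(f"row {row}, column {column!r}: {exc}") from exc
    m = _POINT_RE.search(text)
    if m:
        value = float(m.group(1)) / 100.0
        try:
            return RatioValue.point(value)
        except CaseTableError as exc:
            raise CaseTableError(f"row {row}, column {column!r}: {exc}") from exc
    raise CaseTableError(
        f"row {row}, column {column!r}: cannot parse ratio cell {cell!r}"
    )


_COLUMNS = (
    "case_id",
    "smc_type",
    "offspring_ratio",
    "offspring_phenotype",
    "parent_ratio",
    "parent_phenotype",
    "origin",
    "mechanism",
    "source",
)


def parse_case_table(table_text: str) -> list[TransmissionCase]:
    """Parse CSV case-table content into :class:`TransmissionCase` records.

    The header row is required.  Percent strings are converted to fractions;
    ranges are preserved as RANGE values and unrecorded parental ratios as
    UNRECORDED.  Duplicate case ids raise :class:`CaseTableError`.
    """
    reader = csv.DictReader(io.StringIO(table_text))
    if reader.fieldnames is None:
        raise CaseTableError("empty case table")
    missing = set(_COLUMNS) - set(reader.fieldnames)
    if missing:
        raise CaseTableError(f"case table missing columns: {sorted(missing)}")

    cases: list[TransmissionCase] = []
    seen: set[str] = set()
    for i, rec in enumerate(reader, start=1):
        case_id = rec["case_id"].strip()
        if case_id in seen:
            raise CaseTableError(f"duplicate case_id {case_id!r}")
        seen.add(case_id)
        cases.append(
            TransmissionCase(
                case_id=case_id,
                smc_type=rec["smc_type"].strip(),
                offspring_ratio=parse_ratio_cell(
                    rec["offspring_ratio"], row=i, column="offspring_ratio"
                ),
                parent_ratio=parse_ratio_cell(
                    rec["parent_ratio"], row=i, column="parent_ratio"
                ),
                origin=Origin.parse(rec["origin"]),
                offspring_phenotype=rec["offspring_phenotype"].strip(),
                parent_phenotype=rec["parent_phenotype"].strip(),
                mechanism=rec["mechanism"].strip(),
                source=rec["source"].strip(),
            )
        )
    if not cases:
        raise CaseTableError("case table contains no data rows")
    return cases


def load_reference_table() -> list[TransmissionCase]:
    """Load the packaged 34-row literature case table."""
    text = (
        resources.files("shepherdsim.data")
        .joinpath("transmission_cases.csv")
        .read_text(encoding="utf-8")
    )
    return parse_case_table(text)


def _format_ratio(r: RatioValue) -> str:
    def pct(v: float) -> str:
        p = v * 100.0
        return f"{p:g}%"

    if r.kind is RatioKind.UNRECORDED:
        return "Mosaic (proportion not recorded)"
    if r.kind is RatioKind.RANGE:
        return f"{pct(r.low)}–{pct(r.high)}"
    return pct(r.low)


def cases_to_csv(cases: Iterable[TransmissionCase]) -> str:
    """Serialize cases back to the CSV schema accepted by parse_case_table."""
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(_COLUMNS)
    for c in cases:
        writer.writerow(
            [
                c.case_id,
                c.smc_type,
                _format_ratio(c.offspring_ratio),
                c.offspring_phenotype,
                _format_ratio(c.parent_ratio),
                c.parent_phenotype,
                c.origin.value,
                c.mechanism,
                c.source,
            ]
        )
    return out.getvalue()


_CLONE_RE = re.compile(r"^(.+?)\[(-?\d+)\]$")


def parse_iscn_mosaic(karyotype: str) -> list[tuple[str, int]]:
    """Split an ISCN-style mosaic karyotype into (clone, cell count) pairs.

    ``"46,XY,ins(11;?)(p11;?)[17]/46,XY[13]"`` yields two clones with counts
    17 and 13.  Clone designations are opaque; only the bracketed counts are
    interpreted.
    """
    clones: list[tuple[str, int]] = []
    for part in karyotype.split("/"):
        part = part.strip()
        m = _CLONE_RE.match(part)
        if not m:
            raise CaseTableError(
                f"clone {part!r} lacks a bracketed cell count"
            )
        count = int(m.group(2))
        if count <= 0:
            raise CaseTableError(f"clone {part!r} has non-positive cell count")
        clones.append((m.group(1).strip(), count))
    return clones


def ratio_from_counts(abnormal: int, total: int) -> tuple[float, int]:
    """Mosaic ratio from clone counts, plus the half-up-rounded percent.

    Returns ``(abnormal/total, percent)`` with the percent rounded half-up to
    the nearest integer, matching how clinical captions print e.g. 45/99 as
    45% and 17/30 as 57%.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= abnormal <= total:
        raise ValueError("abnormal must lie in [0, total]")
    fraction = abnormal / total
    percent = int(math.floor(fraction * 100.0 + 0.5))
    return fraction, percent


def effective_ratio(r: RatioValue) -> float | None:
    """Reduce a reported ratio to a single scoring value.

    Point values map to themselves, ranges to their midpoint, and unrecorded
    ratios to ``None``.
    """
    if r.kind is RatioKind.UNRECORDED:
        return None
    if r.kind is RatioKind.RANGE:
        return (r.low + r.high) / 2.0
    return r.low


def classify_transmission(
    case: TransmissionCase, tolerance: float = 0.10
) -> TransmissionClass:
    """Compare offspring vs parent effective ratios.

    Let d = offspring − parent.  d < 0 is LOWER, 0 ≤ d ≤ tolerance is
    COMPARABLE, d > tolerance is HIGHER.  Pairs with an unrecorded side are
    UNDETERMINED.  The default tolerance of 10 percentage points is the
    comparability band used for the retention statistic.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    off = effective_ratio(case.offspring_ratio)
    par = effective_ratio(case.parent_ratio)
    if off is None or par is None:
        return TransmissionClass.UNDETERMINED
    d = off - par
    if d < -_EPS:
        return TransmissionClass.LOWER
    if d <= tolerance + _EPS:
        return TransmissionClass.COMPARABLE
    return TransmissionClass.HIGHER


def retention_summary(
    cases: Sequence[TransmissionCase], tolerance: float = 0.10
) -> RetentionSummary:
    """Score every case and tally the retention statistic.

    UNDETERMINED pairs (unrecorded parental proportion) are excluded from
    the usable denominator.
    """
    counts = {
        TransmissionClass.LOWER: 0,
        TransmissionClass.COMPARABLE: 0,
        TransmissionClass.HIGHER: 0,
    }
    for case in cases:
        cls = classify_transmission(case, tolerance)
        if cls is not TransmissionClass.UNDETERMINED:
            counts[cls] += 1
    n_usable = sum(counts.values())
    if n_usable == 0:
        raise CaseTableError("no usable parent–offspring pairs")
    return RetentionSummary(
        n_usable=n_usable,
        n_lower=counts[TransmissionClass.LOWER],
        n_comparable=counts[TransmissionClass.COMPARABLE],
        n_higher=counts[TransmissionClass.HIGHER],
    )
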