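"""Detection rates, means over detected values, ranges and grouped summaries.

Two rules are deliberately distinct and separately applied:

* *detected* means the censoring flag is false — a printed value of 0.0 with
  no "<" marker still counts as a detection;
* *mean over detected* additionally restricts to strictly positive values, so
  a detected-but-zero entry contributes to the detection count but not to the
  mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .data_model import AnalyteSpec, ConcentrationRecord, DataError, convert_units

__all__ = [
    "DetectionCount",
    "ConcentrationRange",
    "GroupSummary",
    "detection_rate",
    "mean_detected",
    "concentration_range",
    "summarize",
    "summary_frame",
]

GroupBy = Sequence[str] | None
_GROUP_FIELDS = {"water_type", "season", "brand"}


def _group_key(record: ConcentrationRecord, group_by: GroupBy) -> tuple[str, ...]:
    if not group_by:
        return ()
    key = []
    for field in group_by:
        if field not in _GROUP_FIELDS:
            raise DataError(f"cannot group by {field!r}; choose from {sorted(_GROUP_FIELDS)}")
        key.append(getattr(record, field))
    return tuple(key)


def _select(records: Iterable[ConcentrationRecord], analyte: str) -> list[ConcentrationRecord]:
    selected = [r for r in records if r.analyte == analyte]
    if not selected:
        raise DataError(f"no records for analyte {analyte!r}")
    return selected


def _grouped(
    records: Iterable[ConcentrationRecord], analyte: str, group_by: GroupBy
) -> dict[tuple[str, ...], list[ConcentrationRecord]]:
    groups: dict[tuple[str, ...], list[ConcentrationRecord]] = {}
    for rec in _select(records, analyte):
        groups.setdefault(_group_key(rec, group_by), []).append(rec)
    return groups


@dataclass(frozen=True)
class DetectionCount:
    n_detected: int
    n_total: int

    @property
    def rate(self) -> float:
        return self.n_detected / self.n_total


@dataclass(frozen=True)
class ConcentrationRange:
    """(min, max) of a group; ``min_censored`` marks a below-detection floor."""

    min: float
    max: float
    min_censored: bool = False

    def __str__(self) -> str:
        lo = f"<{self.min}" if self.min_censored else f"{self.min}"
        return f"{lo}–{self.max}"


@dataclass(frozen=True)
class GroupSummary:
    analyte: str
    group: tuple[str, ...]
    unit: str
    n_total: int
    n_detected: int
    mean_detected: float | None
    min_detected: float | None  # None when the floor is a censoring bound
    range_min: float  # min detected value, or the censoring bound below it
    max_value: float
    min_censored: bool

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_total


def detection_rate(
    records: Iterable[ConcentrationRecord],
    analyte: str,
    group_by: GroupBy = None,
) -> dict[tuple[str, ...], DetectionCount]:
    """Per-group (n_detected, n_total); a record is detected iff not censored."""
    return {
        key: DetectionCount(
            n_detected=sum(1 for r in recs if not r.measurement.censored),
            n_total=len(recs),
        )
        for key, recs in _grouped(records, analyte, group_by).items()
    }


def mean_detected(
    records: Iterable[ConcentrationRecord],
    analyte: str,
    group_by: GroupBy = None,
) -> dict[tuple[str, ...], float | None]:
    """Arithmetic mean over detected, strictly positive values per group.

    ``None`` (never zero) marks a group with no qualifying value.
    """
    out: dict[tuple[str, ...], float | None] = {}
    for key, recs in _grouped(records, analyte, group_by).items():
        values = [r.measurement.value for r in recs if not r.measurement.censored and r.measurement.value > 0]
        out[key] = fmean(values) if values else None
    return out


def concentration_range(
    records: Iterable[ConcentrationRecord],
    analyte: str,
    group_by: GroupBy = None,
) -> dict[tuple[str, ...], ConcentrationRange]:
    """Per-group range: max over all values, min over detected values.

    When a censored bound lies below every detected value (or nothing was
    detected), the minimum is that bound, flagged ``min_censored``.
    """
    out: dict[tuple[str, ...], ConcentrationRange] = {}
    for key, recs in _grouped(records, analyte, group_by).items():
        all_values = [r.measurement.value for r in recs]
        detected = [r.measurement.value for r in recs if not r.measurement.censored]
        bounds = [r.measurement.value for r in recs if r.measurement.censored]
        max_value = max(all_values)
        if detected and (not bounds or min(bounds) >= min(detected)):
            out[key] = ConcentrationRange(min=min(detected), max=max_value)
        else:
            out[key] = ConcentrationRange(min=min(bounds), max=max_value, min_censored=True)
    return out


def summarize(
    records: Sequence[ConcentrationRecord],
    registry: Mapping[str, AnalyteSpec],
    group_by: GroupBy = None,
) -> list[GroupSummary]:
    """One GroupSummary per analyte x group, in registry order."""
    summaries: list[GroupSummary] = []
    present = {r.analyte for r in records}
    for analyte in registry:
        if analyte not in present:
            continue
        counts = detection_rate(records, analyte, group_by)
        means = mean_detected(records, analyte, group_by)
        ranges = concentration_range(records, analyte, group_by)
        for key in sorted(counts):
            rng = ranges[key]
            summaries.append(
                GroupSummary(
                    analyte=analyte,
                    group=key,
                    unit=registry[analyte].unit,
                    n_total=counts[key].n_total,
                    n_detected=counts[key].n_detected,
                    mean_detected=means[key],
                    min_detected=None if rng.min_censored else rng.min,
                    range_min=rng.min,
                    max_value=rng.max,
                    min_censored=rng.min_censored,
                )
            )
    return summaries


def summary_frame(
    summaries: Sequence[GroupSummary],
    group_names: Sequence[str] = (),
) -> pd.DataFrame:
    """Tabular view; ``mean_detected_ug`` puts every mean on the ug/L scale so
    analytes can be ranked across units."""
    rows = []
    for s in summaries:
        row = {"analyte": s.analyte}
        for i, name in enumerate(group_names):
            row[name] = s.group[i] if i < len(s.group) else ""
        mean_ug = (
            None if s.mean_detected is None else convert_units(s.mean_detected, s.unit, "ug/L")
        )
        row.update(
            unit=s.unit,
            n_total=s.n_total,
            n_detected=s.n_detected,
            detection_rate=s.detection_rate,
            mean_detected=s.mean_detected,
            mean_detected_ug=mean_ug,
            min=s.range_min,
            min_censored=s.min_censored,
            max=s.max_value,
        )
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame


def format_rate(rate: float, decimals: int = 1) -> str:
    """Percent with truncation (not rounding) at the given precision, the
    style used for detection rates in the source tables (e.g. 76.6 %)."""
    scale = 10**decimals
    truncated = int(rate * 100 * scale) / scale
    return f"{truncated:.{decimals}f}"
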