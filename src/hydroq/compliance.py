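"""Regulatory-limit and bottle-label compliance checks.

Both comparisons use a strict ``>``: a measurement exactly at the limit or
label value is not an exceedance.  Censored measurements never violate.
Labels are always in mg/L; measurements are converted to mg/L before the
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Literal, Mapping, Sequence

from .data_model import (
    AnalyteSpec,
    ConcentrationRecord,
    DataError,
    LabelEntry,
    convert_units,
)

__all__ = [
    "ComplianceFinding",
    "LabelComplianceResult",
    "check_regulatory",
    "check_labels",
    "AGGREGATIONS",
]

logger = logging.getLogger(__name__)

Aggregation = Literal["per_season", "brand_max", "brand_mean"]
AGGREGATIONS: tuple[str, ...] = ("per_season", "brand_max", "brand_mean")


@dataclass(frozen=True)
class ComplianceFinding:
    brand: str
    season: str  # "pooled" for aggregated comparisons
    analyte: str
    measured: float
    limit_or_label: float
    source: str  # INSO | WHO | label
    exceeds: bool

    def __post_init__(self) -> None:
        if self.exceeds != (self.measured > self.limit_or_label):
            raise DataError("finding inconsistent with its own comparison")


@dataclass(frozen=True)
class LabelComplianceResult:
    findings: tuple[ComplianceFinding, ...]
    # per analyte: (exceeding labelled brands, labelled brands with data)
    exceedance_counts: Mapping[str, tuple[int, int]]

    def fraction(self, analyte: str) -> float:
        num, den = self.exceedance_counts[analyte]
        return num / den


def check_regulatory(
    records: Iterable[ConcentrationRecord],
    registry: Mapping[str, AnalyteSpec],
    source: str,
) -> list[ComplianceFinding]:
    """Violations (strictly above the requested limit) only.

    Analytes without the requested limit are skipped with a logged notice.
    """
    if source not in ("INSO", "WHO"):
        raise DataError(f"unknown regulatory source {source!r}; expected INSO or WHO")
    findings: list[ComplianceFinding] = []
    skipped: set[str] = set()
    for rec in records:
        if rec.analyte not in registry:
            raise DataError(f"record {rec.key}: analyte not in registry")
        spec = registry[rec.analyte]
        limit = spec.limit(source)
        if limit is None:
            skipped.add(rec.analyte)
            continue
        if rec.measurement.censored:
            continue
        if rec.measurement.value > limit:
            findings.append(
                ComplianceFinding(
                    brand=rec.brand,
                    season=rec.season,
                    analyte=rec.analyte,
                    measured=rec.measurement.value,
                    limit_or_label=limit,
                    source=source,
                    exceeds=True,
                )
            )
    for analyte in sorted(skipped):
        logger.info("no %s limit for %s; skipped", source, analyte)
    return findings


def _aggregate(values: Sequence[tuple[str, float]], aggregation: str) -> list[tuple[str, float]]:
    """Collapse (season, value) pairs to the comparison value(s) for a brand."""
    if not values:
        return []
    if aggregation == "per_season":
        return list(values)
    if aggregation == "brand_max":
        return [("pooled", max(v for _, v in values))]
    if aggregation == "brand_mean":
        return [("pooled", fmean(v for _, v in values))]
    raise DataError(f"unknown aggregation {aggregation!r}; expected one of {AGGREGATIONS}")


def check_labels(
    records: Iterable[ConcentrationRecord],
    labels: Iterable[LabelEntry],
    registry: Mapping[str, AnalyteSpec],
    aggregation: str = "brand_max",
) -> LabelComplianceResult:
    """Compare measurements against label claims.

    Brands with an absent label are excluded from the denominator of the
    exceedance fraction; a ``less_than`` claim is exceeded when the measured
    value is strictly above its bound.  ``aggregation`` maps a brand's
    multi-season measurements onto one comparison value (default: seasonal
    maximum, i.e. a brand exceeds if either season does).
    """
    records = list(records)
    known_brands = {r.brand for r in records}
    detected: dict[tuple[str, str], list[tuple[str, float]]] = {}
    measured_keys: set[tuple[str, str]] = set()
    for rec in records:
        if rec.analyte not in registry:
            raise DataError(f"record {rec.key}: analyte not in registry")
        measured_keys.add((rec.brand, rec.analyte))
        if rec.measurement.censored:
            continue  # below detection can never exceed a claim
        value_mg = convert_units(rec.measurement.value, registry[rec.analyte].unit, "mg/L")
        detected.setdefault((rec.brand, rec.analyte), []).append((rec.season, value_mg))

    findings: list[ComplianceFinding] = []
    counts: dict[str, list[int]] = {}
    for label in labels:
        if label.brand not in known_brands:
            raise DataError(f"label for unknown brand {label.brand!r}")
        if label.qualifier == "absent":
            continue
        if (label.brand, label.analyte) not in measured_keys:
            continue  # labelled but never measured: outside the comparison
        num_den = counts.setdefault(label.analyte, [0, 0])
        num_den[1] += 1
        exceeded = False
        for season, value in _aggregate(detected.get((label.brand, label.analyte), []), aggregation):
            if value > label.labeled_value:
                exceeded = True
                findings.append(
                    ComplianceFinding(
                        brand=label.brand,
                        season=season,
                        analyte=label.analyte,
                        measured=value,
                        limit_or_label=label.labeled_value,
                        source="label",
                        exceeds=True,
                    )
                )
        if exceeded:
            num_den[0] += 1
    return LabelComplianceResult(
        findings=tuple(findings),
        exceedance_counts={k: (v[0], v[1]) for k, v in counts.items()},
    )
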