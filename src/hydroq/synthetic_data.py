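"""Synthetic survey generator with known ground truth.

Concentrations are drawn per analyte from a lognormal law with an additive
brand effect on the log scale and a multiplicative season effect, then
left-censored at a configurable LOD — the same statistical shape the
analysis pipeline assumes (right-skewed values spanning orders of magnitude
with below-detection entries).  The generating parameters are returned
alongside the records so recovery tests can compare estimates with truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import (
    AnalyteSpec,
    ConcentrationRecord,
    DataError,
    LabelEntry,
    Measurement,
)

__all__ = [
    "AnalyteLaw",
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_labels",
    "build_registry",
]


@dataclass(frozen=True)
class AnalyteLaw:
    """Lognormal generative law for one analyte (unit: mg/L)."""

    log_mean: float
    log_sd: float
    lod: float = 0.0  # values below this bound are emitted as censored

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise DataError("log_sd must be positive")
        if self.lod < 0:
            raise DataError("lod must be non-negative")

    @property
    def mean(self) -> float:
        """E[X] = exp(mu + sigma^2 / 2) (no brand/season effects)."""
        return math.exp(self.log_mean + self.log_sd**2 / 2.0)

    def quantile(self, p: float) -> float:
        from scipy.stats import norm

        return math.exp(self.log_mean + self.log_sd * norm.ppf(p))


@dataclass(frozen=True)
class SyntheticConfig:
    analytes: Mapping[str, AnalyteLaw]
    brands_per_type: int = 15
    brand_log_sd: float = 0.0  # sd of the per-brand log-offset
    season_multiplier: float = 1.0  # applied to summer values
    seasons: tuple[str, ...] = ("summer", "winter")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.analytes:
            raise DataError("at least one analyte law is required")
        if self.brands_per_type < 1:
            raise DataError("brands_per_type must be at least 1")
        if self.brand_log_sd < 0:
            raise DataError("brand_log_sd must be non-negative")
        if self.season_multiplier <= 0:
            raise DataError("season_multiplier must be positive")
        for season in self.seasons:
            if season not in ("summer", "winter", "pooled"):
                raise DataError(f"unknown season {season!r}")


@dataclass(frozen=True)
class GroundTruth:
    config: SyntheticConfig
    brand_effects: Mapping[str, float]  # log-scale offsets actually drawn


def _brands(config: SyntheticConfig) -> list[str]:
    return [f"{wt}{i}" for wt in ("BDW", "BMW") for i in range(1, config.brands_per_type + 1)]


def generate_dataset(config: SyntheticConfig) -> tuple[list[ConcentrationRecord], GroundTruth]:
    """Draw a full survey; deterministic for a fixed config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    brands = _brands(config)
    effects = {b: (rng.normal(0.0, config.brand_log_sd) if config.brand_log_sd else 0.0) for b in brands}
    records: list[ConcentrationRecord] = []
    for brand in brands:
        for season in config.seasons:
            for analyte, law in config.analytes.items():
                z = rng.standard_normal()
                log_value = law.log_mean + effects[brand] + law.log_sd * z
                if season == "summer":
                    log_value += math.log(config.season_multiplier)
                value = math.exp(log_value)
                if value < law.lod:
                    measurement = Measurement(value=law.lod, censored=True)
                else:
                    measurement = Measurement(value=value, censored=False)
                records.append(
                    ConcentrationRecord(
                        brand=brand, season=season, analyte=analyte, measurement=measurement
                    )
                )
    return records, GroundTruth(config=config, brand_effects=effects)


def generate_labels(
    records: Sequence[ConcentrationRecord],
    bias: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    absent_fraction: float = 0.0,
) -> list[LabelEntry]:
    """Label claims derived from brand means: mean * bias * exp(noise_sd*Z).

    ``bias`` < 1 understates the content (guaranteeing exceedances under a
    strict ">" when noise is zero); ``absent_fraction`` of labels are emitted
    with no value.  Records are assumed to be in mg/L already.
    """
    if bias <= 0:
        raise DataError("bias must be positive")
    if not 0.0 <= absent_fraction <= 1.0:
        raise DataError("absent_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sums: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        sums.setdefault((rec.brand, rec.analyte), []).append(rec.measurement.value)
    labels: list[LabelEntry] = []
    for (brand, analyte), values in sorted(sums.items()):
        noise = math.exp(noise_sd * rng.standard_normal()) if noise_sd else 1.0
        if absent_fraction and rng.random() < absent_fraction:
            labels.append(LabelEntry(brand=brand, analyte=analyte, labeled_value=None, qualifier="absent"))
        else:
            labels.append(
                LabelEntry(
                    brand=brand,
                    analyte=analyte,
                    labeled_value=float(np.mean(values)) * bias * noise,
                    qualifier="exact",
                )
            )
    return labels


def build_registry(
    config: SyntheticConfig,
    rfds: Mapping[str, float] | None = None,
    limits: Mapping[str, float] | None = None,
) -> dict[str, AnalyteSpec]:
    """Registry matching a synthetic config so the full pipeline can run.

    A tiny positive LOD stands in for laws generated without censoring.
    """
    rfds = rfds or {}
    limits = limits or {}
    registry: dict[str, AnalyteSpec] = {}
    for analyte, law in config.analytes.items():
        lod = law.lod if law.lod > 0 else 1e-12
        registry[analyte] = AnalyteSpec(
            name=analyte,
            unit="mg/L",
            lod=lod,
            loq=lod * 3.0,
            rfd=rfds.get(analyte),
            inso_limit=limits.get(analyte),
            who_limit=limits.get(analyte),
        )
    return registry
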