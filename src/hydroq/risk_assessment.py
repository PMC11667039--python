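"""Deterministic and Monte-Carlo non-carcinogenic ingestion risk.

Chronic daily intake of a waterborne contaminant::

    CDI = C * IR * EF * ED / (BW * AT)      [mg/kg bw/day]

with C in mg/L, IR in L/day, EF in days/year, ED in years, BW in kg and AT
in days.  Because the exposure profiles fix AT = ED * EF, CDI reduces to
C * IR / BW and is independent of ED and EF.  The hazard quotient is
HQ = CDI / RfD; HQ > 1 flags a potential non-carcinogenic risk.

The Monte-Carlo layer draws concentrations from a fitted
:class:`DistributionModel`, maps each draw through the intake equation and
reports percentiles.  HQ percentiles are computed as CDI percentiles divided
by the RfD, so the monotone-transform identity holds exactly by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .data_model import (
    AnalyteSpec,
    ConcentrationRecord,
    DataError,
    ExposureProfile,
    Measurement,
    convert_units,
)

__all__ = [
    "CensorRule",
    "DistributionModel",
    "MonteCarloResult",
    "RiskSettings",
    "chronic_daily_intake",
    "hazard_quotient",
    "substitute_censored",
    "fit_distribution",
    "simulate_hq",
    "percentile",
    "risk_report",
]

CensorRule = Literal["half_lod", "lod", "drop"]
Family = Literal["empirical_bootstrap", "lognormal", "normal", "degenerate"]

CENSOR_RULES: tuple[str, ...] = ("half_lod", "lod", "drop")
FAMILIES: tuple[str, ...] = ("empirical_bootstrap", "lognormal", "normal", "degenerate")


# ---------------------------------------------------------------------------
# deterministic arithmetic
# ---------------------------------------------------------------------------

def chronic_daily_intake(c, profile: ExposureProfile):
    """CDI in mg/kg bw/day for a concentration (scalar or array) in mg/L."""
    if profile.bw <= 0 or profile.at <= 0:
        raise DataError("body weight and averaging time must be positive")
    if np.any(np.asarray(c) < 0):
        raise DataError("concentration must be non-negative")
    full = c * profile.ir * profile.ef * profile.ed / (profile.bw * profile.at)
    if profile.at == profile.ed * profile.ef:
        simplified = c * profile.ir / profile.bw
        # the two algebraic forms must agree; the simplified one is returned
        # so that (ED, EF) pairs with the same product give identical output
        if not np.allclose(full, simplified, rtol=1e-9, atol=0.0):
            raise AssertionError("intake equation forms disagree")
        return simplified
    return full


def hazard_quotient(cdi, rfd: float):
    """HQ = CDI / RfD (dimensionless); both in mg/kg/day."""
    if rfd is None or rfd <= 0:
        raise DataError("a positive oral reference dose is required")
    return cdi / rfd


# ---------------------------------------------------------------------------
# censoring treatment and distribution fitting
# ---------------------------------------------------------------------------

def substitute_censored(measurements: Iterable[Measurement], rule: str) -> list[float]:
    """Value list after censoring substitution.

    ``half_lod`` replaces a censored bound b by b/2, ``lod`` keeps b, and
    ``drop`` removes censored entries entirely.
    """
    if rule not in CENSOR_RULES:
        raise DataError(f"unknown censor rule {rule!r}; expected one of {CENSOR_RULES}")
    values: list[float] = []
    for m in measurements:
        if not m.censored:
            values.append(m.value)
        elif rule == "half_lod":
            values.append(m.value / 2.0)
        elif rule == "lod":
            values.append(m.value)
    return values


@dataclass(frozen=True)
class DistributionModel:
    """A concentration distribution with its censoring treatment.

    ``params`` is family-specific: the substituted value tuple for
    ``empirical_bootstrap``; (mu, sigma) on the log scale for ``lognormal``;
    (mean, sd) for ``normal`` (sampling truncated at zero by resampling); the
    single value for ``degenerate``.
    """

    family: str
    params: tuple[float, ...]
    censor_rule: str

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "degenerate":
            return np.full(size, self.params[0])
        if self.family == "empirical_bootstrap":
            return rng.choice(np.asarray(self.params), size=size, replace=True)
        if self.family == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mean=mu, sigma=sigma, size=size)
        if self.family == "normal":
            mean, sd = self.params
            draws = rng.normal(mean, sd, size=size)
            while True:  # truncate at zero by redrawing
                neg = draws < 0
                if not neg.any():
                    return draws
                draws[neg] = rng.normal(mean, sd, size=int(neg.sum()))
        raise DataError(f"unknown distribution family {self.family!r}")


def fit_distribution(
    measurements: Sequence[Measurement],
    family: str = "empirical_bootstrap",
    censor_rule: str = "half_lod",
) -> DistributionModel:
    """Fit a concentration distribution after censoring substitution.

    All-equal inputs collapse to ``degenerate`` whatever family was asked
    for.  The lognormal fit is a maximum-likelihood fit on the logs of the
    strictly positive values; ``normal`` uses the sample mean and sd
    (ddof=1).  Parametric fits require at least three distinct values.
    """
    if family not in FAMILIES:
        raise DataError(f"unknown distribution family {family!r}; expected one of {FAMILIES}")
    values = substitute_censored(measurements, censor_rule)
    if not values:
        raise DataError("no values remain after censoring treatment")
    arr = np.asarray(values, dtype=float)
    if np.all(arr == arr[0]):
        return DistributionModel("degenerate", (float(arr[0]),), censor_rule)
    if family == "degenerate":
        raise DataError("degenerate family requires all values equal")
    if family == "empirical_bootstrap":
        return DistributionModel(family, tuple(float(v) for v in arr), censor_rule)
    if len(np.unique(arr)) < 3:
        raise DataError("parametric fits need at least three distinct values")
    if family == "lognormal":
        positive = arr[arr > 0]
        if positive.size < 3:
            raise DataError("lognormal fit needs at least three positive values")
        logs = np.log(positive)
        return DistributionModel(family, (float(logs.mean()), float(logs.std(ddof=0))), censor_rule)
    return DistributionModel("normal", (float(arr.mean()), float(arr.std(ddof=1))), censor_rule)


# ---------------------------------------------------------------------------
# percentiles and simulation
# ---------------------------------------------------------------------------

def percentile(samples: Sequence[float], p: float) -> float:
    """Linear-interpolation order statistic at position (n-1)*p/100 + 1."""
    arr = np.sort(np.asarray(samples, dtype=float))
    if arr.size == 0:
        raise DataError("cannot take a percentile of an empty sample")
    if not 0.0 < p < 100.0:
        raise DataError(f"percentile must lie strictly between 0 and 100, got {p}")
    h = (arr.size - 1) * p / 100.0
    lo = math.floor(h)
    hi = min(lo + 1, arr.size - 1)
    return float(arr[lo] + (h - lo) * (arr[hi] - arr[lo]))


@dataclass(frozen=True)
class MonteCarloResult:
    analyte: str
    group: str
    n_iter: int
    seed: int
    cdi_percentiles: Mapping[float, float]
    hq_percentiles: Mapping[float, float]
    mean_cdi: float
    mean_hq: float

    @property
    def flagged(self) -> bool:
        """True when any reported HQ percentile exceeds 1."""
        return any(v > 1.0 for v in self.hq_percentiles.values())


def simulate_hq(
    dist: DistributionModel,
    profile: ExposureProfile,
    rfd: float,
    n_iter: int = 10_000,
    seed: int = 0,
    percentiles: Sequence[float] = (5.0, 50.0, 95.0),
    analyte: str = "",
) -> MonteCarloResult:
    """Monte-Carlo CDI/HQ percentiles for one analyte and exposure group.

    The concentration draws are in mg/L; a fixed seed gives bit-identical
    results.
    """
    if n_iter < 1:
        raise DataError("n_iter must be at least 1")
    for p in percentiles:
        if not 0.0 < p < 100.0:
            raise DataError(f"invalid percentile {p}")
    rng = np.random.default_rng(seed)
    draws = dist.sample(rng, n_iter)
    cdi = chronic_daily_intake(draws, profile)
    if rfd is None or rfd <= 0:
        raise DataError("a positive oral reference dose is required")
    cdi_p = {float(p): percentile(cdi, p) for p in percentiles}
    hq_p = {p: v / rfd for p, v in cdi_p.items()}
    return MonteCarloResult(
        analyte=analyte,
        group=profile.group,
        n_iter=n_iter,
        seed=seed,
        cdi_percentiles=cdi_p,
        hq_percentiles=hq_p,
        mean_cdi=float(np.mean(cdi)),
        mean_hq=float(np.mean(cdi)) / rfd,
    )


@dataclass(frozen=True)
class RiskSettings:
    n_iter: int = 10_000
    seed: int = 0
    family: str = "empirical_bootstrap"
    censor_rule: str = "half_lod"
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)


def risk_report(
    records: Sequence[ConcentrationRecord],
    registry: Mapping[str, AnalyteSpec],
    profiles: Mapping[str, ExposureProfile],
    settings: RiskSettings = RiskSettings(),
) -> list[MonteCarloResult]:
    """One MonteCarloResult per analyte-with-RfD x exposure group.

    Analytes with no RfD, or with every measurement censored, are skipped.
    Concentrations are pooled across water types and seasons and converted
    to mg/L before simulation.  Each (analyte, group) pair gets its own
    deterministic child seed derived from ``settings.seed``.
    """
    results: list[MonteCarloResult] = []
    offset = 0
    for analyte, spec in registry.items():
        if spec.rfd is None:
            continue
        selected = [r.measurement for r in records if r.analyte == analyte]
        if not selected or all(m.censored for m in selected):
            offset += len(profiles)
            continue
        in_mg = [
            Measurement(
                value=convert_units(m.value, spec.unit, "mg/L"),
                censored=m.censored,
                sd=None,
            )
            for m in selected
        ]
        dist = fit_distribution(in_mg, settings.family, settings.censor_rule)
        for i, profile in enumerate(profiles.values()):
            child_seed = int(
                np.random.SeedSequence(entropy=settings.seed, spawn_key=(offset + i,)).generate_state(1)[0]
            )
            results.append(
                simulate_hq(
                    dist,
                    profile,
                    spec.rfd,
                    n_iter=settings.n_iter,
                    seed=child_seed,
                    percentiles=settings.percentiles,
                    analyte=analyte,
                )
            )
        offset += len(profiles)
    return results
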