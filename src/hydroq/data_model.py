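"""Domain types, delimited-text I/O, unit conversion and packaged reference tables.

The survey layout is long-format: one row per (brand, season, analyte)
measurement.  Left-censored results are written as ``"<"`` followed by the
censoring bound (e.g. ``<0.14``), which is the convention used throughout the
packaged fixture tables.

Units
-----
Each analyte carries a single declared unit (``mg/L`` or ``ug/L``) in the
registry; every stored measurement, LOD/LOQ and regulatory limit for that
analyte is expressed in that unit.  ``convert_units`` handles the only
supported conversion (factor 1000).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Literal, Mapping, Sequence

import yaml

__all__ = [
    "DataError",
    "Measurement",
    "ConcentrationRecord",
    "AnalyteSpec",
    "ExposureProfile",
    "LabelEntry",
    "convert_units",
    "normalize_unit",
    "water_type_of",
    "read_concentration_table",
    "write_concentration_table",
    "read_label_table",
    "write_label_table",
    "load_registry",
    "load_profiles",
    "load_fixture",
    "FIXTURE_NAMES",
    "SEASONS",
    "WATER_TYPES",
]

WaterType = Literal["BDW", "BMW"]
Season = Literal["summer", "winter", "pooled"]
Qualifier = Literal["exact", "less_than", "absent"]

WATER_TYPES: tuple[str, ...] = ("BDW", "BMW")
SEASONS: tuple[str, ...] = ("summer", "winter", "pooled")
FIXTURE_NAMES: tuple[str, ...] = (
    "table1",
    "table2",
    "table3",
    "table4",
    "registry",
    "profiles",
)

_BRAND_RE = re.compile(r"^(BDW|BMW)([1-9]\d*)$")
_UG_PER_MG = 1000.0
# accept unicode spellings on input; canonical form is ASCII "ug/L"
_UNIT_ALIASES = {
    "mg/L": "mg/L",
    "mg/l": "mg/L",
    "ug/L": "ug/L",
    "ug/l": "ug/L",
    "μg/L": "ug/L",
    "µg/L": "ug/L",
}


class DataError(ValueError):
    """Malformed or internally inconsistent input data."""


def normalize_unit(unit: str) -> str:
    try:
        return _UNIT_ALIASES[unit]
    except KeyError:
        raise DataError(f"unsupported unit {unit!r}; expected one of mg/L, ug/L") from None


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a concentration between mg/L and ug/L (identity when equal)."""
    src, dst = normalize_unit(from_unit), normalize_unit(to_unit)
    if src == dst:
        return value
    if (src, dst) == ("mg/L", "ug/L"):
        return value * _UG_PER_MG
    return value / _UG_PER_MG


def water_type_of(brand: str) -> str:
    """Water-type code (BDW or BMW) implied by a brand code."""
    m = _BRAND_RE.match(brand)
    if m is None:
        raise DataError(f"invalid brand code {brand!r}; expected BDW<n> or BMW<n>")
    return m.group(1)


@dataclass(frozen=True)
class Measurement:
    """A single concentration result in the analyte's declared unit.

    For a censored result (reported "<LOD") ``value`` holds the censoring
    bound as printed, not an observation.
    """

    value: float
    censored: bool = False
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DataError(f"negative concentration {self.value}")
        if self.sd is not None and self.sd < 0:
            raise DataError(f"negative replicate sd {self.sd}")
        if self.censored and self.value <= 0:
            raise DataError("a censored result must carry a positive bound")


@dataclass(frozen=True)
class ConcentrationRecord:
    brand: str
    season: str
    analyte: str
    measurement: Measurement

    def __post_init__(self) -> None:
        water_type_of(self.brand)  # validates the code
        if self.season not in SEASONS:
            raise DataError(f"unknown season {self.season!r}; expected one of {SEASONS}")

    @property
    def water_type(self) -> str:
        return water_type_of(self.brand)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.brand, self.season, self.analyte)


@dataclass(frozen=True)
class AnalyteSpec:
    """Registry entry: unit, detection limits, reference dose, limits.

    ``lod``/``loq`` and the regulatory limits are in ``unit``; ``rfd`` is
    always in mg/kg/day regardless of ``unit``.
    """

    name: str
    unit: str
    lod: float
    loq: float
    rfd: float | None = None
    inso_limit: float | None = None
    who_limit: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", normalize_unit(self.unit))
        if self.lod <= 0:
            raise DataError(f"{self.name}: LOD must be positive")
        if self.loq <= self.lod:
            raise DataError(f"{self.name}: LOQ ({self.loq}) must exceed LOD ({self.lod})")
        for attr in ("rfd", "inso_limit", "who_limit"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise DataError(f"{self.name}: {attr} must be positive when present")

    def limit(self, source: str) -> float | None:
        if source == "INSO":
            return self.inso_limit
        if source == "WHO":
            return self.who_limit
        raise DataError(f"unknown regulatory source {source!r}")


@dataclass(frozen=True)
class ExposureProfile:
    """Ingestion-exposure parameter set for one population group."""

    group: str
    ir: float  # water ingestion rate, L/day
    ef: float  # exposure frequency, days/year
    ed: float  # exposure duration, years
    bw: float  # body weight, kg
    at: float  # averaging time, days

    def __post_init__(self) -> None:
        for attr in ("ir", "ef", "ed", "bw", "at"):
            if getattr(self, attr) <= 0:
                raise DataError(f"exposure profile {self.group}: {attr} must be positive")
        if abs(self.at - self.ed * self.ef) > 1e-9 * max(self.at, 1.0):
            raise DataError(
                f"exposure profile {self.group}: AT ({self.at}) must equal ED*EF "
                f"({self.ed * self.ef})"
            )


@dataclass(frozen=True)
class LabelEntry:
    """A bottle-label claim (always mg/L); ``qualifier`` distinguishes an
    exact claim, an upper-bound claim ("<x") and a missing entry."""

    brand: str
    analyte: str
    labeled_value: float | None
    qualifier: Qualifier

    def __post_init__(self) -> None:
        water_type_of(self.brand)
        if (self.qualifier == "absent") != (self.labeled_value is None):
            raise DataError(
                f"label {self.brand}/{self.analyte}: value must be absent exactly "
                "when the qualifier is 'absent'"
            )
        if self.labeled_value is not None and self.labeled_value < 0:
            raise DataError(f"label {self.brand}/{self.analyte}: negative value")


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_CONC_HEADER = ["brand", "season", "analyte", "value", "sd"]
_LABEL_HEADER = ["brand", "analyte", "value"]


def _format_number(x: float) -> str:
    # repr() is the shortest digit string that round-trips the float
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


def _open_source(source: str | Path | IO[str]) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline="")
    return source


def read_concentration_table(
    source: str | Path | IO[str],
    registry: Mapping[str, AnalyteSpec],
) -> list[ConcentrationRecord]:
    """Parse a long-format concentration CSV.

    Censored entries are written ``<bound``.  An optional ``unit`` column,
    when present, must agree with the registry unit for the row's analyte.
    """
    stream = _open_source(source)
    close = isinstance(source, (str, Path))
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            return []
        missing = {"brand", "season", "analyte", "value"} - set(reader.fieldnames)
        if missing:
            raise DataError(f"missing required columns: {sorted(missing)}")
        records: list[ConcentrationRecord] = []
        seen: set[tuple[str, str, str]] = set()
        for lineno, row in enumerate(reader, start=2):
            brand = row["brand"].strip()
            season = row["season"].strip()
            analyte = row["analyte"].strip()
            if analyte not in registry:
                raise DataError(f"row {lineno}: unknown analyte {analyte!r}")
            if "unit" in row and row.get("unit"):
                if normalize_unit(row["unit"].strip()) != registry[analyte].unit:
                    raise DataError(
                        f"row {lineno}: unit {row['unit']!r} does not match the "
                        f"registry unit {registry[analyte].unit!r} for {analyte}"
                    )
            raw = row["value"].strip()
            censored = raw.startswith("<")
            try:
                value = float(raw[1:]) if censored else float(raw)
            except ValueError:
                raise DataError(f"row {lineno}: unparseable value {raw!r}") from None
            if value < 0:
                raise DataError(f"row {lineno}: negative value {value}")
            sd_raw = (row.get("sd") or "").strip()
            sd = float(sd_raw) if sd_raw else None
            record = ConcentrationRecord(
                brand=brand,
                season=season,
                analyte=analyte,
                measurement=Measurement(value=value, censored=censored, sd=sd),
            )
            if record.key in seen:
                raise DataError(f"row {lineno}: duplicate record {record.key}")
            seen.add(record.key)
            records.append(record)
        return records
    finally:
        if close:
            stream.close()


def write_concentration_table(
    records: Iterable[ConcentrationRecord],
    dest: str | Path | IO[str],
) -> None:
    stream = open(dest, "w", encoding="utf-8", newline="") if isinstance(dest, (str, Path)) else dest
    close = isinstance(dest, (str, Path))
    try:
        writer = csv.writer(stream, lineterminator="\n")
        writer.writerow(_CONC_HEADER)
        for rec in records:
            m = rec.measurement
            value = f"<{_format_number(m.value)}" if m.censored else _format_number(m.value)
            sd = "" if m.sd is None else _format_number(m.sd)
            writer.writerow([rec.brand, rec.season, rec.analyte, value, sd])
    finally:
        if close:
            stream.close()


def read_label_table(source: str | Path | IO[str]) -> list[LabelEntry]:
    """Parse a label-claims CSV (brand, analyte, value; ``NA`` = no claim)."""
    stream = _open_source(source)
    close = isinstance(source, (str, Path))
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            return []
        missing = set(_LABEL_HEADER) - set(reader.fieldnames)
        if missing:
            raise DataError(f"missing required columns: {sorted(missing)}")
        entries: list[LabelEntry] = []
        for lineno, row in enumerate(reader, start=2):
            raw = row["value"].strip()
            if raw in ("", "NA"):
                value, qualifier = None, "absent"
            elif raw.startswith("<"):
                value, qualifier = float(raw[1:]), "less_than"
            else:
                value, qualifier = float(raw), "exact"
            try:
                entries.append(
                    LabelEntry(
                        brand=row["brand"].strip(),
                        analyte=row["analyte"].strip(),
                        labeled_value=value,
                        qualifier=qualifier,
                    )
                )
            except DataError as exc:
                raise DataError(f"row {lineno}: {exc}") from None
        return entries
    finally:
        if close:
            stream.close()


def write_label_table(entries: Iterable[LabelEntry], dest: str | Path | IO[str]) -> None:
    stream = open(dest, "w", encoding="utf-8", newline="") if isinstance(dest, (str, Path)) else dest
    close = isinstance(dest, (str, Path))
    try:
        writer = csv.writer(stream, lineterminator="\n")
        writer.writerow(_LABEL_HEADER)
        for e in entries:
            if e.qualifier == "absent":
                value = "NA"
            elif e.qualifier == "less_than":
                value = f"<{_format_number(e.labeled_value)}"
            else:
                value = _format_number(e.labeled_value)
            writer.writerow([e.brand, e.analyte, value])
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# keyed-text (YAML) configuration
# ---------------------------------------------------------------------------

def load_registry(source: str | Path | IO[str]) -> dict[str, AnalyteSpec]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    analytes = doc.get("analytes", doc)
    registry: dict[str, AnalyteSpec] = {}
    for name, fields in analytes.items():
        registry[name] = AnalyteSpec(name=name, **fields)
    return registry


def load_profiles(source: str | Path | IO[str]) -> dict[str, ExposureProfile]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    profiles = doc.get("profiles", doc)
    return {name: ExposureProfile(group=name, **fields) for name, fields in profiles.items()}


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_text(filename: str) -> io.StringIO:
    text = resources.files(__package__).joinpath("fixtures", filename).read_text("utf-8")
    return io.StringIO(text)


def load_fixture(name: str):
    """Load one of the packaged survey tables or configuration files.

    ``table1``  anion concentrations per brand and season (mg/L)
    ``table2``  element concentrations per BDW brand, season-pooled
    ``table3``  element concentrations per BMW brand, season-pooled
    ``table4``  bottle-label claims (mg/L)
    ``registry``/``profiles``  analyte registry and exposure profiles
    """
    if name not in FIXTURE_NAMES:
        raise DataError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    if name == "registry":
        return load_registry(_fixture_text("registry.yaml"))
    if name == "profiles":
        return load_profiles(_fixture_text("profiles.yaml"))
    if name == "table4":
        return read_label_table(_fixture_text("table4.csv"))
    registry = load_registry(_fixture_text("registry.yaml"))
    return read_concentration_table(_fixture_text(f"{name}.csv"), registry)


def load_survey() -> list[ConcentrationRecord]:
    """All packaged concentration records (anions + both element tables)."""
    return load_fixture("table1") + load_fixture("table2") + load_fixture("table3")
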