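"""End-to-end orchestration: summaries, compliance, rank tests and risk.

``run_pipeline`` is a pure function of (inputs, config): every stage output
is written as CSV plus a plain-text report, and a JSON manifest records the
seed and settings needed to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import compliance as comp
from . import nonparametric_stats as nps
from . import summary_statistics as ss
from .data_model import (
    AnalyteSpec,
    ConcentrationRecord,
    DataError,
    ExposureProfile,
    LabelEntry,
    load_fixture,
    load_profiles,
    load_registry,
    load_survey,
    read_concentration_table,
    read_label_table,
)
from .risk_assessment import RiskSettings, risk_report, substitute_censored

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

ANION_ANALYTES = ("nitrate", "nitrite")


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``use_fixtures`` / ``input_path`` selects the data."""

    use_fixtures: bool = True
    input_path: str | None = None
    labels_path: str | None = None
    registry_path: str | None = None
    profiles_path: str | None = None
    analytes: tuple[str, ...] | None = None  # None = all in registry
    risk: RiskSettings = field(default_factory=RiskSettings)
    compliance_source: str = "INSO"
    label_aggregation: str = "brand_max"
    out_dir: str = "hydroq-out"

    def __post_init__(self) -> None:
        if self.use_fixtures == (self.input_path is not None):
            raise DataError("provide exactly one of fixtures or an input path")


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    regulatory: pd.DataFrame
    labels: pd.DataFrame
    tests: pd.DataFrame
    risk: pd.DataFrame
    manifest: dict


def _load_inputs(config: PipelineConfig):
    if config.use_fixtures:
        registry = load_fixture("registry")
        profiles = load_fixture("profiles")
        records = load_survey()
        labels = load_fixture("table4")
    else:
        registry = (
            load_registry(config.registry_path) if config.registry_path else load_fixture("registry")
        )
        profiles = (
            load_profiles(config.profiles_path) if config.profiles_path else load_fixture("profiles")
        )
        try:
            records = read_concentration_table(config.input_path, registry)
        except (OSError, DataError) as exc:
            raise DataError(f"cannot read {config.input_path}: {exc}") from exc
        labels = read_label_table(config.labels_path) if config.labels_path else []
    if config.analytes:
        records = [r for r in records if r.analyte in config.analytes]
        labels = [l for l in labels if l.analyte in config.analytes]
    return registry, profiles, records, labels


def _summary_stage(records, registry) -> pd.DataFrame:
    frames = []
    anions = [r for r in records if r.analyte in ANION_ANALYTES]
    elements = [r for r in records if r.analyte not in ANION_ANALYTES]
    if anions:
        frames.append(
            ss.summary_frame(
                ss.summarize(anions, registry, group_by=("water_type", "season")),
                group_names=("water_type", "season"),
            )
        )
    if elements:
        frame = ss.summary_frame(
            ss.summarize(elements, registry, group_by=("water_type",)),
            group_names=("water_type",),
        )
        frame.insert(2, "season", "pooled")
        frames.append(frame)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _tests_stage(records, registry, censor_rule: str) -> pd.DataFrame:
    """Water-type contrast per analyte; season contrast for per-season data.

    Element comparisons use per-brand values, anion comparisons use
    brand x season values; censored entries enter at the substituted bound.
    """
    rows = []
    by_analyte: dict[str, list[ConcentrationRecord]] = {}
    for rec in records:
        by_analyte.setdefault(rec.analyte, []).append(rec)
    for analyte in registry:
        recs = by_analyte.get(analyte)
        if not recs:
            continue
        groups = {}
        for wt in ("BDW", "BMW"):
            groups[wt] = substitute_censored(
                [r.measurement for r in recs if r.water_type == wt], censor_rule
            )
        if len(groups["BDW"]) >= 2 and len(groups["BMW"]) >= 2:
            if len(set(groups["BDW"] + groups["BMW"])) > 1:
                res = nps.mann_whitney_u(groups["BDW"], groups["BMW"])
                rows.append(
                    {
                        "analyte": analyte,
                        "comparison": "BDW_vs_BMW",
                        "method": res.method,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "n": "/".join(str(n) for n in res.n_per_group),
                    }
                )
        seasons = {
            s: substitute_censored([r.measurement for r in recs if r.season == s], censor_rule)
            for s in ("summer", "winter")
        }
        if len(seasons["summer"]) >= 2 and len(seasons["winter"]) >= 2:
            res = nps.kruskal_wallis([seasons["summer"], seasons["winter"]])
            rows.append(
                {
                    "analyte": analyte,
                    "comparison": "summer_vs_winter",
                    "method": res.method,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": "/".join(str(n) for n in res.n_per_group),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    registry, profiles, records, labels = _load_inputs(config)
    logger.info("loaded %d records, %d labels", len(records), len(labels))

    summary = _summary_stage(records, registry)

    reg_findings = comp.check_regulatory(records, registry, config.compliance_source)
    regulatory = pd.DataFrame([asdict(f) for f in reg_findings])

    if labels:
        label_result = comp.check_labels(records, labels, registry, config.label_aggregation)
        label_frame = pd.DataFrame([asdict(f) for f in label_result.findings])
        fractions = pd.DataFrame(
            [
                {"analyte": a, "n_exceeding": n, "n_labelled": d, "fraction": n / d}
                for a, (n, d) in sorted(label_result.exceedance_counts.items())
            ]
        )
    else:
        label_frame = pd.DataFrame()
        fractions = pd.DataFrame()

    tests = _tests_stage(records, registry, config.risk.censor_rule)

    risk_rows = risk_report(records, registry, profiles, config.risk)
    risk = pd.DataFrame(
        [
            {
                "analyte": r.analyte,
                "group": r.group,
                "n_iter": r.n_iter,
                "seed": r.seed,
                **{f"cdi_p{int(p)}": v for p, v in r.cdi_percentiles.items()},
                **{f"hq_p{int(p)}": v for p, v in r.hq_percentiles.items()},
                "mean_cdi": r.mean_cdi,
                "mean_hq": r.mean_hq,
                "flagged": r.flagged,
            }
            for r in risk_rows
        ]
    )

    manifest = {
        "package_version": _pkg_version("hydroq"),
        "config": {
            "use_fixtures": config.use_fixtures,
            "input_path": config.input_path,
            "labels_path": config.labels_path,
            "analytes": list(config.analytes) if config.analytes else None,
            "compliance_source": config.compliance_source,
            "label_aggregation": config.label_aggregation,
            "risk": {**asdict(config.risk), "percentiles": list(config.risk.percentiles)},
        },
        "counts": {
            "records_in": len(records),
            "labels_in": len(labels),
            "regulatory_findings": len(reg_findings),
            "label_findings": int(len(label_frame)),
            "risk_rows": int(len(risk)),
        },
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "summary.csv", index=False)
    regulatory.to_csv(out / "regulatory_findings.csv", index=False)
    label_frame.to_csv(out / "label_findings.csv", index=False)
    fractions.to_csv(out / "label_fractions.csv", index=False)
    tests.to_csv(out / "stat_tests.csv", index=False)
    risk.to_csv(out / "risk.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    _write_text_report(out / "report.txt", summary, regulatory, fractions, tests, risk)
    return PipelineResult(
        summary=summary,
        regulatory=regulatory,
        labels=label_frame,
        tests=tests,
        risk=risk,
        manifest=manifest,
    )


def _write_text_report(path: Path, summary, regulatory, fractions, tests, risk) -> None:
    parts = []
    for title, frame in (
        ("SUMMARY", summary),
        ("REGULATORY FINDINGS", regulatory),
        ("LABEL EXCEEDANCE FRACTIONS", fractions),
        ("RANK TESTS", tests),
        ("RISK (CDI / HQ percentiles)", risk),
    ):
        parts.append(f"== {title} ==")
        parts.append("(none)" if frame.empty else frame.to_string(index=False))
        parts.append("")
    path.write_text("\n".join(parts))
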