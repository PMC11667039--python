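# hydroq

Analysis pipeline for a censored bottled-water contaminant survey: detection
and concentration summaries, regulatory-limit and bottle-label compliance
checks, rank-based group comparisons, and deterministic plus Monte-Carlo
non-carcinogenic ingestion risk (chronic daily intake and hazard quotient,
with percentile reporting).

The package ships the survey tables it analyses as plain-text fixtures
(long-format CSV + YAML): anion concentrations per brand and season, element
concentrations per brand, label claims, an analyte registry (units, LOD/LOQ,
reference doses, regulatory limits) and exposure profiles for children and
adults. A synthetic-data module generates datasets with the same statistical
shape (lognormal with brand/season effects and left-censoring) and known
ground truth, so every stage is testable without the fixtures.

## Concepts

- **CDI** = C·IR·EF·ED / (BW·AT) in mg/kg bw/day. The shipped profiles fix
  AT = ED·EF, so CDI reduces to C·IR/BW (children: 1 L/day, 15 kg; adults:
  2 L/day, 70 kg).
- **HQ** = CDI / RfD; HQ > 1 flags potential non-carcinogenic risk.
- **Censoring**: values below the detection limit are stored as `<bound`.
  Substitution rules `half_lod` (default), `lod` and `drop` are available
  wherever censored values enter a computation.
- **Monte-Carlo risk**: concentrations are resampled (empirical bootstrap by
  default; lognormal/normal/degenerate fits available), mapped through the
  intake equation, and summarised at the 5th/50th/95th percentiles.
  HQ percentiles are CDI percentiles divided by the RfD, so the
  monotone-transform identity holds exactly. All simulations are seeded and
  bit-reproducible.

## CLI

```sh
hydroq run-all --out-dir out               # full pipeline on the fixtures
hydroq summarize --out-dir out             # detection rates, means, ranges
hydroq comply --source INSO --out-dir out  # regulatory findings (INSO/WHO)
hydroq comply --source label --aggregation brand_max --out-dir out
hydroq test --out-dir out                  # Mann-Whitney / Kruskal-Wallis table
hydroq risk --n-iter 10000 --seed 1 --family empirical_bootstrap --out-dir out
hydroq simulate --config syn.yaml -o syn.csv   # synthetic survey
hydroq risk --input syn.csv --out-dir out      # any stage accepts --input
```

Each run writes CSV tables (`summary.csv`, `regulatory_findings.csv`,
`label_findings.csv`, `label_fractions.csv`, `stat_tests.csv`, `risk.csv`),
a plain-text `report.txt`, and a `manifest.json` recording the seed and
settings needed to reproduce the outputs byte-for-byte.

A synthetic config is YAML:

```yaml
analytes:
  nitrate: {log_mean: 1.0, log_sd: 0.6, lod: 0.14}
brands_per_type: 15
brand_log_sd: 0.3
season_multiplier: 1.5
seed: 9
```

## Python API

```python
from hydroq import load_fixture, load_survey, risk_report, RiskSettings

registry = load_fixture("registry")
profiles = load_fixture("profiles")
records = load_survey()
rows = risk_report(records, registry, profiles, RiskSettings(n_iter=10_000, seed=1))
```

Modules: `data_model` (types, CSV/YAML I/O, unit conversion, fixtures),
`summary_statistics`, `compliance`, `risk_assessment`,
`nonparametric_stats`, `synthetic_data`, `pipeline` + `cli`.
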