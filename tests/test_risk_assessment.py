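import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from hydroq.data_model import AnalyteSpec, DataError, ExposureProfile, Measurement
from hydroq.risk_assessment import (
    DistributionModel,
    RiskSettings,
    chronic_daily_intake,
    fit_distribution,
    hazard_quotient,
    percentile,
    risk_report,
    simulate_hq,
    substitute_censored,
)

CHILDREN = ExposureProfile(group="children", ir=1, ef=365, ed=4, bw=15, at=1460)
ADULTS = ExposureProfile(group="adults", ir=2, ef=365, ed=40, bw=70, at=14600)


class TestChronicDailyIntake:
    def test_hand_arithmetic(self):
        # 38.87 mg/L for a 15 kg child drinking 1 L/day
        assert chronic_daily_intake(38.87, CHILDREN) == pytest.approx(38.87 / 15)
        assert chronic_daily_intake(38.87, CHILDREN) == pytest.approx(2.5913, abs=5e-5)

    def test_zero_concentration(self):
        assert chronic_daily_intake(0.0, CHILDREN) == 0.0

    def test_children_to_adult_ratio(self):
        # (1/15) / (2/70) = 7/3, consistent with printed pairs 1.11 / 4.76E-1
        c = 16.65
        ratio = chronic_daily_intake(c, CHILDREN) / chronic_daily_intake(c, ADULTS)
        assert ratio == pytest.approx(7 / 3, rel=1e-12)
        assert 1.11 / 4.76e-1 == pytest.approx(7 / 3, rel=0.01)

    def test_independent_of_ed_ef_under_constraint(self):
        # AT = ED*EF makes the intake depend on C, IR, BW only — bit-identical
        a = ExposureProfile(group="g", ir=1, ef=365, ed=4, bw=15, at=1460)
        b = ExposureProfile(group="g", ir=1, ef=730, ed=2, bw=15, at=1460)
        for c in (0.28, 5.36, 38.87):
            assert chronic_daily_intake(c, a) == chronic_daily_intake(c, b)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DataError):
            chronic_daily_intake(-1.0, CHILDREN)

    def test_vectorized(self):
        out = chronic_daily_intake(np.array([0.0, 15.0]), CHILDREN)
        assert out == pytest.approx([0.0, 1.0])


class TestHazardQuotient:
    def test_nitrate_children(self):
        assert round(hazard_quotient(1.11, 1.6), 2) == 0.69

    def test_ba_children(self):
        assert hazard_quotient(3.84e-3, 0.2) == pytest.approx(1.92e-2)

    def test_zero(self):
        assert hazard_quotient(0.0, 1.6) == 0.0

    def test_missing_rfd_rejected(self):
        with pytest.raises(DataError):
            hazard_quotient(1.0, None)
        with pytest.raises(DataError):
            hazard_quotient(1.0, 0.0)


class TestSubstituteCensored:
    def test_half_lod(self):
        values = substitute_censored([Measurement(0.14, censored=True)], "half_lod")
        assert values == [0.07]

    def test_lod(self):
        assert substitute_censored([Measurement(0.14, censored=True)], "lod") == [0.14]

    def test_drop(self):
        ms = [Measurement(0.14, censored=True), Measurement(1.0)]
        assert substitute_censored(ms, "drop") == [1.0]

    def test_unknown_rule(self):
        with pytest.raises(DataError):
            substitute_censored([], "zero")


class TestFitDistribution:
    def test_all_equal_collapses_to_degenerate(self):
        ms = [Measurement(5.0)] * 3
        for family in ("empirical_bootstrap", "lognormal", "normal", "degenerate"):
            dist = fit_distribution(ms, family)
            assert dist.family == "degenerate"
            assert dist.params == (5.0,)

    def test_all_censored_with_drop_rejected(self):
        with pytest.raises(DataError):
            fit_distribution([Measurement(0.1, censored=True)], censor_rule="drop")

    def test_parametric_needs_three_distinct(self):
        ms = [Measurement(1.0), Measurement(2.0), Measurement(1.0)]
        with pytest.raises(DataError):
            fit_distribution(ms, "lognormal")

    def test_lognormal_parameter_recovery(self):
        # 5000 draws from lognormal(mu=1, sigma=0.5): MLE within 3 SEs
        rng = np.random.default_rng(42)
        draws = rng.lognormal(1.0, 0.5, size=5000)
        dist = fit_distribution([Measurement(v) for v in draws], "lognormal")
        mu_hat, sigma_hat = dist.params
        se_mu = 0.5 / math.sqrt(5000)
        se_sigma = 0.5 / math.sqrt(2 * 5000)
        assert abs(mu_hat - 1.0) < 3 * se_mu
        assert abs(sigma_hat - 0.5) < 3 * se_sigma

    def test_empirical_stores_substituted_values(self):
        ms = [Measurement(0.14, censored=True), Measurement(1.0), Measurement(2.0)]
        dist = fit_distribution(ms, "empirical_bootstrap", "half_lod")
        assert sorted(dist.params) == [0.07, 1.0, 2.0]

    def test_normal_family_truncates_at_zero(self):
        dist = DistributionModel("normal", (0.5, 2.0), "half_lod")
        draws = dist.sample(np.random.default_rng(0), 5000)
        assert (draws >= 0).all()

    def test_degenerate_sampling(self):
        dist = DistributionModel("degenerate", (3.3,), "half_lod")
        assert (dist.sample(np.random.default_rng(0), 10) == 3.3).all()


class TestPercentile:
    def test_linear_interpolation_rule(self):
        assert percentile(list(range(1, 101)), 95) == pytest.approx(95.05)

    def test_single_sample(self):
        assert percentile([3.7], 5) == 3.7
        assert percentile([3.7], 95) == 3.7

    def test_all_equal(self):
        assert percentile([2.0] * 9, 50) == 2.0

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            percentile([], 50)

    @pytest.mark.parametrize("p", [0, 100, -5, 120])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(DataError):
            percentile([1.0, 2.0], p)

    @given(
        samples=st.lists(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
                         min_size=1, max_size=50),
        p=st.floats(min_value=0.01, max_value=99.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_numpy_linear(self, samples, p):
        assert percentile(samples, p) == pytest.approx(
            float(np.percentile(samples, p, method="linear")), rel=1e-9, abs=1e-9
        )

    @given(samples=st.lists(st.floats(min_value=0, max_value=1e3, allow_nan=False),
                            min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p(self, samples):
        values = [percentile(samples, p) for p in (5, 25, 50, 75, 95)]
        assert values == sorted(values)


class TestSimulateHq:
    def test_degenerate_constant_hq(self):
        dist = DistributionModel("degenerate", (16.65,), "half_lod")
        res = simulate_hq(dist, CHILDREN, rfd=1.6, n_iter=500, seed=3)
        for p, hq in res.hq_percentiles.items():
            assert hq == pytest.approx(0.69375, rel=1e-12)

    def test_monotone_transform_identity(self):
        rng = np.random.default_rng(11)
        dist = fit_distribution([Measurement(v) for v in rng.lognormal(0, 1, 200)],
                                "empirical_bootstrap")
        res = simulate_hq(dist, ADULTS, rfd=0.2, n_iter=2000, seed=5,
                          percentiles=(5, 25, 50, 75, 95))
        for p in res.cdi_percentiles:
            assert res.hq_percentiles[p] == res.cdi_percentiles[p] / 0.2

    def test_percentile_maps_monotone(self):
        dist = DistributionModel("lognormal", (0.0, 1.0), "half_lod")
        res = simulate_hq(dist, CHILDREN, rfd=1.0, n_iter=2000, seed=9,
                          percentiles=(5, 50, 95))
        cdi = [res.cdi_percentiles[p] for p in sorted(res.cdi_percentiles)]
        assert cdi == sorted(cdi)

    def test_lognormal_closed_form_hq95(self):
        mu, sigma, rfd, n = 1.0, 0.5, 1.6, 10_000
        z95 = norm.ppf(0.95)
        q = math.exp(mu + z95 * sigma)
        expected = q * (CHILDREN.ir / CHILDREN.bw) / rfd
        # asymptotic SE of the empirical 95th percentile of a lognormal
        density = norm.pdf(z95) / (q * sigma)
        se_q = math.sqrt(0.95 * 0.05 / n) / density
        se_hq = se_q * (CHILDREN.ir / CHILDREN.bw) / rfd
        dist = DistributionModel("lognormal", (mu, sigma), "half_lod")
        res = simulate_hq(dist, CHILDREN, rfd=rfd, n_iter=n, seed=7)
        assert res.hq_percentiles[95.0] == pytest.approx(expected, abs=3 * se_hq)

    def test_seed_determinism(self):
        dist = DistributionModel("lognormal", (0.5, 0.8), "half_lod")
        a = simulate_hq(dist, CHILDREN, rfd=1.6, n_iter=1000, seed=21)
        b = simulate_hq(dist, CHILDREN, rfd=1.6, n_iter=1000, seed=21)
        assert a == b

    def test_doubling_iterations_stays_within_error(self):
        mu, sigma = 1.0, 0.5
        n = 10_000
        z95 = norm.ppf(0.95)
        q = math.exp(mu + z95 * sigma)
        density = norm.pdf(z95) / (q * sigma)
        se_q = math.sqrt(0.95 * 0.05 / n) / density
        dist = DistributionModel("lognormal", (mu, sigma), "half_lod")
        small = simulate_hq(dist, CHILDREN, rfd=1.0, n_iter=n, seed=13)
        large = simulate_hq(dist, CHILDREN, rfd=1.0, n_iter=2 * n, seed=13)
        scale = CHILDREN.ir / CHILDREN.bw
        assert abs(small.cdi_percentiles[95.0] - large.cdi_percentiles[95.0]) < 3 * se_q * scale

    def test_invalid_percentile_rejected(self):
        dist = DistributionModel("degenerate", (1.0,), "half_lod")
        with pytest.raises(DataError):
            simulate_hq(dist, CHILDREN, rfd=1.0, percentiles=(0, 95))

    def test_n_iter_at_least_one(self):
        dist = DistributionModel("degenerate", (1.0,), "half_lod")
        with pytest.raises(DataError):
            simulate_hq(dist, CHILDREN, rfd=1.0, n_iter=0)


class TestRiskReport:
    def test_fixture_defaults_twelve_rows_none_flagged(self, survey, registry, profiles):
        rows = risk_report(survey, registry, profiles,
                           RiskSettings(n_iter=2000, seed=4))
        assert len(rows) == 12  # 6 analytes with an RfD and detections x 2 groups
        assert {r.analyte for r in rows} == {"nitrate", "nitrite", "Ba", "Fe", "Li", "Mn"}
        assert {r.group for r in rows} == {"children", "adults"}
        assert not any(r.flagged for r in rows)

    def test_be_and_mo_skipped(self, survey, registry, profiles):
        rows = risk_report(survey, registry, profiles, RiskSettings(n_iter=100, seed=0))
        assert not {r.analyte for r in rows} & {"Be", "Mo"}

    def test_artificially_small_rfd_flags(self, survey, registry, profiles):
        tiny = dict(registry)
        spec = registry["nitrate"]
        tiny["nitrate"] = AnalyteSpec(name="nitrate", unit=spec.unit, lod=spec.lod,
                                      loq=spec.loq, rfd=1e-6,
                                      inso_limit=spec.inso_limit, who_limit=spec.who_limit)
        rows = risk_report(survey, tiny, profiles, RiskSettings(n_iter=500, seed=0))
        assert all(r.flagged for r in rows if r.analyte == "nitrate")

    def test_empty_analyte_set(self, registry, profiles):
        assert risk_report([], registry, profiles, RiskSettings(n_iter=10)) == []

    def test_report_determinism(self, survey, registry, profiles):
        settings = RiskSettings(n_iter=500, seed=17)
        assert risk_report(survey, registry, profiles, settings) == risk_report(
            survey, registry, profiles, settings
        )
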