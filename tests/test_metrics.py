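import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from isochamber import metrics


class TestClassifyDaynight:
    @pytest.mark.parametrize("par,expect", [
        (600.0, "day"), (501.0, "day"),
        (0.0, "night"), (19.9, "night"),
        (250.0, "transition"), (500.0, "transition"), (20.0, "transition"),
    ])
    def test_rule(self, par, expect):
        assert metrics.classify_daynight(par) == expect

    def test_negative_par_rejected(self):
        with pytest.raises(ValueError):
            metrics.classify_daynight(-1.0)


def flux_frame(rows):
    return pd.DataFrame(rows, columns=["plant_id", "treatment", "day", "hour", "par", "v"])


class TestAggregate:
    def test_hand_arithmetic(self):
        rows = [(p, "control", 0, 12.0, 600.0, v)
                for p, v in [("C1", 4.0), ("C2", 5.0), ("C3", 6.0)]]
        out = metrics.aggregate(flux_frame(rows), "v", window="daily", mask="day")
        assert len(out) == 1
        assert out["mean"].iloc[0] == pytest.approx(5.0)
        assert out["sd"].iloc[0] == pytest.approx(1.0)
        assert out["n"].iloc[0] == 3 and bool(out["available"].iloc[0])

    def test_identical_plants_zero_sd(self):
        rows = [(p, "control", 0, 12.0, 600.0, 4.2) for p in ("C1", "C2", "C3")]
        out = metrics.aggregate(flux_frame(rows), "v")
        assert out["sd"].iloc[0] == pytest.approx(0.0)

    def test_replicate_display_rule(self):
        # 2 plants -> retained; 1 plant -> unavailable
        rows = [("C1", "control", 0, 12.0, 600.0, 4.0), ("C2", "control", 0, 12.0, 600.0, 5.0),
                ("C1", "control", 1, 12.0, 600.0, 4.0)]
        out = metrics.aggregate(flux_frame(rows), "v").set_index("day")
        assert bool(out.loc[0, "available"]) and out.loc[0, "n"] == 2
        assert not bool(out.loc[1, "available"]) and out.loc[1, "n"] == 1

    def test_plant_first_averaging(self):
        # within-plant mean first: C1 has two records, C2 one
        rows = [("C1", "control", 0, 10.0, 600.0, 2.0), ("C1", "control", 0, 14.0, 600.0, 6.0),
                ("C2", "control", 0, 12.0, 600.0, 8.0)]
        out = metrics.aggregate(flux_frame(rows), "v")
        assert out["mean"].iloc[0] == pytest.approx((4.0 + 8.0) / 2)

    def test_mask_excludes_transition(self):
        rows = [("C1", "control", 0, 12.0, 250.0, 99.0), ("C1", "control", 0, 12.0, 600.0, 1.0),
                ("C2", "control", 0, 12.0, 600.0, 1.0)]
        out = metrics.aggregate(flux_frame(rows), "v", mask="day")
        assert out["mean"].iloc[0] == pytest.approx(1.0)
        night = metrics.aggregate(flux_frame(rows), "v", mask="night")
        assert night.empty


class TestPropagateSd:
    def test_three_four_five(self):
        assert metrics.propagate_sd(3.0, 4.0) == pytest.approx(5.0)

    def test_zero_passthrough(self):
        assert metrics.propagate_sd(0.0, 2.5) == pytest.approx(2.5)

    @given(a=st.floats(0, 1e3), b=st.floats(0, 1e3), s=st.floats(0.01, 100))
    def test_symmetric_homogeneous_dominating(self, a, b, s):
        f = metrics.propagate_sd
        assert f(a, b) == pytest.approx(f(b, a))
        assert f(s * a, s * b) == pytest.approx(s * f(a, b), rel=1e-9)
        assert f(a, b) >= max(a, b) - 1e-12

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            metrics.propagate_sd(-1.0, 2.0)


class TestDroughtEffect:
    def test_equal_means_zero(self):
        assert metrics.drought_effect(4.2, 4.2) == pytest.approx(0.0)

    def test_printed_daytime_assimilation(self):
        assert round(metrics.drought_effect(4.84, 3.19), 1) == -34.1

    def test_printed_discrimination(self):
        assert round(metrics.drought_effect(24.90, 17.05), 1) == -31.5

    def test_zero_control_nan(self):
        assert np.isnan(metrics.drought_effect(0.0, 1.0))


class TestRecoveryDay:
    def test_immediate_satisfaction(self):
        assert metrics.recovery_day([0.0, 0.0], [1.0, 1.0]) == 1

    def test_first_day_effect_plus_sd_nonnegative(self):
        assert metrics.recovery_day([-30.0, -12.0, -4.0], [3.0, 3.0, 5.0]) == 3

    def test_consecutive_rule(self):
        effect = [-30.0, -12.0, -4.0, -6.0, 1.0, 2.0]
        sd = [3.0, 3.0, 5.0, 2.0, 1.0, 1.0]
        assert metrics.recovery_day(effect, sd, consecutive=1) == 3
        assert metrics.recovery_day(effect, sd, consecutive=2) == 5

    def test_level90_mode(self):
        # recovery levels 70, 88, 96 -> first >= 90 on day 3
        assert metrics.recovery_day([-30.0, -12.0, -4.0], mode="level90") == 3
        assert metrics.recovery_day([-30.0, -12.0, -4.0], mode="level90", level=85.0) == 2

    def test_never_met(self):
        assert metrics.recovery_day([-50.0, -40.0], [1.0, 1.0]) is None

    def test_monotone_in_treated_series(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            eff = rng.uniform(-40, 5, 6)
            sd = rng.uniform(0, 5, 6)
            d1 = metrics.recovery_day(eff, sd)
            d2 = metrics.recovery_day(eff + rng.uniform(0, 10, 6).cumsum() * 0 + 5.0, sd)
            if d1 is not None:
                assert d2 is not None and d2 <= d1


def brute_force_rank_sum_p(a, b, alternative):
    """Independent oracle: enumerate assignments counting the U statistic
    (pairwise comparisons), not rank sums."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(grp_a, grp_b):
        return sum(0.5 if x == y else float(x > y) for x in grp_a for y in grp_b)

    u_obs = u_stat(a, b)
    mu = n_a * len(b) / 2.0
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        total += 1
        if alternative == "less":
            hits += u <= u_obs + 1e-9
        elif alternative == "greater":
            hits += u >= u_obs - 1e-9
        else:
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-9
    return hits / total


class TestExactRankSum:
    def test_complete_separation_one_sided(self):
        assert metrics.exact_rank_sum([1, 2, 3], [4, 5, 6], "less") == pytest.approx(0.05)

    def test_identical_groups_two_sided(self):
        assert metrics.exact_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "two-sided") == pytest.approx(1.0)

    def test_enumeration_example(self):
        p = metrics.exact_rank_sum([1, 4, 5], [2, 3, 6], "less")
        assert p == pytest.approx(brute_force_rank_sum_p([1, 4, 5], [2, 3, 6], "less"))

    @settings(max_examples=60, deadline=None)
    @given(
        a=st.lists(st.integers(0, 12), min_size=2, max_size=6),
        b=st.lists(st.integers(0, 12), min_size=2, max_size=6),
        alt=st.sampled_from(["less", "greater", "two-sided"]),
    )
    def test_matches_brute_force_oracle(self, a, b, alt):
        assert metrics.exact_rank_sum(a, b, alt) == pytest.approx(
            brute_force_rank_sum_p(a, b, alt))

    @settings(max_examples=30, deadline=None)
    @given(
        pooled=st.lists(st.floats(0, 100), min_size=6, max_size=12, unique=True),
        n_a=st.integers(3, 6),
    )
    def test_matches_scipy_exact_without_ties(self, pooled, n_a):
        n_a = min(n_a, len(pooled) - 3)
        a, b = pooled[:n_a], pooled[n_a:][:6]
        ours = metrics.exact_rank_sum(a, b, "two-sided")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_groups_rejected(self):
        with pytest.raises(ValueError, match="approximation"):
            metrics.exact_rank_sum(list(range(9)), list(range(9)))


def mm_data(seed, effect=0.0, n_days=9, sd_plant=0.5, sd_day=0.4):
    rng = np.random.default_rng(seed)
    vals, trts, plants = [], [], []
    for trt, ids in (("control", ["C1", "C2", "C3"]), ("drought", ["D1", "D2", "D3"])):
        for p in ids:
            b = rng.normal(0, sd_plant)
            for _ in range(n_days):
                vals.append(5.0 + (effect if trt == "drought" else 0.0) + b + rng.normal(0, sd_day))
                trts.append(trt)
                plants.append(p)
    return vals, trts, plants


class TestTreatmentTest:
    def test_identical_series_zero_estimate(self):
        vals = [4.0, 5.0, 6.0] * 2 + [4.0, 5.0, 6.0] * 2
        trts = ["control"] * 6 + ["drought"] * 6
        plants = ["C1"] * 3 + ["C2"] * 3 + ["D1"] * 3 + ["D2"] * 3
        fit = metrics.treatment_test(vals, trts, plants)
        assert fit.estimate == pytest.approx(0.0, abs=1e-8)

    def test_type_one_error_calibrated(self):
        rej = sum(metrics.treatment_test(*mm_data(s)).p_value < 0.05 for s in range(500))
        assert 0.02 <= rej / 500 <= 0.10

    def test_power_at_prescribed_effect(self):
        # -35 % effect on a mean of 5 with default plant/day noise
        rej = sum(metrics.treatment_test(*mm_data(s, effect=-1.75)).p_value < 0.05
                  for s in range(200))
        assert rej / 200 >= 0.80

    def test_p_decreases_with_effect_size(self):
        ps = []
        for effect in (0.0, -0.9, -1.75):
            pvals = [metrics.treatment_test(*mm_data(s, effect=effect)).p_value
                     for s in range(40)]
            ps.append(np.median(pvals))
        assert ps[0] > ps[1] > ps[2]


class TestCouplingRegression:
    def test_recovers_prescribed_slope(self):
        rng = np.random.default_rng(2)
        x, y, plants = [], [], []
        for p in ("D1", "D2", "D3"):
            inter = rng.normal(-25.5, 0.2)
            xs = rng.uniform(15, 26, 12)
            x += list(xs)
            y += list(inter - 0.15 * (xs - 24.9) + rng.normal(0, 0.05, 12))
            plants += [p] * 12
        fit = metrics.coupling_regression(x, y, plants)
        assert fit.estimate == pytest.approx(-0.15, abs=0.02)
        assert fit.p_value < 1e-6

    def test_constant_predictor_raises(self):
        with pytest.raises(ValueError, match="constant"):
            metrics.coupling_regression([1.0] * 9, list(range(9)), ["P"] * 9)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            metrics.coupling_regression([1.0, 2.0], [1.0, 2.0], ["P", "P"])

    def test_null_slope_rarely_significant(self):
        hits = 0
        n = 60
        for s in range(n):
            rng = np.random.default_rng(1000 + s)
            x, y, plants = [], [], []
            for p in ("D1", "D2", "D3"):
                xs = rng.uniform(15, 26, 10)
                x += list(xs)
                y += list(rng.normal(-25.5, 0.3, 10))
                plants += [p] * 10
            hits += metrics.coupling_regression(x, y, plants).p_value < 0.05
        assert hits / n <= 0.10


class TestFractionEnrichment:
    def test_neutral_fraction_printed_value(self):
        diff, _ = metrics.fraction_enrichment([-25.55], [-28.04])
        assert diff == pytest.approx(2.49, abs=1e-9)

    def test_water_soluble_printed_value(self):
        diff, _ = metrics.fraction_enrichment([-27.21], [-28.63])
        assert diff == pytest.approx(1.42, abs=1e-9)

    def test_identical_groups_zero(self):
        diff, se = metrics.fraction_enrichment([-28.0, -28.0], [-28.0, -28.0])
        assert diff == 0.0 and se == 0.0

    def test_se_quadrature(self):
        t = [1.0, 2.0, 3.0]
        c = [0.0, 0.0, 6.0]
        _, se = metrics.fraction_enrichment(t, c)
        se_t = np.std(t, ddof=1) / np.sqrt(3)
        se_c = np.std(c, ddof=1) / np.sqrt(3)
        assert se == pytest.approx(np.hypot(se_t, se_c))


class TestEffectSeries:
    def test_zero_noise_effect_exact(self):
        rows = []
        for day in range(3):
            for p, trt, v in [("C1", "control", 4.0), ("C2", "control", 4.0),
                              ("D1", "drought", 3.0), ("D2", "drought", 3.0)]:
                rows.append((p, trt, day, 12.0, 600.0, v))
        series = metrics.effect_series(flux_frame(rows), "v")
        assert np.allclose(series["effect"], -25.0)
        assert np.allclose(series["sd_diff"], 0.0)
        assert series["available"].all()
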