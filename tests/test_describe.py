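import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdpcast.describe import (
    AnovaIneligible,
    AnovaResult,
    batch_monthly_anova,
    bh_adjust,
    categorize_pcc,
    cross_crop_pcc,
    di_distribution_summary,
    monthly_anova,
    size_bin_report,
)
from cdpcast.simulate import SyntheticConfig, generate_panel
from cdpcast.survey import aggregate_monthly_max

from conftest import make_records, make_series


class TestSizeBinReport:
    def test_single_small_combo(self):
        records = make_records([("a", "b", "c", 2001, m, 1.0) for m in range(1, 6)])
        rep = size_bin_report(records, "crop_cdp_prefecture")
        assert rep.proportions["<=10"] == 1.0
        assert rep.total == 1

    def test_one_combo_per_bin(self):
        rows = []
        for i, n in enumerate((5, 50, 500, 5000)):
            for j in range(n):
                rows.append((f"crop{i}", "b", "c", 2000 + j // 12, 1 + j % 12, 1.0))
        rep = size_bin_report(make_records(rows), "crop")
        assert all(v == pytest.approx(0.25) for v in rep.proportions.values())

    def test_pooling_at_coarser_level(self):
        # two prefecture-level combos of 60 samples each pool to 120 at crop level
        rows = [("a", "b", f"p{k}", 2000 + j // 12, 1 + j % 12, 1.0)
                for k in (1, 2) for j in range(60)]
        records = make_records(rows)
        by_combo = size_bin_report(records, "crop_cdp_prefecture")
        by_crop = size_bin_report(records, "crop")
        assert by_combo.counts["(10,100]"] == 2
        assert by_crop.counts["(100,1000]"] == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            size_bin_report([], "crop")

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            size_bin_report(make_records([("a", "b", "c", 2001, 1, 1.0)]), "region")


class TestDIDistribution:
    def test_hand_counted_fractions(self):
        records = make_records(
            [("a", "b", "c", 2001, 1, 0.5), ("a", "b", "c", 2001, 2, 2.0),
             ("a", "b", "c", 2001, 3, 7.0)]
        )
        s = di_distribution_summary(records, thresholds=(1, 3, 5, 10))
        assert s.cumulative_fractions == pytest.approx((1 / 3, 2 / 3, 2 / 3, 1.0))

    def test_all_zero_values(self):
        records = make_records([("a", "b", "c", 2001, m, 0.0) for m in (1, 2)])
        s = di_distribution_summary(records)
        assert all(f == 1.0 for f in s.cumulative_fractions)

    def test_heap_fraction_exact_equality(self):
        records = make_records(
            [("a", "b", "c", 2001, 1, 1.0), ("a", "b", "c", 2001, 2, 1.0),
             ("a", "b", "c", 2001, 3, 2.0)]
        )
        s = di_distribution_summary(records, heap_points=(1.0,))
        assert s.heap_fractions == pytest.approx((2 / 3,))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            di_distribution_summary([])


class TestCategorizePcc:
    @pytest.mark.parametrize(
        "pcc,expected",
        [(0.7, "strong"), (0.9, "strong"), (0.4, "moderate"), (0.69, "moderate"),
         (0.39, "weak"), (0.0, "weak"), (-0.9, "weak")],
    )
    def test_boundaries_as_printed(self, pcc, expected):
        assert categorize_pcc(pcc) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_pcc(1.5)


class TestCrossCropPcc:
    @staticmethod
    def _pair(obs_a, obs_b):
        a = make_series(obs_a, crop="cuke", cdp="mildew", pref="p")
        b = make_series(obs_b, crop="straw", cdp="mildew", pref="p")
        return [a, b]

    def test_identical_series_strong(self):
        obs = {(2001, m): float(m) for m in range(1, 7)}
        (rec,) = cross_crop_pcc(self._pair(obs, dict(obs)))
        assert rec.pcc == pytest.approx(1.0)
        assert rec.category == "strong"
        assert rec.low_n  # 6 pairs < 10

    def test_perfect_anticorrelation(self):
        a = {(2001, 1): 1.0, (2001, 2): 2.0, (2001, 3): 3.0}
        b = {(2001, 1): 3.0, (2001, 2): 2.0, (2001, 3): 1.0}
        (rec,) = cross_crop_pcc(self._pair(a, b))
        assert rec.pcc == pytest.approx(-1.0)
        assert rec.category == "weak"

    def test_matches_brute_force_formula(self):
        xa = [1.0, 2.0, 3.0, 4.0, 5.0]
        xb = [2.0, 1.0, 4.0, 3.0, 5.0]
        a = {(2001, m + 1): v for m, v in enumerate(xa)}
        b = {(2001, m + 1): v for m, v in enumerate(xb)}
        (rec,) = cross_crop_pcc(self._pair(a, b))
        # textbook formula, computed independently of scipy
        ma, mb = sum(xa) / 5, sum(xb) / 5
        num = sum((x - ma) * (y - mb) for x, y in zip(xa, xb))
        den = (sum((x - ma) ** 2 for x in xa) * sum((y - mb) ** 2 for y in xb)) ** 0.5
        assert rec.pcc == pytest.approx(num / den, abs=1e-12)
        assert rec.n_pairs == 5

    def test_constant_series_skipped(self):
        a = {(2001, m): 5.0 for m in range(1, 5)}
        b = {(2001, m): float(m) for m in range(1, 5)}
        assert cross_crop_pcc(self._pair(a, b)) == []

    def test_complete_case_matching(self):
        # unmatched months must not affect the coefficient
        a = {(2001, 1): 1.0, (2001, 2): 2.0, (2001, 3): 3.0, (2001, 9): 50.0}
        b = {(2001, 1): 1.0, (2001, 2): 2.0, (2001, 3): 3.0, (2002, 4): 9.0}
        (rec,) = cross_crop_pcc(self._pair(a, b))
        assert rec.n_pairs == 3
        assert rec.pcc == pytest.approx(1.0)

    def test_symmetry_under_crop_swap(self):
        a = make_series({(2001, m): float(m * m) for m in range(1, 6)},
                        crop="zzz", cdp="mildew", pref="p")
        b = make_series({(2001, m): float(m) for m in range(1, 6)},
                        crop="aaa", cdp="mildew", pref="p")
        (r1,) = cross_crop_pcc([a, b])
        (r2,) = cross_crop_pcc([b, a])
        assert r1 == r2

    def test_different_cdp_or_prefecture_not_paired(self):
        a = make_series({(2001, 1): 1.0, (2001, 2): 2.0}, crop="a", cdp="x", pref="p")
        b = make_series({(2001, 1): 1.0, (2001, 2): 2.0}, crop="b", cdp="y", pref="p")
        c = make_series({(2001, 1): 1.0, (2001, 2): 2.0}, crop="c", cdp="x", pref="q")
        assert cross_crop_pcc([a, b, c]) == []


class TestMonthlyAnova:
    def test_identical_groups_f_zero(self):
        s = make_series({(y, m): 4.0 for y in (2001, 2002) for m in (4, 7)})
        r = monthly_anova(s)
        assert isinstance(r, AnovaResult)
        assert r.f_stat == 0.0
        assert r.p_value == 1.0

    def test_hand_computed_f(self):
        # months 4: {1,2,3}, 7: {7,8,9}; SSB=54 (df 1), SSW=4 (df 4) -> F=54
        obs = {(2000 + i, 4): v for i, v in enumerate((1.0, 2.0, 3.0))}
        obs |= {(2000 + i, 7): v for i, v in enumerate((7.0, 8.0, 9.0))}
        r = monthly_anova(make_series(obs))
        assert isinstance(r, AnovaResult)
        assert r.f_stat == pytest.approx(54.0)
        assert r.p_value == pytest.approx(0.0018262606682599833, rel=1e-9)
        assert r.n == 6 and r.n_months == 2

    def test_single_month_ineligible(self):
        s = make_series({(2000 + i, 5): float(i) for i in range(6)})
        r = monthly_anova(s)
        assert isinstance(r, AnovaIneligible)
        assert "single month" in r.reason

    def test_too_few_per_month_ineligible(self):
        s = make_series({(2001, 4): 1.0, (2001, 7): 2.0, (2002, 7): 3.0})
        r = monthly_anova(s)
        assert isinstance(r, AnovaIneligible)


def bh_brute_force(p):
    """Step-up formula from first principles."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_three_ascending(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_capped_at_one(self):
        assert bh_adjust([0.5, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_brute_force(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    @given(
        st.lists(st.floats(0.001, 1, allow_nan=False), min_size=2, max_size=20),
        st.integers(0, 19),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_monotone_in_raw_p(self, p, idx):
        """Raising any raw p never lowers any adjusted p."""
        idx = idx % len(p)
        base = bh_adjust(p)
        bumped = list(p)
        bumped[idx] = min(1.0, bumped[idx] * 1.5)
        assert (bh_adjust(bumped) >= base - 1e-12).all()

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(0, 1, 30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)


class TestSeasonalityScreening:
    """Joint generator + ANOVA behaviour on synthetic panels."""

    def test_strong_seasonality_detected(self):
        cfg = SyntheticConfig.calibrated(
            n_combos=60,
            period_sampler={12: 1.0},
            frequency_sampler={10: 1.0},
            month_effect_amplitude=2.5,
            heap_probs=(0, 0, 0, 0),
        )
        records, _ = generate_panel(cfg, seed=21)
        results, skipped = batch_monthly_anova(aggregate_monthly_max(records))
        assert not skipped
        frac = np.mean([r.p_adjusted < 0.01 for r in results])
        assert frac >= 0.95

    def test_no_seasonality_fdr_controlled(self):
        cfg = SyntheticConfig.calibrated(
            n_combos=300,
            period_sampler={8: 1.0},
            frequency_sampler={6: 1.0},
            month_effect_amplitude=0.0,
            heap_probs=(0, 0, 0, 0),
        )
        records, _ = generate_panel(cfg, seed=22)
        results, _ = batch_monthly_anova(aggregate_monthly_max(records))
        assert len(results) == 300
        frac = np.mean([r.p_adjusted < 0.01 for r in results])
        sd = np.sqrt(0.01 * 0.99 / len(results))
        assert frac <= 0.01 + 3 * sd
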