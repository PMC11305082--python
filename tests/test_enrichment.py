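import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sipef.enrichment import (
    EFSeries,
    HeavyShare,
    anova_oneway,
    anova_time,
    classify_enriched,
    ef_pairs,
    ef_timecourse,
    heavy_share,
)
from sipef.errors import DataLossWarning

from conftest import abundance_from_shares, full_design_sheet


def share(p, defined=True, isotope="13C", rep=1):
    return HeavyShare("g", "ST", isotope, rep, 0, p, defined)


def naive_ef_pairs(p13, p12):
    """Independent oracle: explicit double loop over defined replicates."""
    out = []
    for a in p13:
        if not a.defined:
            continue
        for b in p12:
            if not b.defined:
                continue
            out.append(a.p - b.p)
    return np.array(out)


class TestHeavyShare:
    def _ab_sheet(self, ra_heavy, ra_light):
        sheet = full_design_sheet()
        shares = {"ST_13C_r1_d0_heavy": ra_heavy, "ST_13C_r1_d0_light": ra_light}
        return abundance_from_shares(sheet, shares), sheet

    def test_quotient(self):
        ab, sheet = self._ab_sheet(0.30, 0.10)
        hs = heavy_share(ab, sheet, "gX", "ST", "13C", 1, 0)
        assert hs.defined and hs.p == pytest.approx(0.75)

    def test_absent_from_heavy_pool_gives_zero(self):
        ab, sheet = self._ab_sheet(0.0, 0.20)
        hs = heavy_share(ab, sheet, "gX", "ST", "13C", 1, 0)
        assert hs.defined and hs.p == 0.0

    def test_absent_from_both_pools_is_undefined(self):
        ab, sheet = self._ab_sheet(0.0, 0.0)
        hs = heavy_share(ab, sheet, "gX", "ST", "13C", 1, 0)
        assert not hs.defined

    def test_missing_pooled_sample_warns_and_is_undefined(self):
        ab, sheet = self._ab_sheet(0.30, 0.10)
        short = [m for m in sheet if m.sample_id != "ST_13C_r1_d0_light"]
        with pytest.warns(DataLossWarning):
            hs = heavy_share(ab, short, "gX", "ST", "13C", 1, 0)
        assert not hs.defined


class TestEfPairs:
    def test_maximal_labelling(self):
        out = ef_pairs([share(1)] * 3, [share(0, isotope="12C")] * 3)
        assert out == pytest.approx(np.ones(9))

    def test_null_case(self):
        out = ef_pairs([share(0.3)] * 3, [share(0.3, isotope="12C")] * 3)
        assert out == pytest.approx(np.zeros(9))

    def test_hand_enumerated_combinations_row_major(self):
        p13 = [share(0.6), share(0.8)]
        p12 = [share(0.1, isotope="12C"), share(0.3, isotope="12C")]
        out = ef_pairs(p13, p12)
        assert out == pytest.approx([0.5, 0.3, 0.7, 0.5])
        assert out.mean() == pytest.approx(0.5)

    def test_undefined_replicates_skipped(self):
        p13 = [share(0.6), share(math.nan, defined=False), share(0.8)]
        p12 = [share(0.1, isotope="12C"), share(math.nan, defined=False, isotope="12C")]
        out = ef_pairs(p13, p12)
        assert out == pytest.approx([0.5, 0.7])

    def test_no_defined_pair_warns_and_returns_empty(self):
        with pytest.warns(DataLossWarning):
            out = ef_pairs([share(math.nan, defined=False)], [share(0.5, isotope="12C")])
        assert out.size == 0

    def test_matches_naive_double_loop_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n13, n12 = rng.integers(1, 4, size=2)
            p13 = [share(rng.uniform(), defined=rng.uniform() > 0.2) for _ in range(n13)]
            p12 = [
                share(rng.uniform(), defined=rng.uniform() > 0.2, isotope="12C")
                for _ in range(n12)
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DataLossWarning)
                fast = ef_pairs(p13, p12)
            assert fast == pytest.approx(naive_ef_pairs(p13, p12), abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=3),
    st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=3),
)
def test_ef_is_bounded(p13_vals, p12_vals):
    out = ef_pairs(
        [share(p) for p in p13_vals],
        [share(p, isotope="12C") for p in p12_vals],
    )
    assert np.all(out >= -1.0) and np.all(out <= 1.0)


class TestAnovaOneway:
    def test_identical_values_in_every_group(self):
        f, p = anova_oneway([np.full(3, 0.2), np.full(3, 0.2)])
        assert (f, p) == (0.0, 1.0)

    def test_complete_separation(self):
        f, p = anova_oneway([np.zeros(3), np.ones(3)])
        assert p < 0.001

    def test_hand_computed_f_statistic(self):
        # SSB = 1.5, MSW = 1 -> F = 1.5
        f, p = anova_oneway([np.array([1.0, 2, 3]), np.array([2.0, 3, 4])])
        assert f == pytest.approx(1.5)


def make_series(shares13_by_day, shares12_by_day, heavy_ra=None):
    days = sorted(shares13_by_day)
    pairs, s13, s12 = [], [], []
    for d in days:
        a = np.asarray(shares13_by_day[d], dtype=float)
        b = np.asarray(shares12_by_day[d], dtype=float)
        pairs.append(np.subtract.outer(a, b).ravel())
        s13.append(a)
        s12.append(b)
    return EFSeries(
        genus="g",
        soil="ST",
        days=days,
        pairs=pairs,
        heavy_ra_mean=heavy_ra or [0.02] * len(days),
        shares13=s13,
        shares12=s12,
    )


class TestAnovaTime:
    def test_constant_shares_give_p_one(self):
        s = make_series({d: [0.4] * 3 for d in (0, 7)}, {d: [0.4] * 3 for d in (0, 7)})
        assert anova_time(s) == 1.0

    def test_time_varying_labelling_is_significant(self):
        rng = np.random.default_rng(0)
        s13 = {d: 0.4 + lam + rng.normal(0, 0.01, 3) for d, lam in [(0, 0), (7, 0.3), (15, 0.5)]}
        s12 = {d: 0.4 + rng.normal(0, 0.01, 3) for d in (0, 7, 15)}
        assert anova_time(make_series(s13, s12)) < 0.001

    def test_single_day_is_undefined(self):
        s = make_series({0: [0.1, 0.2, 0.3]}, {0: [0.1, 0.2, 0.3]})
        assert math.isnan(anova_time(s))

    def test_pairs_method_matches_one_way_anova(self):
        s = make_series(
            {0: [0.1, 0.2, 0.3], 7: [0.5, 0.6, 0.7]},
            {0: [0.1, 0.2, 0.3], 7: [0.1, 0.2, 0.3]},
        )
        expected = anova_oneway(s.pairs)[1]
        assert anova_time(s, method="pairs") == pytest.approx(expected)

    def test_interaction_test_has_nominal_size_under_null(self):
        """Calibration: uncorrelated shares reject at roughly alpha."""
        rng = np.random.default_rng(1)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            s13 = {d: rng.uniform(0.3, 0.5, 3) for d in (0, 7, 15, 30)}
            s12 = {d: rng.uniform(0.3, 0.5, 3) for d in (0, 7, 15, 30)}
            if anova_time(make_series(s13, s12)) < 0.05:
                rejections += 1
        assert rejections / n_sim < 0.09  # ~3 SE above nominal 0.05


class TestClassifyEnriched:
    def test_inoculum_like_series_is_enriched(self):
        # day-0 EF ~0.42 decaying to ~0.09, strongly time-varying
        rng = np.random.default_rng(2)
        s13 = {0: 0.92 + rng.normal(0, 0.005, 3), 7: 0.75 + rng.normal(0, 0.005, 3),
               15: 0.62 + rng.normal(0, 0.005, 3), 30: 0.59 + rng.normal(0, 0.005, 3)}
        s12 = {d: 0.5 + rng.normal(0, 0.005, 3) for d in (0, 7, 15, 30)}
        out = classify_enriched(make_series(s13, s12))
        assert out.enriched
        assert out.day_enriched[0]
        assert out.means[0] == pytest.approx(0.42, abs=0.02)

    def test_below_threshold_everywhere_is_not_enriched(self):
        # EF changes significantly through time but never exceeds 0.015
        rng = np.random.default_rng(3)
        ef_by_day = {0: 0.014, 7: 0.010, 15: 0.005, 30: 0.0}
        s13 = {d: 0.5 + ef + rng.normal(0, 1e-5, 3) for d, ef in ef_by_day.items()}
        s12 = {d: 0.5 + rng.normal(0, 1e-5, 3) for d in ef_by_day}
        out = classify_enriched(make_series(s13, s12))
        assert out.anova_p < 0.05
        assert all(m < 0.015 for m in out.means)
        assert not out.enriched

    def test_high_ef_without_time_change_is_not_enriched(self):
        rng = np.random.default_rng(4)
        s13 = {d: 0.8 + rng.normal(0, 0.02, 3) for d in (0, 7, 15, 30)}
        s12 = {d: 0.5 + rng.normal(0, 0.02, 3) for d in (0, 7, 15, 30)}
        out = classify_enriched(make_series(s13, s12))
        assert out.anova_p > 0.05
        assert not out.enriched

    def test_display_flag_follows_heavy_abundance(self):
        s = make_series(
            {0: [0.6] * 3, 7: [0.9] * 3}, {0: [0.5] * 3, 7: [0.5] * 3},
            heavy_ra=[0.004, 0.02],
        )
        out = classify_enriched(s)
        assert out.day_displayed == [False, True]


class TestEfTimecourse:
    def _shares_map(self, sheet, p13_by_day, p12=0.4, lost=()):
        shares = {}
        for m in sheet:
            if m.soil != "ST" or m.sample_id in lost:
                continue
            p = p13_by_day[m.day] if m.isotope == "13C" else p12
            ra = 0.05
            shares[m.sample_id] = ra * (p if m.pool == "heavy" else 1 - p) * 2
        return shares

    def test_equal_shares_give_zero_means(self):
        sheet = full_design_sheet()
        ab = abundance_from_shares(sheet, self._shares_map(sheet, {d: 0.4 for d in (0, 7, 15, 30)}))
        series = ef_timecourse(ab, sheet, "gX", "ST")
        assert series.means == pytest.approx([0.0] * 4, abs=1e-12)
        assert series.n_pairs == [9, 9, 9, 9]

    def test_decreasing_labelling_gives_decreasing_means(self):
        sheet = full_design_sheet()
        p13 = {0: 0.9, 7: 0.7, 15: 0.55, 30: 0.45}
        ab = abundance_from_shares(sheet, self._shares_map(sheet, p13))
        series = ef_timecourse(ab, sheet, "gX", "ST")
        assert all(a > b for a, b in zip(series.means, series.means[1:]))

    def test_lost_replicate_reduces_n_pairs_to_six(self):
        sheet = full_design_sheet()
        lost = ("ST_13C_r2_d15_heavy",)
        shares = self._shares_map(sheet, {d: 0.6 for d in (0, 7, 15, 30)}, lost=lost)
        sheet = [m for m in sheet if m.sample_id not in lost]
        ab = abundance_from_shares(sheet, shares)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DataLossWarning)
            series = ef_timecourse(ab, sheet, "gX", "ST")
        assert series.n_pairs == [9, 9, 6, 9]

    def test_one_sign_mean_keeps_sign_after_replicate_loss(self):
        """Removing a 13C replicate never flips a same-sign day mean."""
        sheet = full_design_sheet()
        shares = self._shares_map(sheet, {d: 0.7 for d in (0, 7, 15, 30)})
        ab = abundance_from_shares(sheet, shares)
        full = ef_timecourse(ab, sheet, "gX", "ST")
        reduced_sheet = [
            m for m in sheet
            if not (m.soil == "ST" and m.isotope == "13C" and m.replicate == 2 and m.day == 7)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DataLossWarning)
            reduced = ef_timecourse(ab, reduced_sheet, "gX", "ST")
        assert reduced.n_pairs[1] == 6
        assert np.sign(reduced.means[1]) == np.sign(full.means[1])

    def test_unknown_genus_raises(self):
        sheet = full_design_sheet()
        ab = abundance_from_shares(sheet, {})
        with pytest.raises(KeyError):
            ef_timecourse(ab, sheet, "nope", "ST")
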