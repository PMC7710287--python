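import itertools

import numpy as np
import pytest
from scipy import stats

from vvdyn.cohort import Cohort
from vvdyn.vvevents import (
    chi_square_2x2,
    classify_contraction_status,
    coefficient_of_variation,
    cohort_median_change,
    detect_interval_changes,
    estimate_normal_variation_threshold,
    mann_whitney_u,
    percent_change_from_baseline,
    stratify_cohort,
    two_sample_t,
    wilcoxon_signed_rank,
)
from conftest import make_subject
from helpers_oracles import brute_classify, brute_mannwhitney, brute_wilcoxon_p


class TestPercentChange:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([100, 130], [0.0, 30.0]),
            ([50, 50, 50], [0.0, 0.0, 0.0]),
            ([33500, 33784], [0.0, 0.84776]),  # the published group medians
        ],
    )
    def test_examples(self, series, expected):
        np.testing.assert_allclose(
            percent_change_from_baseline(series), expected, atol=1e-4
        )

    def test_nonpositive_or_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change_from_baseline([0.0, 10.0])
        with pytest.raises(ValueError):
            percent_change_from_baseline([np.nan, 10.0])
        with pytest.raises(ValueError):
            percent_change_from_baseline([10.0])


class TestThresholdEstimate:
    def test_cohort_maximum_of_subject_maxima(self):
        cohort = Cohort(
            subjects=[
                make_subject("a", group="healthy", vv=[100, 103.1]),
                make_subject("b", group="healthy", vv=[100, 94.2, 100]),
                make_subject("c", group="healthy", vv=[100, 100, 104.2]),
            ]
        )
        est = estimate_normal_variation_threshold(cohort)
        assert est.value == pytest.approx(5.8)
        assert sorted(est.per_subject_maxima) == pytest.approx([3.1, 4.2, 5.8])
        assert est.source == "estimated"

    def test_constant_subject_warns_about_degenerate_zero(self):
        cohort = Cohort(subjects=[make_subject("a", group="healthy", vv=[100, 100])])
        with pytest.warns(UserWarning, match="degenerate"):
            est = estimate_normal_variation_threshold(cohort)
        assert est.value == 0.0

    def test_published_band_used_without_healthy_data(self):
        est = estimate_normal_variation_threshold(None)
        assert est.value == 6.0 and est.source == "fixed"


class TestIntervalEvents:
    def test_single_expansion(self):
        events = detect_interval_changes([0, 8, 8], 6.0)
        assert len(events) == 1
        e = events[0]
        assert (e.start, e.end, e.direction) == (0, 1, "expansion")
        assert e.magnitude == pytest.approx(8.0)

    def test_subthreshold_run_gives_no_event(self):
        assert detect_interval_changes([0, 3, 5], 6.0) == []

    def test_expansion_then_two_interval_contraction(self):
        events = detect_interval_changes([0, 10, 4, -1], 6.0)
        assert [(e.direction, round(e.magnitude)) for e in events] == [
            ("expansion", 10),
            ("contraction", -11),
        ]
        assert (events[1].start, events[1].end) == (1, 3)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_interval_changes([0.0], 6.0)


class TestContractionClassifier:
    @pytest.mark.parametrize(
        "pct, status, expansion_only",
        [
            ([0, 10, 6, 2, 2], "contracting", False),   # 8-point drop over 2 intervals
            ([0, 7, 14, 15], "noncontracting", True),   # monotone rise
            ([0, 10, 3, 9, 2], "noncontracting", False),  # only 1-interval drops
        ],
    )
    def test_reference_traces(self, pct, status, expansion_only):
        got_status, got_exp_only, _ = classify_contraction_status(pct, 6.0, 2)
        assert got_status == status
        assert got_exp_only == expansion_only

    def test_agrees_with_exhaustive_window_search_on_grid_traces(self):
        grid = [-8.0, -3.0, 0.0, 3.0, 8.0]
        for length in range(2, 6):
            for tail in itertools.product(grid, repeat=length - 1):
                pct = [0.0, *tail]
                status, _, max_c = classify_contraction_status(pct, 6.0, 2)
                want_contracting, want_max_c = brute_classify(pct, 6.0, 2)
                assert (status == "contracting") == want_contracting, pct
                assert max_c == pytest.approx(want_max_c), pct

    def test_agrees_with_oracle_on_random_longer_traces(self, rng):
        grid = np.array([-9, -5, -2, 0, 2, 5, 9], dtype=float)
        for _ in range(800):
            length = rng.integers(6, 9)
            pct = np.concatenate([[0.0], rng.choice(grid, size=length - 1)])
            status, _, max_c = classify_contraction_status(pct, 6.0, 2)
            want_contracting, want_max_c = brute_classify(pct, 6.0, 2)
            assert (status == "contracting") == want_contracting
            assert max_c == pytest.approx(want_max_c)

    def test_raising_threshold_never_creates_contracting(self, rng):
        grid = np.array([-9, -5, -2, 0, 2, 5, 9], dtype=float)
        for _ in range(300):
            pct = np.concatenate([[0.0], rng.choice(grid, size=6)])
            lo = classify_contraction_status(pct, 6.0, 2)[0]
            hi = classify_contraction_status(pct, 9.0, 2)[0]
            assert not (lo == "noncontracting" and hi == "contracting")

    def test_zero_change_month_does_not_break_a_contraction(self):
        status, _, _ = classify_contraction_status([0, 10, 6, 6, 2], 6.0, 2)
        assert status == "contracting"


class TestCoefficientOfVariation:
    def test_examples(self):
        assert coefficient_of_variation([10, 10, 10]) == 0.0
        assert coefficient_of_variation([9, 11]) == pytest.approx(14.1421, abs=1e-4)

    def test_scale_invariance(self, rng):
        x = rng.uniform(10, 20, size=8)
        assert coefficient_of_variation(x) == pytest.approx(coefficient_of_variation(3.7 * x))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestStratification:
    def test_flat_cohort_is_all_noncontracting(self):
        cohort = Cohort(subjects=[make_subject(f"s{i}", vv=[100.0] * 5) for i in range(4)])
        result = stratify_cohort(cohort)
        summary = result.summary()
        assert summary["n_contracting"] == 0
        assert summary["n_noncontracting"] == 4
        assert summary["n_expansion_only"] == 0

    def test_partition_is_disjoint_and_exhaustive(self):
        traces = [[100, 110, 106, 102, 102], [100, 107, 114, 115], [100, 110, 103, 109, 102]]
        cohort = Cohort(subjects=[make_subject(f"s{i}", vv=t) for i, t in enumerate(traces)])
        result = stratify_cohort(cohort)
        assert len(result.contracting_ids) == 1
        assert len(result.noncontracting_ids) == 2
        assert set(result.contracting_ids) | set(result.noncontracting_ids) == {"s0", "s1", "s2"}
        assert not set(result.contracting_ids) & set(result.noncontracting_ids)

    def test_missing_vv_excluded(self):
        cohort = Cohort(
            subjects=[
                make_subject("ok", vv=[100, 101, 99]),
                make_subject("gap", vv=[100, np.nan, 99]),
            ]
        )
        result = stratify_cohort(cohort)
        assert result.excluded == ["gap"]
        assert [p.subject_id for p in result.profiles] == ["ok"]

    def test_lollipop_coordinates_cover_every_scan(self):
        cohort = Cohort(subjects=[make_subject("a", vv=[100, 104, 98])])
        frame = stratify_cohort(cohort).lollipop_frame()
        assert len(frame) == 3
        assert frame["pct_change"].iloc[0] == 0.0


class TestWilcoxon:
    def test_three_positive_units(self):
        _, p = wilcoxon_signed_rank([1.0, 1.0, 1.0])
        assert p == pytest.approx(0.25)

    def test_antisymmetric_pair(self):
        _, p = wilcoxon_signed_rank([1.0, -1.0])
        assert p == pytest.approx(1.0)

    def test_identical_pairs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([2.0, 3.0], [2.0, 3.0])

    def test_exact_p_matches_sign_flip_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 9))
            d = rng.integers(-5, 6, size=n).astype(float)
            if np.all(d == 0):
                continue
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(brute_wilcoxon_p(d), abs=1e-12)

    def test_large_sample_matches_normal_approximation(self, rng):
        d = rng.normal(0.3, 1.0, size=40)
        w, p = wilcoxon_signed_rank(d)
        res = stats.wilcoxon(d, correction=False, method="approx")
        assert p == pytest.approx(res.pvalue, rel=1e-10)


class TestMannWhitney:
    def test_complete_separation_of_two_pairs(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(20):
            a = rng.permutation(100)[: int(rng.integers(3, 7))].astype(float)
            b = rng.permutation(100)[100 - int(rng.integers(3, 7)) :].astype(float) + 0.5
            u, p = mann_whitney_u(a, b)
            u_brute, p_brute = brute_mannwhitney(a, b)
            assert u == pytest.approx(u_brute)
            assert p == pytest.approx(p_brute, abs=1e-12)

    def test_larger_shift_never_raises_p(self, rng):
        a = rng.normal(size=8)
        b0 = rng.normal(size=8)
        ps = [mann_whitney_u(a, b0 + shift)[1] for shift in np.linspace(0, 4, 9)]
        assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(len(ps) - 1))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestTAndChiSquare:
    def test_identical_samples_give_zero_t(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_balanced_table_gives_zero_chi2(self):
        chi2, p = chi_square_2x2([[5, 5], [5, 5]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_diagonal_table_formula(self):
        chi2, _ = chi_square_2x2([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)  # n(ad-bc)^2 / (r1 r2 c1 c2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


def test_group_median_change_reports_both_percent_definitions():
    baseline = np.array([27028.0, 33500.0, 39468.0])
    final = np.array([27953.0, 33784.0, 41185.0])
    out = cohort_median_change(baseline, final)
    assert out["median_difference"] == pytest.approx(284.0)
    assert out["pct_of_baseline_median"] == pytest.approx(0.84776, abs=1e-4)
    assert out["median_subject_pct_change"] != out["pct_of_baseline_median"]
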