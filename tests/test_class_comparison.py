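"""Contingency tables, Yates chi-square, BH, rank-sum and the compare path."""

import numpy as np
import pytest
from scipy import stats

from idpcmp.class_comparison import (
    ContingencyTable,
    bh_adjust,
    build_contingency,
    chi2_yates,
    compare_classes,
    excess_filter,
    rank_sum_test,
)
from idpcmp.disorder import DisorderMetrics
from idpcmp.errors import DataError

from conftest import make_annotations


def table(d_a, nd_a, d_b, nd_b):
    return ContingencyTable("GO:t", d_a, nd_a, d_b, nd_b)


class TestBuildContingency:
    def _annotations(self):
        ann_a = make_annotations("a", {p: {"GO:t"} for p in ("p1", "p2")},
                                 expanded=True)
        ann_b = make_annotations("b", {q: {"GO:t"} for q in ("q1", "q2", "q3")},
                                 expanded=True)
        return ann_a, ann_b

    def test_counts(self):
        ann_a, ann_b = self._annotations()
        t = build_contingency(
            "GO:t",
            {"p1": True, "p2": False},
            {"q1": True, "q2": True, "q3": False},
            ann_a, ann_b,
        )
        assert (t.d_a, t.nd_a, t.d_b, t.nd_b) == (1, 1, 2, 1)

    def test_all_true_gives_zero_nd_cells(self):
        ann_a, ann_b = self._annotations()
        t = build_contingency(
            "GO:t",
            {"p1": True, "p2": True},
            {"q1": True, "q2": True, "q3": True},
            ann_a, ann_b,
        )
        assert (t.nd_a, t.nd_b) == (0, 0)

    def test_term_must_be_shared(self):
        ann_a, ann_b = self._annotations()
        with pytest.raises(DataError, match="both organisms"):
            build_contingency("GO:other", {}, {}, ann_a, ann_b)


class TestChi2Yates:
    def test_hand_evaluated_table(self):
        stat, p = chi2_yates(table(20, 80, 40, 60))
        assert stat == pytest.approx(8.595, abs=0.001)
        assert p == pytest.approx(3.37e-3, rel=0.01)

    def test_observed_equals_expected_gives_zero(self):
        stat, p = chi2_yates(table(10, 10, 10, 10))
        assert (stat, p) == (0.0, 1.0)

    def test_proteome_scale_table_is_overwhelming(self):
        # counts recovered from 29.5%/35.9% of 32,398/35,244 proteins
        _, p = chi2_yates(table(9557, 22841, 12653, 22591))
        assert p < 1e-15

    def test_zero_marginal_degenerate(self):
        assert chi2_yates(table(0, 10, 0, 20)) == (0.0, 1.0)

    def test_invariant_under_simultaneous_row_column_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 200, size=4))
            direct = chi2_yates(table(a, b, c, d))
            swapped = chi2_yates(table(d, c, b, a))
            assert direct[0] == pytest.approx(swapped[0])

    def test_matches_scipy_when_deviation_large(self):
        """Independent cross-check: scipy applies the same correction when
        |O-E| >= 0.5, which holds for clearly unbalanced tables."""
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 25:
            a, b, c, d = (int(x) + 1 for x in rng.integers(5, 100, size=4))
            t = table(a, b, c, d)
            expected = (a + b) * (a + c) / t.n
            if abs(a - expected) < 0.5:
                continue
            stat, p = chi2_yates(t)
            ref = stats.chi2_contingency(np.array([[a, b], [c, d]]))
            assert stat == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)
            checked += 1


class TestExcessFilter:
    def test_boundary_inclusive(self):
        t = table(105, 95, 95, 105)
        assert t.expected_d_a == pytest.approx(100.0)
        assert excess_filter(t)

    def test_below_boundary(self):
        t = table(104, 96, 96, 104)
        assert not excess_filter(t)

    def test_degenerate_expected_zero(self):
        assert not excess_filter(table(0, 10, 0, 10))
        # observed > 0 with expected 0 cannot arise from real marginals,
        # but the convention is documented: pass iff observed > 0
        degenerate = table(0, 0, 0, 0)
        assert not excess_filter(degenerate)


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_constant_vector_unchanged(self):
        assert np.allclose(bh_adjust([0.5] * 7), 0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            m = int(rng.integers(1, 60))
            pvals = rng.random(m)
            assert np.allclose(bh_adjust(pvals), _bh_oracle(pvals))


def _bh_oracle(pvals):
    """Literal step-up: sort, scale by m/rank, enforce monotonicity, cap."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    scaled = np.array([pvals[j] * m / (i + 1) for i, j in enumerate(order)])
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(scaled, 1.0)
    return out


class TestRankSum:
    def test_extreme_separation_small_n(self):
        w, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_centered(self):
        # ties force the approximation path; identical samples sit at the null
        w, p = rank_sum_test([1.0, 2.0, 3.0] * 4, [1.0, 2.0, 3.0] * 4)
        assert p > 0.9

    def test_far_shift_large_n(self):
        xs = list(np.arange(20) + 100.0)
        ys = list(np.arange(20) * 1.0)
        _, p = rank_sum_test(xs, ys)
        assert p < 1e-6

    def test_exact_close_to_approximation_at_n6(self):
        from idpcmp.class_comparison import _ranksum_normal_p

        rng = np.random.default_rng(4)
        for _ in range(150):
            xs = list(rng.normal(size=6))
            ys = list(rng.normal(loc=rng.normal(), size=6))
            w, p_exact = rank_sum_test(xs, ys)
            p_approx = _ranksum_normal_p(w, 6, 6, xs + ys, True)
            assert abs(p_exact - p_approx) <= 0.01

    def test_approximation_close_to_scipy_reference(self):
        """Independent cross-check of the approximation path: scipy's
        continuity-corrected asymptotic Mann-Whitney differs only by the
        small Edgeworth term."""
        rng = np.random.default_rng(14)
        for _ in range(50):
            xs = list(rng.normal(size=15))
            ys = list(rng.normal(loc=0.5, size=18))
            _, p = rank_sum_test(xs, ys)
            ref = stats.mannwhitneyu(xs, ys, alternative="two-sided",
                                     method="asymptotic").pvalue
            assert abs(p - ref) <= 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            rank_sum_test([], [1.0])


def _metrics(pid, pct, n_ldw=0, n_dbr=0):
    return DisorderMetrics(
        protein_id=pid, length=100, pct_disordered=pct, n_ldw=n_ldw,
        pct_in_ldw=0.0, is_disordered_protein=pct >= 50, n_dbr=n_dbr,
        pct_dbr_residues=0.0,
    )


class TestCompareClasses:
    def _study(self, rate_a=0.6, rate_b=0.2, n=200):
        metrics_a = {
            f"a{i}": _metrics(f"a{i}", 80.0 if i < rate_a * n else 10.0)
            for i in range(n)
        }
        metrics_b = {
            f"b{i}": _metrics(f"b{i}", 80.0 if i < rate_b * n else 10.0)
            for i in range(n)
        }
        ann_a = make_annotations(
            "a", {p: {"GO:t"} for p in metrics_a}, expanded=True
        )
        ann_b = make_annotations(
            "b", {p: {"GO:t"} for p in metrics_b}, expanded=True
        )
        return metrics_a, metrics_b, ann_a, ann_b

    def test_planted_effect_detected(self):
        results = compare_classes(*self._study(), criterion="pct50")
        assert len(results) == 1
        assert results[0].significant
        assert results[0].p_adj < 1e-10

    def test_single_term_bh_is_identity(self):
        results = compare_classes(*self._study(), criterion="pct50")
        assert results[0].p_adj == pytest.approx(results[0].p_raw)

    def test_direction_filter_blocks_b_favoured_terms(self):
        results = compare_classes(
            *self._study(rate_a=0.2, rate_b=0.6), criterion="pct50"
        )
        assert not results[0].significant
        assert not results[0].passes_excess_filter

    def test_quantitative_path(self):
        results = compare_classes(
            *self._study(), criterion="pct_disordered"
        )
        assert results[0].significant
        assert results[0].mean_a > results[0].mean_b

    def test_no_shared_terms_warns_empty(self):
        metrics_a, metrics_b, ann_a, _ = self._study()
        ann_other = make_annotations(
            "b", {p: {"GO:other"} for p in metrics_b}, expanded=True
        )
        with pytest.warns(UserWarning):
            assert compare_classes(metrics_a, metrics_b, ann_a, ann_other) == []
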