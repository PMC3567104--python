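"""Disorder track parsing, binarization, window detection and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idpcmp.disorder import (
    DisorderMask,
    DisorderProfile,
    bin_fractions,
    binarize,
    builtin_predictor,
    compute_metrics,
    long_windows,
    parse_scores,
)
from idpcmp.errors import ConfigError, DataError


def profile(scores, pid="p1"):
    return DisorderProfile(pid, "test", np.asarray(scores, dtype=float))


def mask(flags, pid="p1", threshold=0.5):
    return DisorderMask(pid, np.asarray(flags, dtype=bool), threshold)


class TestParseScores:
    def test_long_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "scores.tsv"
        lines = ["protein_id\tposition\tscore"]
        lines += [f"pA\t{i}\t0.1" for i in range(1, 6)]
        lines += [f"pB\t{i}\t0.9" for i in range(1, 8)]
        path.write_text("\n".join(lines) + "\n")
        profiles = parse_scores(path)
        assert len(profiles) == 2
        assert len(profiles["pA"]) == 5
        assert len(profiles["pB"]) == 7

    def test_score_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("protein_id\tposition\tscore\npA\t1\t1.2\n")
        with pytest.raises(DataError, match=r"\[0, 1\]"):
            parse_scores(path)

    def test_position_gap_names_protein_and_position(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text(
            "protein_id\tposition\tscore\npA\t1\t0.1\npA\t2\t0.1\npA\t4\t0.1\n"
        )
        with pytest.raises(DataError, match="pA.*position 3"):
            parse_scores(path)

    def test_horizontal_dialect(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("pA\t0.1\t0.6\t0.8\npB\t0.2\t0.3\n")
        profiles = parse_scores(path, dialect="horizontal")
        assert len(profiles["pA"]) == 3
        assert len(profiles["pB"]) == 2


class TestBinarize:
    def test_boundary_is_inclusive(self):
        out = binarize(profile([0.4, 0.5, 0.6]), 0.5)
        assert out.flags.tolist() == [False, True, True]

    def test_lower_threshold_is_superset(self):
        rng = np.random.default_rng(0)
        p = profile(rng.random(200))
        low = binarize(p, 0.05).flags
        high = binarize(p, 0.5).flags
        assert np.all(low[high])  # every high-threshold call survives at 0.05

    def test_all_zero_scores_all_ordered(self):
        assert not binarize(profile([0.0] * 10), 0.5).flags.any()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(ConfigError):
            binarize(profile([0.5]), bad)


class TestLongWindows:
    def test_run_of_29_is_not_a_window(self):
        flags = np.zeros(100, dtype=bool)
        flags[10:39] = True
        assert long_windows(mask(flags)) == []

    def test_run_of_exactly_30(self):
        flags = np.zeros(100, dtype=bool)
        flags[10:40] = True
        assert long_windows(mask(flags)) == [(10, 40)]

    def test_two_separated_runs(self):
        flags = np.zeros(100, dtype=bool)
        flags[0:35] = True
        flags[50:90] = True
        windows = long_windows(mask(flags))
        assert windows == [(0, 35), (50, 90)]
        assert sum(e - s for s, e in windows) == 75

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 200))
            flags = rng.random(n) < rng.random()
            expected = _brute_force_windows(flags, 30)
            assert long_windows(mask(flags)) == expected


def _brute_force_windows(flags, min_len):
    """Check every start position; extend while flags stay true."""
    out = []
    for start in range(len(flags)):
        if flags[start] and (start == 0 or not flags[start - 1]):
            end = start
            while end < len(flags) and flags[end]:
                end += 1
            if end - start >= min_len:
                out.append((start, end))
    return out


class TestComputeMetrics:
    def test_half_disordered_is_flagged_inclusive(self):
        flags = np.zeros(100, dtype=bool)
        flags[:50] = True
        m = compute_metrics(mask(flags))
        assert m.pct_disordered == 50.0
        assert m.is_disordered_protein

    def test_all_ordered_gives_zero_metrics(self):
        m = compute_metrics(mask(np.zeros(80, dtype=bool)))
        assert (m.pct_disordered, m.n_ldw, m.pct_in_ldw) == (0.0, 0, 0.0)
        assert not m.is_disordered_protein

    def test_mixed_run_and_scatter(self):
        # 60 residues: one 30-run plus 10 isolated disordered residues
        flags = np.zeros(60, dtype=bool)
        flags[0:30] = True
        flags[31:50:2] = True  # 10 scattered singletons
        m = compute_metrics(mask(flags))
        assert m.pct_disordered == pytest.approx(40 / 60 * 100, abs=0.05)
        assert m.n_ldw == 1
        assert m.pct_in_ldw == pytest.approx(50.0)

    def test_dbr_fields_none_without_track(self):
        m = compute_metrics(mask([True] * 40))
        assert m.n_dbr is None and m.pct_dbr_residues is None

    def test_dbr_minimum_length(self):
        flags = np.zeros(40, dtype=bool)
        dbr = np.zeros(40, dtype=bool)
        dbr[0:6] = True   # counted (>= 6)
        dbr[20:25] = True  # too short
        m = compute_metrics(mask(flags), mask(dbr), dbr_min_len=6)
        assert m.n_dbr == 1
        assert m.pct_dbr_residues == pytest.approx(15.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            compute_metrics(mask([True] * 10), mask([True] * 9))

    def test_bernoulli_masks_concentrate_at_q(self):
        rng = np.random.default_rng(7)
        q = 0.35
        vals = [
            compute_metrics(mask(rng.random(500) < q)).pct_disordered
            for _ in range(200)
        ]
        assert np.mean(vals) == pytest.approx(100 * q, abs=1.0)


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=40)
def test_metrics_monotone_in_threshold(seed):
    """Lowering the binarization threshold never shrinks disorder coverage;
    stricter-threshold windows are nested inside looser-threshold ones."""
    rng = np.random.default_rng(seed)
    p = profile(rng.random(150))
    lo = compute_metrics(binarize(p, 0.2))
    hi = compute_metrics(binarize(p, 0.7))
    assert lo.pct_disordered >= hi.pct_disordered
    assert lo.pct_in_ldw >= hi.pct_in_ldw
    loose = long_windows(binarize(p, 0.2))
    for s, e in long_windows(binarize(p, 0.7)):
        assert any(ls <= s and e <= le for ls, le in loose)


class TestBuiltinPredictor:
    def test_poly_glutamate_is_disordered(self):
        scores = builtin_predictor("E" * 121).scores
        assert scores[60] > 0.5  # interior residue, full window

    def test_poly_isoleucine_is_ordered(self):
        scores = builtin_predictor("I" * 121).scores
        assert scores[60] < 0.5

    def test_mixed_sequence_marginally_disordered(self):
        # <H> ~ 0.556, |<R>| = 0.5 -> f ~ -0.104, just above 0.5
        scores = builtin_predictor("EEEEIIII", window=9).scores
        mid = scores[4]
        assert 0.5 < mid < 0.6

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(DataError):
            builtin_predictor("MKVU")

    def test_even_window_rejected(self):
        with pytest.raises(ConfigError):
            builtin_predictor("MKVL", window=10)


class TestBinFractions:
    def _metrics(self, values):
        return [
            compute_metrics(mask([True] * int(v) + [False] * (100 - int(v)), f"p{i}"))
            for i, v in enumerate(values)
        ]

    def test_half_open_convention(self):
        frame = bin_fractions(self._metrics([10, 30, 95]), edges=[0, 30, 50, 100])
        assert frame["count"].tolist() == [1, 1, 1]

    def test_single_protein(self):
        frame = bin_fractions(self._metrics([42]), edges=[0, 50, 100])
        assert frame["count"].tolist() == [1, 0]
        assert frame["fraction"].sum() == pytest.approx(1.0)

    def test_value_100_in_last_closed_bin(self):
        frame = bin_fractions(self._metrics([100]), edges=[0, 50, 100])
        assert frame["count"].tolist() == [0, 1]

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ConfigError):
            bin_fractions(self._metrics([10]), edges=[0, 50, 40, 100])
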