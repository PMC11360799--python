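"""Unit and property tests for the Halfwave reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halfwave.reduction import (
    HalfwaveLevel,
    Kind,
    Signal,
    find_extrema,
    reduce_complete,
    reduce_once,
    reduce_to_level,
    to_piecewise,
)
from oracles import brute_force_extrema, brute_force_reduce_once


def level_from_values(values):
    """Alternating level directly from extremal values (indices 0..n)."""
    values = np.asarray(values, dtype=float)
    kinds = np.empty(values.size, dtype=np.int8)
    kinds[::2] = Kind.MIN if values[0] <= values[1] else Kind.MAX
    kinds[1::2] = -kinds[0]
    return HalfwaveLevel(np.arange(values.size), values, kinds)


def assert_valid_level(lvl):
    if len(lvl) >= 2:
        assert np.all(np.diff(lvl.indices) > 0)
        assert np.all(lvl.kinds[:-1] + lvl.kinds[1:] == 0), "alternation broken"


class TestFindExtrema:
    def test_monotone_signal_has_only_endpoint_extrema(self):
        lvl = find_extrema([0, 1, 2, 3, 4])
        assert lvl.indices.tolist() == [0, 4]
        assert lvl.kinds.tolist() == [Kind.MIN, Kind.MAX]

    def test_fully_oscillating_signal_keeps_every_sample(self):
        lvl = find_extrema([0, 3, 1, 2, -1, 4])
        assert lvl.indices.tolist() == [0, 1, 2, 3, 4, 5]
        assert lvl.kinds.tolist() == [-1, 1, -1, 1, -1, 1]

    def test_plateau_run_gets_single_first_sample_representative(self):
        lvl = find_extrema([0, 1, 1, 0])
        assert lvl.indices.tolist() == [0, 1, 3]
        assert lvl.values.tolist() == [0, 1, 0]
        assert lvl.kinds.tolist() == [-1, 1, -1]

    def test_constant_signal_without_endpoints_is_empty(self):
        assert len(find_extrema([2.0, 2.0, 2.0], include_endpoints=False)) == 0

    def test_constant_signal_with_endpoints(self):
        lvl = find_extrema([2.0, 2.0, 2.0])
        assert lvl.indices.tolist() == [0, 2]

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            find_extrema([1.0])

    def test_nonfinite_signal_rejected(self):
        with pytest.raises(ValueError):
            find_extrema([0.0, np.nan, 1.0])

    def test_interior_extrema_match_exhaustive_neighbor_scan(self, rng):
        for _ in range(200):
            x = rng.integers(-2, 3, size=rng.integers(2, 40)).astype(float)
            lvl = find_extrema(x, include_endpoints=False)
            assert lvl.indices.tolist() == brute_force_extrema(x)
            assert_valid_level(lvl)

    @given(st.lists(st.integers(-3, 3), min_size=2, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_alternation_and_bounds_hold(self, xs):
        lvl = find_extrema(np.array(xs, dtype=float))
        assert_valid_level(lvl)
        assert lvl.indices[0] >= 0 and lvl.indices[-1] <= len(xs) - 1


class TestReduceOnce:
    def test_hand_trace_default_mode(self):
        lvl = level_from_values([0, 3, 1, 2, -1, 4])
        out = reduce_once(lvl)
        assert out.indices.tolist() == [0, 1, 4, 5]
        assert out.values.tolist() == [0, 3, -1, 4]
        assert out.level == 2

    def test_hand_trace_literal_trailing_index_mode(self):
        lvl = level_from_values([0, 3, 1, 2, -1, 4])
        out = reduce_once(lvl, preserve_endpoints=False)
        assert out.indices.tolist() == [0, 1, 4]
        assert out.values.tolist() == [0, 3, -1]

    def test_increasing_amplitude_signal_is_fixed_point(self):
        lvl = level_from_values([0, 1, -1, 3, -4])
        out = reduce_once(lvl)
        assert out.values.tolist() == [0, 1, -1, 3, -4]
        assert out.complete

    def test_under_two_points_returned_unchanged(self):
        lvl = HalfwaveLevel(np.array([3]), np.array([1.0]), np.array([1], np.int8))
        out = reduce_once(lvl)
        assert out.indices.tolist() == [3] and out.complete

    def test_matches_brute_force_oracle_on_random_levels(self, rng):
        for _ in range(300):
            m = int(rng.integers(2, 25))
            vals = np.round(rng.normal(size=m), 1)
            lvl = level_from_values(vals)
            for pe in (True, False):
                out = reduce_once(lvl, preserve_endpoints=pe)
                assert out.indices.tolist() == brute_force_reduce_once(vals, pe)
                assert_valid_level(out)
                # nesting: output points are a subset of input points
                assert set(out.indices.tolist()) <= set(lvl.indices.tolist())


class TestReduceToLevel:
    def test_level_one_equals_find_extrema(self, rng):
        x = rng.normal(size=120)
        a, b = reduce_to_level(x, k=1), find_extrema(x)
        assert a.indices.tolist() == b.indices.tolist()

    def test_level_two_hand_trace(self):
        out = reduce_to_level([0, 3, 1, 2, -1, 4], k=2)
        assert out.values.tolist() == [0, 3, -1, 4]

    def test_large_k_reaches_complete_fixed_point(self, rng):
        x = rng.normal(size=200)
        deep = reduce_to_level(x, k=50)
        full = reduce_complete(x)
        assert deep.complete
        assert deep.indices.tolist() == full.indices.tolist()

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            reduce_to_level([0.0, 1.0], k=0)


class TestReduceComplete:
    def test_monotone_signal_complete_immediately(self):
        out = reduce_complete([0, 1, 2, 3])
        assert len(out) == 2 and out.complete

    def test_idempotent_under_further_reduction(self, rng):
        for _ in range(30):
            x = rng.normal(size=int(rng.integers(10, 300)))
            full = reduce_complete(x)
            again = reduce_once(full)
            assert again.indices.tolist() == full.indices.tolist()

    def test_literal_mode_still_terminates(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(4, 60)))
            out = reduce_complete(x, preserve_endpoints=False)
            assert len(out) <= 1 or reduce_once(
                out, preserve_endpoints=False
            ).indices.tolist() == out.indices.tolist()

    def test_level_counts_non_increasing_until_convergence(self, rng):
        x = rng.normal(size=400)
        lvl = find_extrema(x)
        counts = [len(lvl)]
        for _ in range(len(lvl)):
            nxt = reduce_once(lvl)
            counts.append(len(nxt))
            if len(nxt) == len(lvl):
                break
            lvl = nxt
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert len(counts) - 1 <= counts[0]  # convergence within n iterations


class TestPiecewise:
    def test_single_point_single_knot(self):
        lvl = HalfwaveLevel(np.array([5]), np.array([2.0]), np.array([1], np.int8))
        assert to_piecewise(lvl).tolist() == [[5.0, 2.0]]

    def test_empty_level_empty_knots(self):
        lvl = HalfwaveLevel(
            np.empty(0, np.int64), np.empty(0), np.empty(0, np.int8)
        )
        assert to_piecewise(lvl).shape[0] == 0

    def test_interpolation_exact_at_knots(self):
        x = np.array([0, 3, 1, 2, -1, 4], dtype=float)
        knots = to_piecewise(find_extrema(x))
        recon = np.interp(np.arange(6), knots[:, 0], knots[:, 1])
        assert np.allclose(recon[knots[:, 0].astype(int)], x[knots[:, 0].astype(int)])

    def test_deeper_levels_never_beat_level_one_reconstruction(self, rng):
        # max reconstruction error is not pairwise monotone across levels (a
        # deletion pass can move the interpolant closer to the signal
        # locally), but no deeper level reconstructs better than level 1,
        # which interpolates through every extremum
        for _ in range(10):
            x = rng.normal(size=250)
            t = np.arange(x.size)
            errs = []
            for k in range(1, 8):
                lvl = reduce_to_level(Signal(x), k=k)
                knots = to_piecewise(lvl)
                recon = np.interp(t, knots[:, 0], knots[:, 1])
                errs.append(float(np.max(np.abs(recon - x))))
                if lvl.complete:
                    break
            assert all(e >= errs[0] - 1e-12 for e in errs)
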