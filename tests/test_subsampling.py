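import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from towcam.annotations import FrameRecord, aggregate_counts
from towcam.diversity import hills_n2, shannon
from towcam.subsampling import (
    SubsampleDesign,
    default_systematic_intervals,
    log_spaced_sizes,
    random_select,
    run_design,
    split_halves,
    systematic_select,
)

from conftest import deterministic_stream


class TestSystematicSelect:
    def test_interval_five_always_yields_1831(self):
        for start in range(1, 6):
            assert len(systematic_select(9155, 5, start)) == 1831

    def test_degenerate_single_frame(self):
        assert systematic_select(10, 10, 1).tolist() == [1]

    def test_interval_300_sizes_by_exhaustive_enumeration(self):
        sizes = set()
        for start in range(1, 301):
            idx = systematic_select(9155, 300, start)
            brute = [i for i in range(1, 9156) if i >= start and (i - start) % 300 == 0]
            assert idx.tolist() == brute
            sizes.add(len(idx))
        assert sizes == {30, 31}

    @settings(max_examples=200, deadline=None)
    @given(st.integers(2, 2000), st.data())
    def test_size_matches_closed_form(self, n, data):
        k = data.draw(st.integers(1, n))
        start = data.draw(st.integers(1, k))
        idx = systematic_select(n, k, start)
        assert len(idx) == (n - start) // k + 1
        assert idx[0] == start and idx[-1] <= n

    def test_start_out_of_range(self):
        with pytest.raises(ValueError):
            systematic_select(100, 5, 6)
        with pytest.raises(ValueError):
            systematic_select(100, 5, 0)


class TestRandomSelect:
    def test_full_set_when_n_equals_total(self):
        idx = random_select(100, 100, np.random.default_rng(0))
        assert idx.tolist() == list(range(1, 101))

    def test_distinct_indices_in_range(self):
        idx = random_select(9155, 31, np.random.default_rng(1))
        assert len(idx) == 31 == len(set(idx.tolist()))
        assert idx.min() >= 1 and idx.max() <= 9155

    def test_seed_determinism(self):
        a = random_select(500, 50, np.random.default_rng(42))
        b = random_select(500, 50, np.random.default_rng(42))
        assert a.tolist() == b.tolist()

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError):
            random_select(10, 11, np.random.default_rng(0))


class TestLogSpacedSizes:
    def test_published_grid(self):
        sizes = log_spaced_sizes(31, 1778, 36)
        assert len(sizes) == 36
        assert sizes[0] == 31 and sizes[-1] == 1778

    def test_exact_decades(self):
        assert log_spaced_sizes(10, 1000, 3) == [10, 100, 1000]

    def test_middle_values_match_arbitrary_precision_formula(self):
        import sympy

        sizes = log_spaced_sizes(31, 1778, 36)
        lo, hi = sympy.log(31, 10), sympy.log(1778, 10)
        for i, expected in enumerate(sizes):
            x = lo + sympy.Rational(i, 35) * (hi - lo)
            val = int((10**x).evalf(50).round())
            assert val == expected

    def test_duplicates_removed_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            sizes = log_spaced_sizes(2, 5, 10)
        assert sizes == sorted(set(sizes))

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            log_spaced_sizes(100, 100, 5)
        with pytest.raises(ValueError):
            log_spaced_sizes(10, 100, 1)


def test_default_intervals_are_forty_unique_log_spaced():
    iv = default_systematic_intervals()
    assert len(iv) == 40 == len(set(iv))
    assert iv[0] == 5 and iv[-1] == 300
    assert iv == sorted(iv)


class TestRunDesign:
    def test_interval_one_equals_full_set(self, stream_200):
        full = aggregate_counts(stream_200)
        design = SubsampleDesign(kind="systematic", intervals=(1,), n_reps=3, seed=0)
        curve = run_design(stream_200, design)
        assert np.allclose(curve["H"], shannon(full))
        assert np.allclose(curve["N2"], hills_n2(full))
        assert (curve["n_frames"] == 200).all()
        assert np.allclose(curve["fraction_of_total"], 100.0)

    def test_all_empty_frames_give_undefined_markers(self):
        frames = [FrameRecord("T1", i + 1, {}) for i in range(50)]
        design = SubsampleDesign(kind="random", sizes=(10, 20), n_reps=2, seed=0)
        curve = run_design(frames, design)
        assert curve["H"].isna().all() and curve["N2"].isna().all()

    def test_size_equal_to_total_forces_full_set(self, stream_200):
        full_n2 = hills_n2(aggregate_counts(stream_200))
        design = SubsampleDesign(kind="random", sizes=(50, 100, 200), n_reps=10, seed=3)
        curve = run_design(stream_200, design)
        at_full = curve[curve["size_nominal"] == 200]
        assert len(at_full) == 10
        assert np.allclose(at_full["N2"], full_n2)

    def test_unusable_frames_excluded_from_selection(self, stream_200):
        for r in stream_200[:100]:
            r.usable = False
        design = SubsampleDesign(kind="systematic", intervals=(1,), n_reps=1, seed=0)
        curve = run_design(stream_200, design)
        assert curve["n_frames"].iloc[0] == 100

    def test_invalid_design_rejected_before_compute(self):
        with pytest.raises(ValueError):
            SubsampleDesign(kind="systematic", intervals=(), n_reps=1)
        with pytest.raises(ValueError):
            SubsampleDesign(kind="stratified", intervals=(5,))

    def test_systematic_composition_unbiased_by_exhaustive_starts(self):
        # systematic samples over all starts partition the frames, so the
        # organism-weighted average of sampled proportions (pooled counts over
        # all starts, renormalized) equals the full-set proportions exactly
        frames = deterministic_stream(500, {"A": 40, "B": 25, "C": 10})
        full = aggregate_counts(frames)
        full_p = (full / full.sum()).sort_index()
        for k in (2, 5, 7, 10):
            pooled = pd.Series(0.0, index=full_p.index)
            for start in range(1, k + 1):
                idx = systematic_select(500, k, start)
                sel = [frames[i - 1] for i in idx]
                pooled = pooled.add(aggregate_counts(sel), fill_value=0.0)
            assert np.allclose((pooled / pooled.sum()).to_numpy(),
                               full_p.to_numpy(), atol=1e-12)

    def test_random_composition_unbiased_monte_carlo(self, stream_200):
        full = aggregate_counts(stream_200)
        full_p = (full / full.sum()).sort_index()
        rng = np.random.default_rng(11)
        acc = np.zeros(len(full_p))
        reps = 400
        for _ in range(reps):
            idx = random_select(200, 50, rng)
            v = aggregate_counts([stream_200[i - 1] for i in idx])
            v = v.reindex(full_p.index, fill_value=0.0)
            acc += (v / v.sum()).to_numpy()
        assert np.allclose(acc / reps, full_p.to_numpy(), atol=0.02)


class TestSplitHalves:
    @pytest.mark.parametrize("n,first,second", [(10, 5, 5), (9155, 4577, 4578), (3, 1, 2)])
    def test_half_sizes(self, n, first, second):
        frames = [FrameRecord("T1", i + 1, {}) for i in range(n)]
        a, b = split_halves(frames)
        assert (len(a), len(b)) == (first, second)
        assert [r.frame_index for r in a + b] == list(range(1, n + 1))

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            split_halves([FrameRecord("T1", 1, {})])

    def test_mixed_transects_rejected(self):
        with pytest.raises(ValueError):
            split_halves([FrameRecord("T1", 1, {}), FrameRecord("T2", 1, {})])
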