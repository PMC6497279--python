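import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from towcam.annotations import FrameRecord
from towcam.community import (
    cut_tree,
    euclidean_distances,
    sediment_composition,
    standardize,
    to_newick,
    ward_cluster,
)


def brute_force_ward(points):
    """All greedy Ward merge sequences on a small point set (oracle).

    Explores every tie-breaking choice among minimum-cost merges and returns
    the set of possible sorted height sequences.
    """
    points = [np.atleast_1d(np.asarray(p, float)) for p in points]

    def delta(a, b):
        (na, ca), (nb, cb) = a, b
        return na * nb / (na + nb) * float(((ca - cb) ** 2).sum())

    results = []

    def recurse(clusters, heights):
        if len(clusters) == 1:
            results.append(tuple(sorted(heights)))
            return
        costs = {
            (i, j): delta(clusters[i], clusters[j])
            for i, j in itertools.combinations(range(len(clusters)), 2)
        }
        best = min(costs.values())
        for (i, j), c in costs.items():
            if c <= best + 1e-12:
                (na, ca), (nb, cb) = clusters[i], clusters[j]
                merged = (na + nb, (na * ca + nb * cb) / (na + nb))
                rest = [cl for k, cl in enumerate(clusters) if k not in (i, j)]
                recurse(rest + [merged], heights + [c])

    recurse([(1, p) for p in points], [])
    return results


class TestStandardize:
    def test_unit_sd_column(self):
        out = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["a"], [-1, 0, 1])

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = standardize(df)
        assert list(out.columns) == ["a"]

    def test_transect_matrix_standardized_post_hoc(self, transect_counts, taxonomy):
        # one-row-per-transect matrix built by splitting the pooled counts
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(
            rng.multinomial(500, transect_counts / transect_counts.sum(), size=7),
            index=[f"T{i}" for i in range(1, 8)],
            columns=transect_counts.index,
        )
        with pytest.warns(UserWarning):
            z = standardize(mat)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            standardize(pd.DataFrame({"a": [1.0]}))


class TestDistances:
    def test_identical_rows_distance_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["x", "y"])
        d = euclidean_distances(m)
        assert d.loc["x", "y"] == 0.0

    def test_three_four_five(self):
        m = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["x", "y"])
        assert euclidean_distances(m).loc["x", "y"] == pytest.approx(5.0)

    def test_random_matrix_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(5, 3)))
        d = euclidean_distances(m).to_numpy()
        for i in range(5):
            for j in range(5):
                expected = np.sqrt(((m.iloc[i] - m.iloc[j]) ** 2).sum())
                assert d[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distances(pd.DataFrame([[1.0, np.nan], [0.0, 1.0]]))


class TestWard:
    def test_line_points_match_brute_force(self):
        pts = [0.0, 1.0, 10.0, 11.0]
        dend = ward_cluster(pd.DataFrame({"x": pts}, index=list("abcd")))
        oracle = brute_force_ward(pts)
        assert any(np.allclose(sorted(dend.heights), seq, atol=1e-9) for seq in oracle)
        # the two cheap merges cost 0.5 each; the final merge costs 100
        assert np.allclose(sorted(dend.heights), [0.5, 0.5, 100.0])

    def test_two_identical_points_single_zero_merge(self):
        dend = ward_cluster(pd.DataFrame({"x": [2.0, 2.0]}, index=["p", "q"]))
        assert len(dend.heights) == 1
        assert dend.heights[0] == pytest.approx(0.0)

    def test_planted_two_cluster_recovery(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.5, size=(6, 3))
        b = rng.normal(20, 0.5, size=(5, 3))
        m = pd.DataFrame(np.vstack([a, b]),
                         index=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(5)])
        groups = cut_tree(ward_cluster(m), 2)
        assert groups[[f"a{i}" for i in range(6)]].nunique() == 1
        assert groups[[f"b{i}" for i in range(5)]].nunique() == 1
        assert groups["a0"] != groups["b0"]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_heights_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.normal(size=(rng.integers(3, 9), 4)))
        dend = ward_cluster(m)
        assert np.all(np.diff(dend.heights) >= -1e-9)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10_000))
    def test_small_inputs_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=rng.integers(3, 7)).round(2)
        dend = ward_cluster(pd.DataFrame({"x": pts}))
        oracle = brute_force_ward(pts)
        assert any(np.allclose(sorted(dend.heights), seq, atol=1e-8) for seq in oracle)

    def test_row_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.normal(size=(6, 3)), index=list("abcdef"))
        perm = m.sample(frac=1, random_state=1)
        g1 = cut_tree(ward_cluster(m), 3).sort_index()
        g2 = cut_tree(ward_cluster(perm), 3).sort_index()
        # identical partitions: co-membership matrices agree
        co1 = np.equal.outer(g1.to_numpy(), g1.to_numpy())
        co2 = np.equal.outer(g2.to_numpy(), g2.to_numpy())
        assert np.array_equal(co1, co2)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.array([[0.0, np.inf], [1.0, 2.0]]))


class TestCutTree:
    @pytest.fixture
    def dend(self):
        return ward_cluster(pd.DataFrame({"x": [0.0, 1.0, 10.0, 11.0]}, index=list("abcd")))

    def test_singletons(self, dend):
        assert cut_tree(dend, 4).nunique() == 4

    def test_one_group(self, dend):
        assert cut_tree(dend, 1).nunique() == 1

    def test_two_groups_split_the_gap(self, dend):
        g = cut_tree(dend, 2)
        assert g["a"] == g["b"] and g["c"] == g["d"] and g["a"] != g["c"]

    def test_out_of_range_k(self, dend):
        with pytest.raises(ValueError):
            cut_tree(dend, 0)
        with pytest.raises(ValueError):
            cut_tree(dend, 5)


class TestNewick:
    def test_round_trip_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(5, 2)), index=list("vwxyz"))
        dend = ward_cluster(m)
        tree = dendropy.Tree.get(data=to_newick(dend), schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == list("vwxyz")
        # root-to-leaf path length equals the final merge height for every leaf
        root_h = dend.heights[-1]
        for leaf in tree.leaf_node_iter():
            dist = leaf.distance_from_root()
            assert dist == pytest.approx(root_h, rel=1e-4)


class TestSedimentComposition:
    def test_pure_sand(self):
        frames = [FrameRecord("T1", i + 1, {}, sediment_pct={"sand": 100.0}) for i in range(3)]
        out = sediment_composition(frames)
        assert out.loc["T1", "sand"] == pytest.approx(1.0)
        assert out.loc["T1", "silt"] == 0.0

    def test_hand_arithmetic_two_frames(self):
        frames = [
            FrameRecord("T1", 1, {}, sediment_pct={"sand": 50.0, "silt": 50.0}),
            FrameRecord("T1", 2, {}, sediment_pct={"sand": 100.0}),
        ]
        out = sediment_composition(frames)
        assert out.loc["T1", "sand"] == pytest.approx(0.75)
        assert out.loc["T1", "silt"] == pytest.approx(0.25)

    def test_mixed_fixture_matches_mean_oracle(self):
        rng = np.random.default_rng(6)
        frames = []
        raw = []
        for i in range(20):
            sand = rng.uniform(20, 80)
            gravel = rng.uniform(0, 100 - sand)
            silt = 100 - sand - gravel
            raw.append((sand, silt, gravel))
            frames.append(FrameRecord("T1", i + 1, {},
                                      sediment_pct={"sand": sand, "silt": silt, "gravel": gravel}))
        out = sediment_composition(frames)
        sums = np.array(raw).mean(axis=0)
        expected = sums / sums.sum()
        assert out.loc["T1", "sand"] == pytest.approx(expected[0])
        assert out.loc["T1", "silt"] == pytest.approx(expected[1])
        assert out.loc["T1", "gravel"] == pytest.approx(expected[2])

    def test_group_without_sediment_is_nan(self):
        frames = [
            FrameRecord("T1", 1, {}, sediment_pct={"sand": 100.0}),
            FrameRecord("T2", 1, {}),
        ]
        out = sediment_composition(frames)
        assert out.loc["T2"].isna().all()
        assert out.loc["T1", "sand"] == 1.0

    def test_rows_sum_to_one(self):
        frames = [FrameRecord("T1", 1, {}, sediment_pct={"sand": 60.0, "shell": 20.0})]
        out = sediment_composition(frames)
        assert out.loc["T1"].sum() == pytest.approx(1.0)
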