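"""R2E seriation: rank iteration, elliptical ordering, constrained clustering.

The key oracle is brute-force enumeration: for small perfect Robinson
matrices every permutation is scored by its number of Robinson violations,
and the R2E order must be among the violation-free ones (the generating
order or its reversal).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gutmap.seriate import (RANK_THRESHOLD, SeriationError, effective_rank,
                            iterate_correlation, elliptical_order, seriate,
                            constrained_cluster, build_gap)
from _oracles import (robinson_correlation, robinson_violations,
                      all_permutations, violations_all_perms)


class TestEffectiveRank:
    def test_identity_full_rank(self):
        assert effective_rank(np.eye(6)) == 6

    def test_all_ones_rank_one(self):
        assert effective_rank(np.ones((3, 3))) == 1

    def test_constructed_rank_two(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        X = np.vstack([a, -a + 0.5 * b, b])
        # correlation matrix of 3 vectors spanning a 2-D space has rank 2
        R = np.corrcoef(np.vstack([a, b, a + b]))
        eig = np.linalg.eigvalsh(R)
        assert (eig > RANK_THRESHOLD).sum() == 2
        assert effective_rank(R) == 2
        del X

    def test_asymmetric_rejected(self):
        M = np.eye(3)
        M[0, 1] = 0.5
        with pytest.raises(SeriationError):
            effective_rank(M)


class TestIterateCorrelation:
    def test_rank2_input_needs_no_iteration(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(size=8)
        X = np.vstack([a, b, a + b])
        R, traj = iterate_correlation(X)
        assert len(traj) == 1
        assert traj[0] <= 2

    def test_output_is_correlation_matrix(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 30))
        R, traj = iterate_correlation(X)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert traj[-1] <= 2

    def test_constant_row_raises_with_item(self):
        X = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        with pytest.raises(SeriationError, match="constant"):
            iterate_correlation(X)

    def test_rank_trajectory_reaches_two_quickly_on_robinson_data(self):
        rng = np.random.default_rng(3)
        R = robinson_correlation(20, rng)
        _, traj = iterate_correlation(R)
        assert traj[-1] <= 2
        assert len(traj) - 1 <= 10


class TestEllipticalOrder:
    def test_largest_gap_rule(self):
        # items on the unit circle at 0, 90, 180 degrees: the largest gap is
        # 180..360, so the order starts at the item at angle 0
        U = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        R2 = U @ np.diag([1.0, 0.5]) @ U.T
        res = elliptical_order(R2, item_ids=["a", "b", "c"])
        assert res.ordered_ids in (["a", "b", "c"], ["c", "b", "a"])
        assert res.permutation[0] in (0, 2)

    def test_anchor_forced_into_first_half(self):
        rng = np.random.default_rng(4)
        R = robinson_correlation(8, rng)
        ids = [f"seg{i}" for i in range(8)]
        res = elliptical_order(iterate_correlation(R)[0], item_ids=ids,
                               anchor="seg7")
        assert res.ordered_ids.index("seg7") < 4
        assert res.anchor_used == "seg7"

    def test_rank_gt2_rejected(self):
        with pytest.raises(SeriationError, match="rank"):
            elliptical_order(np.eye(5))


class TestSeriateOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_robinson_order_against_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        R = robinson_correlation(n, rng)
        true_perm = rng.permutation(n)
        X = R[np.ix_(true_perm, true_perm)]      # shuffled Robinson matrix
        res = seriate(X, item_ids=[f"i{p}" for p in true_perm])
        got = [int(i[1:]) for i in res.ordered_ids]
        assert got in ([*range(n)], [*range(n)][::-1])
        # brute-force: the recovered order is violation-free and any
        # violation-free order is the identity or its reversal
        assert robinson_violations(X, res.permutation) == 0
        perms = all_permutations(n)
        viol = violations_all_perms(R, perms)
        zero = perms[viol == 0]
        assert sorted(map(tuple, zero)) == sorted([tuple(range(n)),
                                                   tuple(reversed(range(n)))])

    def test_fixed_point_after_permuting(self):
        rng = np.random.default_rng(11)
        R = robinson_correlation(10, rng)
        res = seriate(R, item_ids=list(range(10)))
        X2 = R[np.ix_(res.permutation, res.permutation)]
        res2 = seriate(X2, item_ids=[str(i) for i in range(10)])
        got = [int(i) for i in res2.ordered_ids]
        assert got in ([*range(10)], [*range(10)][::-1])

    def test_noisy_gradient_recovery(self):
        rng = np.random.default_rng(12)
        ok = 0
        for _ in range(20):
            centers = np.linspace(0, 7, 60)
            X = np.exp(-0.5 * ((np.arange(8)[None, :] - centers[:, None])
                               / 1.2) ** 2)
            Xz = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
            noisy = Xz + rng.normal(0, 0.5, X.shape)
            res = seriate(noisy.T, item_ids=list(range(8)))
            from scipy.stats import spearmanr
            rho = abs(spearmanr(res.permutation, range(8)).statistic)
            ok += rho >= 0.9
        assert ok >= 18

    def test_three_items_deterministic(self):
        X = np.array([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0], [2.0, 3.0, 1.0]])
        r1 = seriate(X, item_ids=["a", "b", "c"])
        r2 = seriate(X, item_ids=["a", "b", "c"])
        assert r1.permutation == r2.permutation


class TestSeriateProperties:
    def test_reversal_symmetry(self):
        rng = np.random.default_rng(13)
        R = robinson_correlation(9, rng)
        fwd = seriate(R, item_ids=list(range(9)))
        rev = seriate(R[::-1], item_ids=list(range(9)))
        mapped = [8 - i for i in rev.permutation]
        assert mapped in (fwd.permutation, fwd.permutation[::-1])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0), shift=st.floats(-5.0, 5.0))
    def test_scale_invariance(self, scale, shift):
        rng = np.random.default_rng(14)
        R = robinson_correlation(7, rng)
        base = seriate(R, item_ids=list(range(7)))
        scaled = seriate(R * scale + shift, item_ids=list(range(7)))
        assert scaled.permutation in (base.permutation,
                                      base.permutation[::-1])


class TestConstrainedCluster:
    def test_k_equals_n_singletons(self):
        rng = np.random.default_rng(15)
        R = robinson_correlation(6, rng)
        res = seriate(R, item_ids=list(range(6)))
        blocks = constrained_cluster(res, R, 6)
        assert all(len(b) == 1 for b in blocks)

    def test_two_planted_clusters_exact_split(self):
        within, between = 0.9, 0.1
        R = np.full((8, 8), between)
        R[:4, :4] = within
        R[4:, 4:] = within
        np.fill_diagonal(R, 1.0)
        blocks = constrained_cluster(list(range(8)), R, 2)
        assert sorted(map(sorted, blocks)) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_blocks_contiguous_along_order(self):
        rng = np.random.default_rng(16)
        R = robinson_correlation(10, rng)
        res = seriate(R, item_ids=list(range(10)))
        blocks = constrained_cluster(res, R, 3)
        pos = {i: p for p, i in enumerate(res.permutation)}
        for a, b in zip(blocks[:-1], blocks[1:]):
            assert max(pos[i] for i in a) < min(pos[i] for i in b)

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            constrained_cluster(list(range(4)), np.eye(4), 0)


class TestGAP:
    def test_bundle_consistency_and_roundtrip(self, tmp_path):
        rng = np.random.default_rng(17)
        n_seg, n_item = 8, 20
        segR = robinson_correlation(n_seg, rng)
        X = rng.normal(size=(n_item, n_seg)) + \
            np.linspace(0, 3, n_seg)[None, :] * \
            np.linspace(0, 1, n_item)[:, None]
        itemR = np.corrcoef(X)
        item_order = seriate(X, item_ids=[f"g{i}" for i in range(n_item)])
        seg_order = seriate(segR, item_ids=[f"s{i}" for i in range(n_seg)])
        gap = build_gap(X, itemR, segR, item_order, seg_order)
        assert gap.expression.shape == (n_item, n_seg)
        assert gap.item_ids == item_order.ordered_ids
        assert gap.segment_ids == seg_order.ordered_ids
        # permuted consistently
        ip, sp = item_order.permutation, seg_order.permutation
        assert np.allclose(gap.expression, X[np.ix_(ip, sp)])
        # TSV round trip
        import pandas as pd
        df = pd.DataFrame(gap.expression, index=gap.item_ids,
                          columns=gap.segment_ids)
        path = tmp_path / "gap_expression.tsv"
        df.to_csv(path, sep="\t")
        back = pd.read_csv(path, sep="\t", index_col=0)
        assert np.allclose(back.to_numpy(), gap.expression)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(18)
        R = robinson_correlation(5, rng)
        order = seriate(R, item_ids=list(range(5)))
        with pytest.raises(ValueError):
            build_gap(np.zeros((4, 5)), np.eye(5), R, order, order)
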