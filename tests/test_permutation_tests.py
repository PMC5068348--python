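import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway, pearsonr
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from betanull.permutation_tests import (
    compute_pseudo_F,
    mantel_test,
    pairwise_permanova,
    partial_mantel_test,
    permanova_one_way,
    two_group_permutation_test,
)


def _euclid_dm(points, ids=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] == points.shape[0] == 1:
        points = points.T
    n = points.shape[0]
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(d, ids=ids or [f"s{i}" for i in range(n)])


class TestTwoGroupPermutation:
    def test_equal_groups_give_p_one(self):
        res = two_group_permutation_test([1.0, 2.0], [1.0, 2.0])
        assert res.observed_diff == 0.0
        assert res.p_value == 1.0

    def test_exhaustive_extreme_split(self):
        # C(4,2)=6 assignments; only the two extreme splits reach |9|
        res = two_group_permutation_test([10, 11], [1, 2])
        assert res.exhaustive
        assert res.n_permutations == 6
        assert res.p_value == pytest.approx(2 / 6)

    def test_monte_carlo_matches_enumeration(self, rng):
        a = rng.normal(1.0, 1.0, size=4)
        b = rng.normal(0.0, 1.0, size=4)
        exact = two_group_permutation_test(a, b, n_permutations=10_000)
        assert exact.exhaustive
        mc = two_group_permutation_test(a, b, n_permutations=30, seed=4)
        assert not mc.exhaustive
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 30)
        assert abs(mc.p_value - exact.p_value) < 3 * se + 2 / 31

    def test_degenerate_values_warn_p_one(self):
        with pytest.warns(UserWarning):
            res = two_group_permutation_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_p_floor(self, rng):
        a = rng.normal(10, 0.1, size=8)
        b = rng.normal(0, 0.1, size=8)
        res = two_group_permutation_test(a, b, n_permutations=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            two_group_permutation_test([1.0], [2.0, 3.0])


class TestPseudoF:
    def test_printed_aboveground_decomposition(self):
        ms_a, ms_r, f = compute_pseudo_F(1.54, 4, 6.29, 35)
        assert ms_a == pytest.approx(0.385)
        assert round(f, 2) == 2.14

    def test_printed_belowground_decomposition(self):
        ms_a, ms_r, f = compute_pseudo_F(1.68, 4, 6.94, 25)
        assert ms_a == pytest.approx(0.42)
        assert round(f, 2) == 1.51

    def test_zero_among_ss_gives_zero_F(self):
        assert compute_pseudo_F(0.0, 3, 5.0, 10)[2] == 0.0

    def test_zero_residual_ms_raises(self):
        with pytest.raises(ValueError):
            compute_pseudo_F(1.0, 2, 0.0, 5)


class TestPermanova:
    def brute_force(self, dm, labels):
        """Independent direct-definition PERMANOVA (no shared code paths):
        recompute SS terms from scratch for every distinct relabeling."""
        d = dm.data
        n = d.shape[0]
        labels = np.asarray(labels, dtype=object)

        def f_stat(lab):
            ss_t = sum(
                d[i, j] ** 2 for i, j in itertools.combinations(range(n), 2)
            ) / n
            ss_w = 0.0
            for lev in set(lab):
                members = [i for i in range(n) if lab[i] == lev]
                ss_w += sum(
                    d[i, j] ** 2 for i, j in itertools.combinations(members, 2)
                ) / len(members)
            ss_a = ss_t - ss_w
            a = len(set(lab))
            return (ss_a / (a - 1)) / (ss_w / (n - a))

        f_obs = f_stat(labels)
        seen = set()
        count = total = 0
        for perm in itertools.permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            if f_stat(list(perm)) >= f_obs - 1e-12:
                count += 1
        return f_obs, count / total

    def test_constant_distances_p_one(self):
        d = np.ones((6, 6)) - np.eye(6)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        res = permanova_one_way(dm, ["a"] * 3 + ["b"] * 3, n_permutations=99)
        assert res.p_value == 1.0

    def test_matches_exhaustive_brute_force(self, rng):
        points = rng.normal(size=(6, 2))
        points[:3] += 1.5
        dm = _euclid_dm(points)
        labels = ["a"] * 3 + ["b"] * 3
        res = permanova_one_way(dm, labels, n_permutations=10_000)
        f_bf, p_bf = self.brute_force(dm, labels)
        assert res.exhaustive
        assert res.pseudo_F == pytest.approx(f_bf)
        assert res.p_value == pytest.approx(p_bf)

    def test_ss_decomposition_identity(self, rng):
        points = rng.normal(size=(9, 3))
        dm = _euclid_dm(points)
        res = permanova_one_way(dm, ["a", "b", "c"] * 3, n_permutations=50)
        assert res.ss_among + res.ss_resid == pytest.approx(res.ss_total)
        assert res.df_among + res.df_resid == res.df_total == 8
        assert res.pseudo_F == pytest.approx(res.ms_among / res.ms_resid)

    def test_agrees_with_skbio_statistic(self, rng):
        points = rng.normal(size=(10, 4))
        dm = _euclid_dm(points)
        labels = ["a", "b"] * 5
        res = permanova_one_way(dm, labels, n_permutations=99)
        ref = skbio_permanova(dm, grouping=list(labels), permutations=0)
        assert res.pseudo_F == pytest.approx(ref["test statistic"])

    def test_univariate_euclidean_equals_classical_anova(self, rng):
        groups = [rng.normal(m, 1.0, size=5) for m in (0.0, 1.0, 2.5)]
        values = np.concatenate(groups)
        dm = _euclid_dm(values[:, None])
        labels = np.repeat(["a", "b", "c"], 5)
        res = permanova_one_way(dm, labels, n_permutations=30)
        assert res.pseudo_F == pytest.approx(f_oneway(*groups).statistic)

    def test_singleton_group_raises(self):
        dm = _euclid_dm(np.arange(4)[:, None].astype(float))
        with pytest.raises(ValueError, match="singleton"):
            permanova_one_way(dm, ["a", "a", "a", "b"])


class TestPairwisePermanova:
    def _dm_labels(self, rng, n_groups=3, per=3):
        points = rng.normal(size=(n_groups * per, 2))
        points += np.repeat(np.arange(n_groups), per)[:, None]
        labels = np.repeat([f"g{k}" for k in range(n_groups)], per)
        return _euclid_dm(points), labels

    def test_two_groups_equals_one_way(self, rng):
        dm, labels = self._dm_labels(rng, n_groups=2)
        pair = pairwise_permanova(dm, labels, n_permutations=500, seed=0)
        one = permanova_one_way(dm, labels, n_permutations=500, seed=0)
        assert len(pair) == 1
        assert pair[0].result.pseudo_F == pytest.approx(one.pseudo_F)
        assert pair[0].result.p_value == pytest.approx(one.p_value)

    def test_three_groups_match_submatrix_calls(self, rng):
        dm, labels = self._dm_labels(rng, n_groups=3)
        entries = pairwise_permanova(dm, labels, n_permutations=200, seed=1)
        assert len(entries) == 3
        lab_map = dict(zip(dm.ids, labels))
        for e in entries:
            keep = [i for i in dm.ids if lab_map[i] in (e.group_a, e.group_b)]
            direct = permanova_one_way(
                dm.filter(keep), {i: lab_map[i] for i in keep},
                n_permutations=200, seed=1,
            )
            assert e.result.pseudo_F == pytest.approx(direct.pseudo_F)

    def test_holm_adjustment_monotone(self, rng):
        dm, labels = self._dm_labels(rng, n_groups=3)
        entries = pairwise_permanova(
            dm, labels, n_permutations=200, seed=2, correction="holm"
        )
        for e in entries:
            assert e.p_adjusted >= e.result.p_value - 1e-12


class TestMantel:
    def _pair(self, rng, n=6):
        x = rng.normal(size=(n, 2))
        return _euclid_dm(x)

    def test_self_correlation_is_one(self, rng):
        dx = self._pair(rng)
        res = mantel_test(dx, dx, n_permutations=99)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        dx = self._pair(rng)
        dy = DistanceMatrix(
            np.where(np.eye(dx.shape[0]), 0.0, 0.3 + 2.0 * dx.data), ids=dx.ids
        )
        res = mantel_test(dx, dy, n_permutations=99)
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_r_and_exact_p(self, rng):
        dx = self._pair(rng, n=4)
        dy = self._pair(rng, n=4)
        res = mantel_test(dx, dy, n_permutations=10_000)
        # oracle: Pearson on hand-listed triangles + enumeration of 4! = 24
        i, j = np.tril_indices(4, k=-1)
        xv, yv = dx.data[i, j], dy.data[i, j]
        r_hand = pearsonr(xv, yv).statistic
        assert res.r == pytest.approx(r_hand)
        count = 0
        for perm in itertools.permutations(range(4)):
            idx = np.asarray(perm)
            yp = dy.data[np.ix_(idx, idx)][i, j]
            if pearsonr(xv, yp).statistic >= r_hand - 1e-12:
                count += 1
        assert res.exhaustive and res.n_permutations == 24
        assert res.p_value == pytest.approx(count / 24)

    def test_agrees_with_skbio_r(self, rng):
        dx = self._pair(rng, n=8)
        dy = self._pair(rng, n=8)
        res = mantel_test(dx, dy, n_permutations=99)
        r_ref, _, _ = skbio_mantel(dx, dy, permutations=0)
        assert res.r == pytest.approx(r_ref)

    def test_zero_variance_raises(self):
        dx = _euclid_dm(np.arange(4)[:, None].astype(float))
        flat = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=dx.ids)
        with pytest.raises(ValueError, match="variance"):
            mantel_test(dx, flat, n_permutations=9)

    def test_too_small_raises(self, rng):
        dx = self._pair(rng, n=3)
        with pytest.raises(ValueError):
            mantel_test(dx, dx)


class TestPartialMantel:
    def test_controlling_noise_keeps_r_near_one(self, rng):
        dx = _euclid_dm(rng.normal(size=(8, 2)))
        dz = _euclid_dm(rng.normal(size=(8, 2)), ids=list(dx.ids))
        res = partial_mantel_test(dx, dx, dz, n_permutations=99)
        assert res.r > 0.95
        assert res.partial

    def test_dy_equal_dz_residualizes_to_zero(self, rng):
        dx = _euclid_dm(rng.normal(size=(8, 2)))
        dy = _euclid_dm(rng.normal(size=(8, 2)), ids=list(dx.ids))
        res = partial_mantel_test(dx, dy, dy, n_permutations=99)
        assert abs(res.r) < 1e-8

    def test_matches_two_stage_regression_oracle(self, rng):
        n = 7
        dx = _euclid_dm(rng.normal(size=(n, 2)))
        dy = _euclid_dm(rng.normal(size=(n, 2)), ids=list(dx.ids))
        dz = _euclid_dm(rng.normal(size=(n, 2)), ids=list(dx.ids))
        res = partial_mantel_test(dx, dy, dz, n_permutations=99)
        i, j = np.tril_indices(n, k=-1)
        xv, yv, zv = dx.data[i, j], dy.data[i, j], dz.data[i, j]
        design = np.column_stack([np.ones_like(zv), zv])
        rx = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
        ry = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
        assert res.r == pytest.approx(pearsonr(rx, ry).statistic)
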