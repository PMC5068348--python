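"""Label-shuffling inference on community data.

Three families of permutation tests:

* :func:`two_group_permutation_test` — difference of group means under
  random relabeling; used to compare null-deviation values between
  community fractions within a chronosequence year.  Two-sided on the
  absolute mean difference.
* :func:`permanova_one_way` / :func:`pairwise_permanova` — permutational
  multivariate ANOVA from a distance matrix: the sums of squares follow
  the standard decomposition SS_total = (1/N) sum_{i<j} d_ij^2,
  SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2, and the pseudo-F is
  (SS_among/df_among) / (SS_within/df_within); p-values come from shuffling
  group labels (one-sided upper: large F indicates group structure).
* :func:`mantel_test` / :func:`partial_mantel_test` — Pearson correlation
  of the lower triangles of two distance matrices; p by jointly permuting
  the rows and columns of the second matrix.  The partial test residualizes
  both triangles on a third matrix and permutes the residual matrix
  (method of residuals).

All Monte-Carlo p-values use the add-one convention
p = (1 + #extreme) / (1 + n_permutations); each test switches automatically
to exhaustive enumeration when the number of distinct relabelings does not
exceed the requested permutation count, in which case p is the exact
fraction of relabelings (including the identity) at least as extreme as the
observed statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "PermutationTestResult",
    "PermanovaResult",
    "MantelResult",
    "PairwisePermanovaEntry",
    "two_group_permutation_test",
    "compute_pseudo_F",
    "permanova_one_way",
    "pairwise_permanova",
    "mantel_test",
    "partial_mantel_test",
]


@dataclass
class PermutationTestResult:
    observed_diff: float
    n_permutations: int
    p_value: float
    two_sided: bool = True
    exhaustive: bool = False


@dataclass
class PermanovaResult:
    """One-way PERMANOVA decomposition (among / residual / total)."""

    df_among: int
    df_resid: int
    df_total: int
    ss_among: float
    ss_resid: float
    ss_total: float
    ms_among: float
    ms_resid: float
    pseudo_F: float
    p_value: float
    n_permutations: int
    exhaustive: bool = False

    def to_table(self, community: str = "") -> pd.DataFrame:
        """Rows Community/Source/df/SS/MSE/F/P."""
        return pd.DataFrame(
            {
                "Community": [community, "", ""],
                "Source": ["Among", "Residual", "Total"],
                "df": [self.df_among, self.df_resid, self.df_total],
                "SS": [self.ss_among, self.ss_resid, self.ss_total],
                "MSE": [self.ms_among, self.ms_resid, np.nan],
                "F": [self.pseudo_F, np.nan, np.nan],
                "P": [self.p_value, np.nan, np.nan],
            }
        )


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    partial: bool = False
    controlled: str | None = None
    exhaustive: bool = False


@dataclass
class PairwisePermanovaEntry:
    group_a: str
    group_b: str
    result: PermanovaResult
    p_adjusted: float


# ---------------------------------------------------------------------------
# Two-group mean-difference permutation test
# ---------------------------------------------------------------------------

def two_group_permutation_test(
    a, b, n_permutations: int = 9999, seed: int = 0
) -> PermutationTestResult:
    """Two-sided permutation test of mean(a) - mean(b).

    Group labels are shuffled among the pooled values; the p-value is the
    fraction of relabelings whose |mean difference| is at least the
    observed |difference|.  When the number of distinct label assignments
    C(n_a + n_b, n_a) does not exceed ``n_permutations`` the test
    enumerates all of them exactly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    observed = float(a.mean() - b.mean())

    if np.ptp(pooled) == 0:
        warnings.warn("all values identical; permutation test is degenerate")
        return PermutationTestResult(observed, 0, 1.0, exhaustive=True)

    n_total = math.comb(n, na)
    tol = 1e-12 * max(1.0, abs(observed))
    if n_total <= n_permutations:
        count = 0
        for idx_a in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            diff = pooled[mask].mean() - pooled[~mask].mean()
            if abs(diff) >= abs(observed) - tol:
                count += 1
        return PermutationTestResult(
            observed, n_total, count / n_total, exhaustive=True
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        diff = pooled[perm[:na]].mean() - pooled[perm[na:]].mean()
        if abs(diff) >= abs(observed) - tol:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermutationTestResult(observed, n_permutations, p)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def compute_pseudo_F(
    ss_among: float, df_among: int, ss_resid: float, df_resid: int
) -> tuple[float, float, float]:
    """Mean squares and pseudo-F from a sums-of-squares decomposition."""
    if df_among <= 0 or df_resid <= 0:
        raise ValueError("degrees of freedom must be positive")
    if ss_among < 0 or ss_resid < 0:
        raise ValueError("sums of squares must be non-negative")
    ms_among = ss_among / df_among
    ms_resid = ss_resid / df_resid
    if ms_resid == 0:
        raise ValueError("residual mean square is zero; F undefined")
    return ms_among, ms_resid, ms_among / ms_resid


def _as_label_array(dm: DistanceMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, dict):
        return np.asarray([grouping[i] for i in dm.ids], dtype=object)
    if isinstance(grouping, pd.Series):
        return grouping.loc[list(dm.ids)].to_numpy(dtype=object)
    labels = np.asarray(grouping, dtype=object)
    if len(labels) != dm.shape[0]:
        raise ValueError("grouping length does not match distance matrix")
    return labels


def _ss_within(d2: np.ndarray, labels: np.ndarray, levels: np.ndarray) -> float:
    total = 0.0
    for lev in levels:
        mask = labels == lev
        ng = int(mask.sum())
        total += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    return total


def permanova_one_way(
    dm: DistanceMatrix, grouping, n_permutations: int = 9999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against a single factor.

    p is the proportion of label permutations whose pseudo-F meets or
    exceeds the observed F (one-sided upper).  Exhaustive over all distinct
    label arrangements when there are no more of them than
    ``n_permutations``.
    """
    labels = _as_label_array(dm, grouping)
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = levels[counts < 2].tolist()
        raise ValueError(f"singleton group(s) {small} not allowed")

    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, labels, levels)
    ss_among = ss_total - ss_within
    df_among = len(levels) - 1
    df_resid = n - len(levels)
    ms_among, ms_resid, f_obs = compute_pseudo_F(
        ss_among, df_among, ss_within, df_resid
    )

    # F is a strictly decreasing function of SS_within at fixed SS_total,
    # so permutations are compared on SS_within (cheaper, same ordering).
    tol = 1e-12 * max(1.0, ss_total)
    n_distinct = math.factorial(n)
    for c in counts:
        n_distinct //= math.factorial(int(c))
    if n_distinct <= n_permutations:
        count = 0
        for lab in multiset_permutations(list(labels)):
            sw = _ss_within(d2, np.asarray(lab, dtype=object), levels)
            if sw <= ss_within + tol:
                count += 1
        p = count / n_distinct
        return PermanovaResult(
            df_among, df_resid, n - 1, ss_among, ss_within, ss_total,
            ms_among, ms_resid, f_obs, p, n_distinct, exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm_labels = labels[rng.permutation(n)]
        if _ss_within(d2, perm_labels, levels) <= ss_within + tol:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(
        df_among, df_resid, n - 1, ss_among, ss_within, ss_total,
        ms_among, ms_resid, f_obs, p, n_permutations,
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 9999,
    seed: int = 0,
    correction: str = "none",
) -> list[PairwisePermanovaEntry]:
    """One-way PERMANOVA on every pair of groups.

    ``correction`` is ``"none"`` or ``"holm"`` (step-down Bonferroni on the
    per-pair p-values).
    """
    if correction not in ("none", "holm"):
        raise ValueError(f"unknown correction {correction!r}")
    labels = _as_label_array(dm, grouping)
    levels = np.unique(labels)
    entries = []
    for ga, gb in combinations(levels, 2):
        keep = [i for i, lab in zip(dm.ids, labels) if lab in (ga, gb)]
        sub = dm.filter(keep)
        sub_labels = {i: lab for i, lab in zip(dm.ids, labels)}
        res = permanova_one_way(sub, sub_labels, n_permutations, seed)
        entries.append(PairwisePermanovaEntry(str(ga), str(gb), res, res.p_value))
    if correction == "holm":
        raw = [e.result.p_value for e in entries]
        adj = multipletests(raw, method="holm")[1]
        for e, p in zip(entries, adj):
            e.p_adjusted = float(p)
    return entries


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def _lower_triangle(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise ValueError("zero variance in a distance-matrix triangle")
    return float((xc * yc).sum() / denom)


def _aligned_data(dx: DistanceMatrix, dy: DistanceMatrix) -> np.ndarray:
    if set(dx.ids) != set(dy.ids):
        raise ValueError("distance matrices have different sample sets")
    return np.asarray(dy.filter(dx.ids).data, dtype=float)


def _mantel_p(
    x_vec: np.ndarray,
    y_mat: np.ndarray,
    r_obs: float,
    n_permutations: int,
    seed: int,
) -> tuple[float, int, bool]:
    """One-sided upper permutation p for a Mantel-type correlation."""
    n = y_mat.shape[0]
    tol = 1e-12
    if math.factorial(n) <= n_permutations:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            idx = np.asarray(perm)
            r = _pearson(x_vec, _lower_triangle(y_mat[np.ix_(idx, idx)]))
            if r >= r_obs - tol:
                count += 1
            total += 1
        return count / total, total, True
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        idx = rng.permutation(n)
        r = _pearson(x_vec, _lower_triangle(y_mat[np.ix_(idx, idx)]))
        if r >= r_obs - tol:
            count += 1
    return (1 + count) / (1 + n_permutations), n_permutations, False


def mantel_test(
    dx: DistanceMatrix, dy: DistanceMatrix, n_permutations: int = 9999, seed: int = 0
) -> MantelResult:
    """Mantel test: Pearson correlation of two distance matrices.

    r correlates the strict lower triangles; the p-value permutes the rows
    and columns of ``dy`` jointly (one-sided upper, add-one convention;
    exhaustive over all N! relabelings when feasible).
    """
    if dx.shape[0] < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    x_mat = np.asarray(dx.data, dtype=float)
    y_mat = _aligned_data(dx, dy)
    x_vec = _lower_triangle(x_mat)
    r_obs = _pearson(x_vec, _lower_triangle(y_mat))
    p, n_used, exhaustive = _mantel_p(x_vec, y_mat, r_obs, n_permutations, seed)
    return MantelResult(r_obs, p, n_used, exhaustive=exhaustive)


def _residualize(v: np.ndarray, on: np.ndarray) -> np.ndarray:
    slope, intercept = np.polyfit(on, v, 1)
    return v - (slope * on + intercept)


def partial_mantel_test(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    dz: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int = 0,
    controlled: str | None = None,
) -> MantelResult:
    """Partial Mantel test of dx vs dy controlling for dz.

    Both triangles are residualized on dz by simple linear regression; r is
    the Pearson correlation of the residuals.  For the p-value the dy
    residuals are reshaped into a symmetric matrix and permuted jointly
    (method of residuals).
    """
    if dx.shape[0] < 4:
        raise ValueError("partial Mantel test needs at least 4 samples")
    n = dx.shape[0]
    x_vec = _lower_triangle(np.asarray(dx.data, dtype=float))
    y_vec = _lower_triangle(_aligned_data(dx, dy))
    z_vec = _lower_triangle(_aligned_data(dx, dz))

    rx = _residualize(x_vec, z_vec)
    ry = _residualize(y_vec, z_vec)
    if np.allclose(rx, 0, atol=1e-10 * max(1.0, np.abs(x_vec).max())):
        raise ValueError("zero residual variance in dx; partial correlation undefined")
    if np.allclose(ry, 0, atol=1e-10 * max(1.0, np.abs(y_vec).max())):
        # dz explains dy completely: nothing left to correlate
        return MantelResult(0.0, 1.0, 0, partial=True, controlled=controlled)
    r_obs = _pearson(rx, ry)

    ry_mat = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    ry_mat[i, j] = ry
    ry_mat[j, i] = ry
    p, n_used, exhaustive = _mantel_p(rx, ry_mat, r_obs, n_permutations, seed)
    return MantelResult(
        r_obs, p, n_used, partial=True, controlled=controlled, exhaustive=exhaustive
    )
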