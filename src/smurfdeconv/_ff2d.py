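"""Sweep-line kernel for the two-sample Fasano-Franceschini statistic.

For an origin point (xi, yi) the plane is split into four quadrants in
each of two boundary closures: at the point itself ((x<=xi, y<=yi) and
its three orientations) and just below it ((x<xi, y<yi) and orientations,
i.e. the left limits).  The statistic takes, at every data point of the
conditioning sample, the largest absolute difference between the two
samples' quadrant fractions over all eight candidates, and averages the
two conditioning-sample maxima.  Including the left-limit quadrants makes
the statistic reach 1 for completely separated clouds and collapse
exactly to the 1-D two-sample KS distance when one coordinate is
constant.

The kernel sweeps the pooled points in x order while maintaining Fenwick
trees over y ranks, giving O(n log n) per evaluation so the permutation
null is affordable even against a whole-transcriptome background cloud.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _max_quadrant_diffs(x_sorted, yrank_sorted, labels_sorted, cum_a, cum_b, n_a, n_b, m):
    n = x_sorted.size
    bit_a = np.zeros(m + 1, np.int64)
    bit_b = np.zeros(m + 1, np.int64)
    d_open = np.zeros(n, np.float64)
    d_a = 0.0
    d_b = 0.0
    count_a_lex = 0
    count_b_lex = 0
    i = 0
    while i < n:
        j = i
        while j < n and x_sorted[j] == x_sorted[i]:
            j += 1
        # open (left-limit) quadrants: BIT state excludes the x-tie group
        for t in range(i, j):
            r0 = yrank_sorted[t] - 1  # strictly-below-y count
            a11 = 0
            r = r0
            while r > 0:
                a11 += bit_a[r]
                r -= r & (-r)
            b11 = 0
            r = r0
            while r > 0:
                b11 += bit_b[r]
                r -= r & (-r)
            a_ley = cum_a[r0]
            b_ley = cum_b[r0]
            d = abs(a11 / n_a - b11 / n_b)
            d2 = abs((count_a_lex - a11) / n_a - (count_b_lex - b11) / n_b)
            if d2 > d:
                d = d2
            d2 = abs((a_ley - a11) / n_a - (b_ley - b11) / n_b)
            if d2 > d:
                d = d2
            d2 = abs(
                (n_a - count_a_lex - a_ley + a11) / n_a
                - (n_b - count_b_lex - b_ley + b11) / n_b
            )
            if d2 > d:
                d = d2
            d_open[t] = d
        for t in range(i, j):  # insert the whole x-tie group before closed queries
            r = yrank_sorted[t]
            if labels_sorted[t]:
                count_a_lex += 1
                while r <= m:
                    bit_a[r] += 1
                    r += r & (-r)
            else:
                count_b_lex += 1
                while r <= m:
                    bit_b[r] += 1
                    r += r & (-r)
        for t in range(i, j):
            r0 = yrank_sorted[t]
            a11 = 0
            r = r0
            while r > 0:
                a11 += bit_a[r]
                r -= r & (-r)
            b11 = 0
            r = r0
            while r > 0:
                b11 += bit_b[r]
                r -= r & (-r)
            a_ley = cum_a[r0]
            b_ley = cum_b[r0]
            d = d_open[t]
            d2 = abs(a11 / n_a - b11 / n_b)
            if d2 > d:
                d = d2
            d2 = abs((count_a_lex - a11) / n_a - (count_b_lex - b11) / n_b)
            if d2 > d:
                d = d2
            d2 = abs((a_ley - a11) / n_a - (b_ley - b11) / n_b)
            if d2 > d:
                d = d2
            d2 = abs(
                (n_a - count_a_lex - a_ley + a11) / n_a
                - (n_b - count_b_lex - b_ley + b11) / n_b
            )
            if d2 > d:
                d = d2
            if labels_sorted[t]:
                if d > d_a:
                    d_a = d
            else:
                if d > d_b:
                    d_b = d
        i = j
    return d_a, d_b


class _Pooled:
    """Precomputed pooled geometry shared across label permutations."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.n = x.size
        self.order = np.argsort(x, kind="mergesort")
        self.x_sorted = np.ascontiguousarray(x[self.order])
        uniq = np.unique(y)
        yrank = np.searchsorted(uniq, y) + 1
        self.m = len(uniq)
        self.yrank = yrank.astype(np.int64)
        self.yrank_sorted = np.ascontiguousarray(self.yrank[self.order])

    def stat(self, labels: np.ndarray) -> float:
        n_a = int(labels.sum())
        n_b = self.n - n_a
        cum_a = np.zeros(self.m + 1, dtype=np.int64)
        np.add.at(cum_a, self.yrank[labels], 1)
        cum_a = np.cumsum(cum_a)
        cum_b = np.zeros(self.m + 1, dtype=np.int64)
        np.add.at(cum_b, self.yrank[~labels], 1)
        cum_b = np.cumsum(cum_b)
        d_a, d_b = _max_quadrant_diffs(
            self.x_sorted,
            self.yrank_sorted,
            np.ascontiguousarray(labels[self.order]),
            cum_a,
            cum_b,
            n_a,
            n_b,
            self.m,
        )
        return 0.5 * (d_a + d_b)


def ff_statistic(a_points: np.ndarray, b_points: np.ndarray) -> float:
    """Fasano-Franceschini distance between two 2-D point clouds."""
    a_points = np.asarray(a_points, dtype=float)
    b_points = np.asarray(b_points, dtype=float)
    x = np.concatenate([a_points[:, 0], b_points[:, 0]])
    y = np.concatenate([a_points[:, 1], b_points[:, 1]])
    labels = np.zeros(len(x), dtype=bool)
    labels[: len(a_points)] = True
    return _Pooled(x, y).stat(labels)
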