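"""Independent oracles used by the test suite.

Deliberately written with primitive operations (numpy shifts, pure-Python
BFS, exhaustive enumeration) so they share no algorithmic path with the
package implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def floodfill_hole_count(mask: np.ndarray, fov: np.ndarray | None = None) -> int:
    """Count background components enclosed by foreground, by flood fill.

    Reachability from the border (and from outside the FOV) is computed with
    plain numpy shifts; the enclosed remainder is partitioned into
    4-connected components with a pure-Python BFS.
    """
    mask = np.asarray(mask, dtype=bool)
    if fov is None:
        fov = np.ones_like(mask)
    bg = ~mask
    seed = np.zeros_like(bg)
    seed[0, :] = seed[-1, :] = seed[:, 0] = seed[:, -1] = True
    seed |= ~fov
    seed &= bg
    reach = seed
    while True:
        grow = reach.copy()
        grow[1:, :] |= reach[:-1, :]
        grow[:-1, :] |= reach[1:, :]
        grow[:, 1:] |= reach[:, :-1]
        grow[:, :-1] |= reach[:, 1:]
        grow &= bg
        if np.array_equal(grow, reach):
            break
        reach = grow
    remaining = set(map(tuple, np.argwhere(bg & ~reach)))
    count = 0
    while remaining:
        count += 1
        stack = [remaining.pop()]
        while stack:
            r, c = stack.pop()
            for nb in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
                if nb in remaining:
                    remaining.remove(nb)
                    stack.append(nb)
    return count


def brute_force_nearest_background(
    mask: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Exhaustive min Euclidean distance (px) from each point to background."""
    bg = np.argwhere(~np.asarray(mask, dtype=bool)).astype(float)
    out = np.empty(len(points))
    for i, p in enumerate(np.asarray(points, dtype=float)):
        d2 = (bg[:, 0] - p[0]) ** 2 + (bg[:, 1] - p[1]) ** 2
        out[i] = np.sqrt(d2.min())
    return out


def pair_count_auc(scores, labels) -> float:
    """AUC by exhaustive positive/negative pair counting (ties count 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def enumerate_ranksum_p(x, y) -> float:
    """Exact two-tailed rank-sum p by enumerating all rank assignments.

    Requires tie-free samples.  The statistic is the rank sum of x; the
    two-tailed p is the null fraction of assignments at least as extreme
    (in |W - E[W]|) as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    assert np.unique(combined).size == combined.size, "tie-free samples required"
    ranks = np.argsort(np.argsort(combined)) + 1
    w_obs = ranks[: len(x)].sum()
    n = len(combined)
    mean_w = len(x) * (n + 1) / 2.0
    extreme = 0
    total = 0
    for subset in combinations(range(1, n + 1), len(x)):
        total += 1
        if abs(sum(subset) - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            extreme += 1
    return extreme / total


def naive_median_and_population_sd(values) -> tuple[float, float]:
    """Sort-based median (midpoint of central order stats) and two-pass
    population standard deviation."""
    v = sorted(float(u) for u in values)
    n = len(v)
    if n % 2 == 1:
        med = v[n // 2]
    else:
        med = (v[n // 2 - 1] + v[n // 2]) / 2.0
    mean = sum(v) / n
    var = sum((u - mean) ** 2 for u in v) / n
    return med, var**0.5


def random_blob_mask(rng: np.random.Generator, size: int) -> np.ndarray:
    """Smooth-noise blob mask with a mix of structures and holes."""
    from scipy import ndimage  # oracle generates inputs only; checks stay manual

    field = ndimage.gaussian_filter(
        rng.normal(size=(size, size)), sigma=rng.uniform(2.0, 6.0)
    )
    return field > rng.uniform(-0.3, 0.3)
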