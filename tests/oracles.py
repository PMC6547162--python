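"""Independent reference implementations used to check the package.

Everything here is deliberately written as plain loops / closed forms,
independent of the implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def yen_index_exhaustive(counts) -> int:
    """Argmax of the Yen maximum-correlation criterion by brute scan.

    Pure-Python loop over every candidate split of the histogram;
    ties take the smallest split index.
    """
    total = float(sum(counts))
    p = [c / total for c in counts]
    best_val, best_idx = None, None
    for t in range(len(p) - 1):
        p1 = sum(p[: t + 1])
        p1sq = sum(x * x for x in p[: t + 1])
        p2sq = sum(x * x for x in p[t + 1 :])
        if p1 <= 0.0 or p1 >= 1.0 or p1sq <= 0.0 or p2sq <= 0.0:
            continue
        crit = 2.0 * math.log(p1 * (1.0 - p1)) - math.log(p1sq * p2sq)
        if best_val is None or crit > best_val:
            best_val, best_idx = crit, t
    return best_idx


def bilinear(grid: np.ndarray, y: float, x: float) -> float:
    """Textbook bilinear interpolation at (y, x)."""
    y0, x0 = int(math.floor(y)), int(math.floor(x))
    y1 = min(y0 + 1, grid.shape[0] - 1)
    x1 = min(x0 + 1, grid.shape[1] - 1)
    fy, fx = y - y0, x - x0
    return float(
        grid[y0, x0] * (1 - fy) * (1 - fx)
        + grid[y1, x0] * fy * (1 - fx)
        + grid[y0, x1] * (1 - fy) * fx
        + grid[y1, x1] * fy * fx
    )


def local_maxima_scan(values) -> list[int]:
    """All local maxima by explicit neighbor comparison.

    Strictly greater than both neighbors; plateaus take the leftmost
    index; boundary samples need only beat their single neighbor.
    """
    v = list(values)
    n = len(v)
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left = v[i - 1] if i > 0 else None
        right = v[j + 1] if j + 1 < n else None
        cands = [c for c in (left, right) if c is not None]
        if cands and all(c < v[i] for c in cands):
            out.append(i)
        i = j + 1
    return out


def median_sort(values) -> float:
    """Median by explicit sort."""
    v = sorted(values)
    n = len(v)
    mid = n // 2
    if n % 2:
        return float(v[mid])
    return float((v[mid - 1] + v[mid]) / 2.0)


def one_sample_t(values, mu: float = 0.0):
    """One-sample t statistic and two-sided p from the t CDF."""
    from scipy.stats import t as tdist

    v = np.asarray(values, dtype=float)
    n = len(v)
    sd = v.std(ddof=1)
    t_stat = (v.mean() - mu) / (sd / math.sqrt(n))
    p = 2.0 * tdist.sf(abs(t_stat), n - 1)
    return t_stat, p


def paired_t(a, b):
    """Paired t statistic and two-sided p from the differences."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return one_sample_t(d, 0.0)
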