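"""Inter-kinetochore line profiles and two-brightest-peak extraction.

When pericentromeric cohesin sits *between* bioriented kinetochores, its
signal is read by sampling both colour channels along the straight
segment joining the two kinetochore centroids — over exactly the same
coordinates in every channel — and taking the two brightest local
maxima of the readout channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class LineProfile:
    """Samples along the segment between two points.

    ``positions`` are pixel distances from ``endpoints[0]``, strictly
    increasing from 0 to the segment length; ``intensities`` maps each
    channel key to the sampled values.  All channels are sampled at
    identical coordinates.
    """

    positions: np.ndarray
    intensities: dict
    endpoints: tuple[tuple[float, float], tuple[float, float]]

    @property
    def n_samples(self) -> int:
        return len(self.positions)


@dataclass
class PeakPair:
    """The two brightest local maxima of a profile channel.

    ``degenerate`` is set when fewer than two local maxima exist, in
    which case the global maximum is reported twice.
    """

    value_1: float
    value_2: float
    position_1: float
    position_2: float
    degenerate: bool = False


def _check_inside(p, shape) -> None:
    y, x = p
    if not (0 <= y <= shape[0] - 1 and 0 <= x <= shape[1] - 1):
        raise ValueError(f"endpoint {p} outside image of shape {shape}")


def sample_line(grids: dict, p1, p2) -> LineProfile:
    """Sample every channel along the segment from ``p1`` to ``p2``.

    Samples are evenly spaced at (approximately) unit-pixel intervals,
    inclusive of both endpoints — ``ceil(length) + 1`` samples, so the
    spacing is exactly 1 px for integer lengths and slightly finer
    otherwise, which keeps the sample set symmetric under endpoint
    reversal.  Interpolation is bilinear; the same sample coordinates
    are applied to every channel in ``grids`` (a mapping
    ``channel -> 2-D array``).
    """
    p1 = (float(p1[0]), float(p1[1]))
    p2 = (float(p2[0]), float(p2[1]))
    if p1 == p2:
        raise ValueError("endpoints must differ")
    shapes = {np.asarray(g).shape for g in grids.values()}
    if len(shapes) != 1:
        raise ValueError("all channels must share one shape")
    shape = shapes.pop()
    _check_inside(p1, shape)
    _check_inside(p2, shape)
    length = float(np.hypot(p2[0] - p1[0], p2[1] - p1[1]))
    n_samples = max(2, int(np.ceil(length)) + 1)
    positions = np.linspace(0.0, length, n_samples)
    frac = positions / length
    ys = p1[0] + frac * (p2[0] - p1[0])
    xs = p1[1] + frac * (p2[1] - p1[1])
    intensities = {
        ch: ndimage.map_coordinates(
            np.asarray(g, dtype=float), [ys, xs], order=1, mode="nearest"
        )
        for ch, g in grids.items()
    }
    return LineProfile(positions=positions, intensities=intensities, endpoints=(p1, p2))


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of strict local maxima; a plateau takes its leftmost index.

    Boundary samples count only when strictly greater than their single
    neighbor.
    """
    n = len(values)
    maxima: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_ok = i == 0 or values[i - 1] < values[i]
        right_ok = j == n - 1 or values[j + 1] < values[i]
        # a run spanning the whole profile has no neighbor to beat
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            maxima.append(i)
        i = j + 1
    return maxima


def two_brightest_peaks(profile: LineProfile, channel) -> PeakPair:
    """Rank local maxima of one channel by value and return the top two.

    Local maxima must be strictly greater than both neighbors (plateaus
    take the leftmost index; boundary samples need only beat their one
    neighbor).  If fewer than two exist, the global maximum is returned
    twice with ``degenerate=True``.
    """
    values = np.asarray(profile.intensities[channel], dtype=float)
    if len(values) < 3:
        raise ValueError("profile too short: need at least 3 samples")
    idx = _local_maxima(values)
    idx.sort(key=lambda i: (-values[i], profile.positions[i]))
    if len(idx) >= 2:
        i1, i2 = idx[0], idx[1]
        return PeakPair(
            value_1=float(values[i1]),
            value_2=float(values[i2]),
            position_1=float(profile.positions[i1]),
            position_2=float(profile.positions[i2]),
            degenerate=False,
        )
    g = int(np.argmax(values))
    return PeakPair(
        value_1=float(values[g]),
        value_2=float(values[g]),
        position_1=float(profile.positions[g]),
        position_2=float(profile.positions[g]),
        degenerate=True,
    )
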