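import numpy as np
import pytest

from meioquant.classify import CellTrajectory, Focus


def plant_gaussian(grid, y0, x0, amplitude, sigma):
    """Add a symmetric 2-D Gaussian of given peak amplitude in place."""
    yy, xx = np.mgrid[0 : grid.shape[0], 0 : grid.shape[1]]
    grid += amplitude * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sigma**2))
    return grid


def simple_trajectory(positions_by_frame, marker, intensities=None, secondary=None):
    """Build a CellTrajectory from per-frame lists of (y_um, x_um)."""
    foci = []
    for f, pts in enumerate(positions_by_frame):
        frame_foci = []
        for k, (y, x) in enumerate(pts):
            inten = intensities[f][k] if intensities else 100.0
            sec = secondary[f][k] if secondary else None
            frame_foci.append(Focus(y_um=y, x_um=x, intensity=inten, secondary_intensity=sec))
        foci.append(frame_foci)
    return CellTrajectory(cell_id="t", foci=foci, marker_state=list(marker))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
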