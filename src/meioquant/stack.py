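"""Calibrated multi-channel, multi-frame, multi-slice image stacks.

The in-memory layout is a 5-D array indexed ``(frame, z, channel, y, x)``
("TZCYX"), matching how time-lapse movies of sporulating yeast are
acquired: a handful of z-slices per time point in two colour channels,
with the pixel size (um/px) and the frame interval (min) carried as
calibration metadata.  Stacks round-trip through multi-page TIFF via
:mod:`tifffile`, with the axis order and calibration recorded in the
file's shaped metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

AXES = "TZCYX"


@dataclass
class ImageStack:
    """A calibrated movie: intensities indexed (frame, z, channel, y, x).

    Parameters
    ----------
    voxels
        Non-negative intensity grid of shape ``(T, Z, C, Y, X)``.
    pixel_size
        Lateral pixel size in micrometres per pixel; must be positive.
    frame_interval
        Time between frames in minutes.
    channel_names
        Label per channel, e.g. ``("tdTomato", "GFP")``.
    """

    voxels: np.ndarray
    pixel_size: float
    frame_interval: float = 15.0
    channel_names: tuple[str, ...] = ("tdTomato", "GFP")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 5:
            raise ValueError(
                f"voxels must be 5-D (T, Z, C, Y, X); got {self.voxels.ndim}-D"
            )
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if len(self.channel_names) != self.voxels.shape[2]:
            raise ValueError("channel_names length must match channel axis")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[2]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


def write_tiff(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF with calibration metadata.

    Dimension order T, Z, C, Y, X is documented in the file metadata
    (``axes`` key).  ``datetime`` is suppressed so that identical stacks
    serialize to byte-identical files.
    """
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        metadata={
            "axes": AXES,
            "pixel_size_um": stack.pixel_size,
            "frame_interval_min": stack.frame_interval,
            "channel_names": list(stack.channel_names),
        },
        datetime=False,
    )


def read_tiff(path) -> ImageStack:
    """Read a stack written by :func:`write_tiff`."""
    with tifffile.TiffFile(path) as tif:
        voxels = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if voxels.ndim != 5:
        raise ValueError(f"expected a 5-D ({AXES}) TIFF; got {voxels.ndim}-D")
    return ImageStack(
        voxels=voxels,
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        frame_interval=float(meta.get("frame_interval_min", 15.0)),
        channel_names=tuple(meta.get("channel_names", [str(c) for c in range(voxels.shape[2])])),
    )
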