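"""Calibrated image-stack container and TIFF round-trip.

Movies are multi-page TIFFs with ImageJ-style metadata: the frame interval
is stored in ``finterval`` (seconds) and the pixel size in the TIFF
resolution tags (pixels per micron).
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Movie:
    """A time-lapse stack with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity frames, time first.
    pixel_size : float
        Microns per pixel.
    frame_interval : float
        Seconds between consecutive frames.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


def write_movie(path: str | Path, movie: Movie) -> None:
    """Write a movie as a 16-bit ImageJ-style multi-page TIFF."""
    frames = np.clip(np.round(movie.frames), 0, 65535).astype(np.uint16)
    ppu = 1.0 / movie.pixel_size  # pixels per micron
    tifffile.imwrite(
        path,
        frames,
        imagej=True,
        resolution=(ppu, ppu),
        metadata={
            "unit": "um",
            "finterval": movie.frame_interval,
            "axes": "TYX",
        },
    )


def _resolution_to_pixel_size(tag_value) -> float:
    num, den = tag_value
    ppu = float(Fraction(int(num), int(den)))
    if ppu <= 0:
        raise ValueError("invalid resolution tag")
    return 1.0 / ppu


def read_movie(path: str | Path) -> Movie:
    """Read a calibrated movie written by :func:`write_movie`."""
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        if frames.ndim == 2:
            frames = frames[None]
        meta = tif.imagej_metadata or {}
        interval = float(meta.get("finterval", 1.0))
        page = tif.pages[0]
        try:
            pixel_size = _resolution_to_pixel_size(page.tags["XResolution"].value)
        except (KeyError, ValueError):
            pixel_size = 1.0
    return Movie(frames=frames.astype(np.float64), pixel_size=pixel_size,
                 frame_interval=interval)
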