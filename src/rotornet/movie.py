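"""Activation-movie containers and file I/O.

A *movie* is a time-ordered stack of 2D scalar fields on a square cell grid
with a known physical cell spacing.  Voltage movies hold the raw model
voltage; binary movies hold thresholded activation maps (the form every
downstream network stage consumes).

Movies are stored on disk as multi-page TIFF (one page per frame; 32-bit
float for voltage, 8-bit for binary) with a JSON sidecar carrying the frame
interval, the mm-per-cell calibration and any provenance metadata.  A
directory of pre-binarized PNG frames (e.g. an externally exported
activation video) can be imported as a :class:`BinaryMovie`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VoltageMovie",
    "BinaryMovie",
    "binarize",
    "write_movie",
    "read_movie",
    "import_png_frames",
]


@dataclass
class VoltageMovie:
    """T x H x W stack of model voltage frames.

    Parameters
    ----------
    frames
        Array of shape (T, H, W), finite values, float.
    frame_interval
        Wall time per frame, seconds.
    mm_per_cell
        Physical edge length of one grid cell, millimetres.
    meta
        Free-form provenance (simulation parameters, seed, ...).
    """

    frames: np.ndarray
    frame_interval: float
    mm_per_cell: float = 0.3
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack")
        if not np.isfinite(self.frames).all():
            raise ValueError("voltage frames contain non-finite values")
        if self.mm_per_cell <= 0:
            raise ValueError("mm_per_cell must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class BinaryMovie:
    """T x H x W boolean activation stack (1 = excited)."""

    frames: np.ndarray
    frame_interval: float
    mm_per_cell: float = 0.3
    threshold_used: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.dtype != np.bool_:
            uniq = np.unique(self.frames)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("binary frames must contain only 0/1 values")
            self.frames = self.frames.astype(bool)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.mm_per_cell <= 0:
            raise ValueError("mm_per_cell must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def binarize(movie: VoltageMovie | BinaryMovie, threshold: float) -> BinaryMovie:
    """Threshold a movie: frame value 1 wherever voltage >= ``threshold``.

    The >= convention means a frame exactly at the threshold maps to 1.
    Binarizing an already-binary movie at 0.5 is the identity.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    frames = np.asarray(movie.frames)
    return BinaryMovie(
        frames=frames >= threshold,
        frame_interval=movie.frame_interval,
        mm_per_cell=movie.mm_per_cell,
        threshold_used=float(threshold),
        meta=dict(movie.meta),
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: VoltageMovie | BinaryMovie, path: str | Path) -> Path:
    """Write a movie as a multi-page TIFF plus a JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    if isinstance(movie, BinaryMovie):
        data = movie.frames.astype(np.uint8)
        kind = "binary"
    else:
        data = movie.frames.astype(np.float32)
        kind = "voltage"
    tifffile.imwrite(path, data)
    sidecar = {
        "kind": kind,
        "frame_interval": movie.frame_interval,
        "mm_per_cell": movie.mm_per_cell,
        "meta": movie.meta,
    }
    if isinstance(movie, BinaryMovie):
        sidecar["threshold_used"] = movie.threshold_used
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_movie(path: str | Path) -> VoltageMovie | BinaryMovie:
    """Read a movie written by :func:`write_movie`."""
    import tifffile

    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    side = json.loads(_sidecar_path(path).read_text())
    common = dict(
        frame_interval=float(side["frame_interval"]),
        mm_per_cell=float(side["mm_per_cell"]),
        meta=side.get("meta", {}),
    )
    if side.get("kind") == "binary":
        return BinaryMovie(
            frames=frames.astype(bool),
            threshold_used=float(side.get("threshold_used", float("nan"))),
            **common,
        )
    return VoltageMovie(frames=frames, **common)


def import_png_frames(
    directory: str | Path,
    frame_interval: float,
    mm_per_cell: float,
    threshold: float = 127.0,
) -> BinaryMovie:
    """Import a directory of PNG frames (sorted by filename) as a BinaryMovie.

    Pixels with grey value >= ``threshold`` (on the file's own scale,
    default 127 for 8-bit frames) are treated as excited.  Colour frames are
    averaged over channels first.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    files = sorted(directory.glob("*.png"))
    if not files:
        raise FileNotFoundError(f"no PNG frames found in {directory}")
    frames = []
    for f in files:
        img = np.asarray(iio.imread(f), dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=-1)
        frames.append(img >= threshold)
    stack = np.stack(frames)
    return BinaryMovie(
        frames=stack,
        frame_interval=frame_interval,
        mm_per_cell=mm_per_cell,
        threshold_used=float(threshold),
        meta={"source": str(directory), "n_files": len(files)},
    )
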