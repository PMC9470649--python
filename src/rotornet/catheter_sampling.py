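"""Virtual high-resolution mapping-catheter geometries and signal extraction.

Two investigational 48-electrode layouts are modeled:

``flower``
    Eight radial 2 cm splines separated by 45 degrees, six electrodes per
    spline spaced 2 mm apart with the outermost at the spline tip
    (radii 10, 12, ..., 20 mm).
``grid``
    Six parallel splines with 2.14 mm pitch, eight electrodes per spline
    spaced 2 mm apart (at +-1, +-3, +-5, +-7 mm along the spline), centred
    on the catheter centre.

Sampling follows the averaged-neighbourhood rule: each electrode's mm
position is converted to fractional cell coordinates, the 2x2 block of
cells surrounding that point is averaged per frame, and the average is
rounded to {0, 1} with ties (0.5) rounding up.  The 0.5 mm physical
electrode length is represented only through this four-cell footprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .movie import BinaryMovie

__all__ = [
    "CatheterGeometry",
    "CatheterPlacement",
    "ElectrodeSignals",
    "build_geometry",
    "sample_electrodes",
    "place_catheters",
    "write_geometry_csv",
    "read_geometry_csv",
    "write_signals",
    "read_signals",
]

N_ELECTRODES = 48
ELECTRODE_LENGTH_MM = 0.5
FLOWER_RADII_MM = (10.0, 12.0, 14.0, 16.0, 18.0, 20.0)
GRID_ALONG_MM = (-7.0, -5.0, -3.0, -1.0, 1.0, 3.0, 5.0, 7.0)
GRID_PITCH_MM = 2.14


@dataclass(frozen=True)
class CatheterGeometry:
    """Named, ordered set of 48 electrode centres in mm about the catheter
    centre (x right, y down, matching movie row/column orientation)."""

    name: str
    electrode_xy: np.ndarray
    electrode_length_mm: float = ELECTRODE_LENGTH_MM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        xy = np.asarray(self.electrode_xy, dtype=float)
        if xy.shape != (N_ELECTRODES, 2):
            raise ValueError(f"geometry must have exactly {N_ELECTRODES} electrodes")
        if len(np.unique(np.round(xy, 9), axis=0)) != N_ELECTRODES:
            raise ValueError("electrode coordinates must be unique")
        object.__setattr__(self, "electrode_xy", xy)

    @property
    def n_electrodes(self) -> int:
        return N_ELECTRODES


@dataclass(frozen=True)
class CatheterPlacement:
    """Catheter centre in movie mm coordinates plus an in-plane rotation."""

    center_xy: tuple[float, float]
    rotation: float = 0.0

    def transform(self, electrode_xy: np.ndarray) -> np.ndarray:
        """Electrode positions in movie mm coordinates."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.array([[c, -s], [s, c]])
        return np.asarray(electrode_xy) @ rot.T + np.asarray(self.center_xy)


@dataclass
class ElectrodeSignals:
    """48 x T binary matrix of per-electrode activation sequences."""

    signals: np.ndarray
    geometry_name: str
    placement: CatheterPlacement
    frame_interval: float

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals)
        if sig.ndim != 2 or sig.shape[0] != N_ELECTRODES:
            raise ValueError(f"signals must be ({N_ELECTRODES}, T)")
        if sig.dtype != np.bool_:
            if not np.all(np.isin(np.unique(sig), (0, 1))):
                raise ValueError("signals must be binary")
            sig = sig.astype(bool)
        self.signals = sig

    @property
    def n_frames(self) -> int:
        return self.signals.shape[1]


def build_geometry(name: str) -> CatheterGeometry:
    """Construct the named 48-electrode catheter layout."""
    if name == "flower":
        pts = []
        for spline in range(8):
            ang = np.deg2rad(45.0 * spline)
            for radius in FLOWER_RADII_MM:
                pts.append((radius * np.cos(ang), radius * np.sin(ang)))
        meta = {"splines": 8, "per_spline": 6, "spline_length_mm": 20.0}
    elif name == "grid":
        offsets = (np.arange(6) - 2.5) * GRID_PITCH_MM
        pts = [(x, y) for y in offsets for x in GRID_ALONG_MM]
        meta = {"splines": 6, "per_spline": 8, "pitch_mm": GRID_PITCH_MM}
    else:
        raise ValueError(
            f"unknown geometry {name!r}; supported geometries: 'flower', 'grid'"
        )
    return CatheterGeometry(name=name, electrode_xy=np.array(pts), metadata=meta)


def _block_indices(
    movie: BinaryMovie, geometry: CatheterGeometry, placement: CatheterPlacement
) -> tuple[np.ndarray, np.ndarray]:
    """Top-left cell index (col0, row0) of each electrode's 2x2 block.

    Raises if any electrode's block falls outside the movie domain.
    """
    pos_mm = placement.transform(geometry.electrode_xy)
    cells = pos_mm / movie.mm_per_cell  # fractional (x=col, y=row)
    col0 = np.floor(cells[:, 0]).astype(int)
    row0 = np.floor(cells[:, 1]).astype(int)
    h, w = movie.shape
    bad = (col0 < 0) | (row0 < 0) | (col0 + 1 >= w) | (row0 + 1 >= h)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"electrode {i} at ({pos_mm[i, 0]:.2f}, {pos_mm[i, 1]:.2f}) mm "
            f"(cell {cells[i, 0]:.2f}, {cells[i, 1]:.2f}) falls outside the "
            f"{h}x{w}-cell movie domain"
        )
    return col0, row0


def sample_electrodes(
    movie: BinaryMovie, geometry: CatheterGeometry, placement: CatheterPlacement
) -> ElectrodeSignals:
    """Extract one binary time series per electrode.

    Per frame, the four cells of the 2x2 block surrounding the electrode's
    fractional cell position are averaged and rounded half-up.
    """
    col0, row0 = _block_indices(movie, geometry, placement)
    frames = movie.frames
    block_sum = (
        frames[:, row0, col0].astype(np.uint8)
        + frames[:, row0, col0 + 1]
        + frames[:, row0 + 1, col0]
        + frames[:, row0 + 1, col0 + 1]
    )
    # mean >= 0.5 of four cells <=> sum >= 2 (ties round up)
    return ElectrodeSignals(
        signals=(block_sum.T >= 2),
        geometry_name=geometry.name,
        placement=placement,
        frame_interval=movie.frame_interval,
    )


def place_catheters(
    movie: BinaryMovie,
    geometry: CatheterGeometry,
    n_positions: int,
    strategy: str = "around_point",
    *,
    ref_xy_mm: tuple[float, float] | None = None,
    radius_mm: float = 10.0,
    seed: int = 0,
    rotation: float = 0.0,
    centers: list[tuple[float, float]] | None = None,
    max_tries_per_position: int = 500,
) -> list[CatheterPlacement]:
    """Generate validated catheter placements.

    ``around_point`` draws centres uniformly from a disc of ``radius_mm``
    about ``ref_xy_mm`` (default: the domain centre) with a seeded generator;
    ``explicit`` validates and passes through user-supplied ``centers``.
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    h, w = movie.shape
    if strategy == "explicit":
        if centers is None or len(centers) != n_positions:
            raise ValueError("explicit strategy requires n_positions centers")
        placements = [
            CatheterPlacement(center_xy=(float(x), float(y)), rotation=rotation)
            for x, y in centers
        ]
        for pl in placements:
            _block_indices(movie, geometry, pl)
        return placements
    if strategy != "around_point":
        raise ValueError("strategy must be 'around_point' or 'explicit'")

    if ref_xy_mm is None:
        ref_xy_mm = (w / 2.0 * movie.mm_per_cell, h / 2.0 * movie.mm_per_cell)
    rng = np.random.default_rng(seed)
    placements: list[CatheterPlacement] = []
    tries = 0
    while len(placements) < n_positions:
        if tries >= max_tries_per_position * n_positions:
            raise RuntimeError(
                f"could not find {n_positions} in-bounds placements within "
                f"{tries} draws; reduce radius_mm or move ref_xy_mm inward"
            )
        tries += 1
        r = radius_mm * np.sqrt(rng.random())
        phi = 2 * np.pi * rng.random()
        center = (ref_xy_mm[0] + r * np.cos(phi), ref_xy_mm[1] + r * np.sin(phi))
        candidate = CatheterPlacement(center_xy=center, rotation=rotation)
        try:
            _block_indices(movie, geometry, candidate)
        except ValueError:
            continue
        placements.append(candidate)
    return placements


def write_geometry_csv(geometry: CatheterGeometry, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "electrode_id": np.arange(N_ELECTRODES),
            "x_mm": geometry.electrode_xy[:, 0],
            "y_mm": geometry.electrode_xy[:, 1],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_geometry_csv(path: str | Path, name: str = "custom") -> CatheterGeometry:
    df = pd.read_csv(path)
    xy = df.sort_values("electrode_id")[["x_mm", "y_mm"]].to_numpy()
    return CatheterGeometry(name=name, electrode_xy=xy)


def write_signals(signals: ElectrodeSignals, path: str | Path) -> Path:
    """Electrode x frame CSV plus a JSON sidecar with placement metadata."""
    path = Path(path)
    df = pd.DataFrame(signals.signals.astype(np.uint8))
    df.insert(0, "electrode_id", np.arange(N_ELECTRODES))
    df.to_csv(path, index=False)
    side = {
        "geometry": signals.geometry_name,
        "center_xy_mm": list(signals.placement.center_xy),
        "rotation_rad": signals.placement.rotation,
        "frame_interval": signals.frame_interval,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(side, indent=1, sort_keys=True)
    )
    return path


def read_signals(path: str | Path) -> ElectrodeSignals:
    path = Path(path)
    df = pd.read_csv(path)
    sig = df.drop(columns=["electrode_id"]).to_numpy()
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ElectrodeSignals(
        signals=sig,
        geometry_name=side["geometry"],
        placement=CatheterPlacement(
            center_xy=tuple(side["center_xy_mm"]), rotation=side["rotation_rad"]
        ),
        frame_interval=side["frame_interval"],
    )
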