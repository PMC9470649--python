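"""Analytic binary activation movies with known structure.

These generators produce the two activation archetypes the network pipeline
must tell apart — a rotating spiral (phase-organized, periodic everywhere)
and spatially incoherent irregular activity — directly from closed-form
expressions, so every downstream stage (catheter sampling, mutual
information, efficiency curves) can be tested in milliseconds against known
answers without integrating the reaction–diffusion model.

They are test surrogates, not physiology: the spiral has a rigidly rotating
Archimedean phase field with no core meander, conduction-velocity
restitution or wavefront curvature effects, and the irregular generator is
thresholded space–time correlated noise with no refractoriness at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .movie import BinaryMovie

__all__ = ["SpiralSpec", "IrregularSpec", "make_spiral_movie", "make_irregular_movie"]


@dataclass(frozen=True)
class SpiralSpec:
    """Rigidly rotating binary spiral.

    A pixel at polar coordinates (r, theta) about ``core_xy`` is "on" at
    frame t iff frac((theta - omega t + k r) / 2pi) < duty_cycle, i.e. an
    Archimedean spiral of angular velocity ``angular_velocity`` (rad/frame)
    and radial wavenumber ``spatial_wavenumber`` (rad/cell) sweeps the
    plane; ``duty_cycle`` is the fraction of each cycle a pixel is excited.
    """

    grid_n: int = 64
    n_frames: int = 600
    angular_velocity: float = 2 * np.pi / 25
    # wavelength 60 cells (18 mm at 0.3 mm/cell): large against the 2 mm
    # electrode pitch, as for a physiological rotor under a mapping catheter
    spatial_wavenumber: float = 2 * np.pi / 60
    core_xy: tuple[float, float] | None = None
    duty_cycle: float = 0.35
    mm_per_cell: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty_cycle must be in (0, 1)")
        if self.angular_velocity == 0:
            raise ValueError("angular_velocity must be nonzero")
        if self.grid_n < 2 or self.n_frames < 1:
            raise ValueError("grid_n >= 2 and n_frames >= 1 required")

    @property
    def period_frames(self) -> float:
        return 2 * np.pi / abs(self.angular_velocity)


@dataclass(frozen=True)
class IrregularSpec:
    """Spatially and temporally correlated binary noise.

    White Gaussian noise is smoothed with an AR(1) process in time
    (decorrelating over ``correlation_time`` frames; 1 means independent
    frames) and an isotropic Gaussian kernel of width ``correlation_length``
    cells in space, then thresholded at the movie-wide quantile that leaves
    ``on_fraction`` of all pixels excited.
    """

    grid_n: int = 64
    n_frames: int = 600
    correlation_length: float = 3.0
    correlation_time: float = 3.0
    on_fraction: float = 0.35
    seed: int = 0
    mm_per_cell: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.on_fraction < 1:
            raise ValueError("on_fraction must be in (0, 1)")
        if self.correlation_length < 1:
            raise ValueError("correlation_length must be >= 1 cell")
        if self.correlation_time < 1:
            raise ValueError("correlation_time must be >= 1 frame")


def make_spiral_movie(spec: SpiralSpec) -> BinaryMovie:
    """Render the rotating-spiral movie defined by ``spec``.

    Every pixel's time series is periodic with period 2pi/omega frames, and
    pixels at equal radius are circular time shifts of one another — the
    idealized signature of rotational (driver) activation.
    """
    n = spec.grid_n
    core = spec.core_xy if spec.core_xy is not None else ((n - 1) / 2.0, (n - 1) / 2.0)
    y, x = np.mgrid[0:n, 0:n]
    dx = x - core[0]
    dy = y - core[1]
    theta = np.arctan2(dy, dx)
    r = np.hypot(dx, dy)
    t = np.arange(spec.n_frames)[:, None, None]
    phase = (
        theta[None] - spec.angular_velocity * t + spec.spatial_wavenumber * r[None]
    ) / (2 * np.pi)
    frames = (phase - np.floor(phase)) < spec.duty_cycle
    return BinaryMovie(
        frames=frames,
        frame_interval=1.0 / 150.0,
        mm_per_cell=spec.mm_per_cell,
        threshold_used=spec.duty_cycle,
        meta={"generator": "spiral", "period_frames": spec.period_frames},
    )


def make_irregular_movie(spec: IrregularSpec) -> BinaryMovie:
    """Render the incoherent-activation movie defined by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((spec.n_frames, spec.grid_n, spec.grid_n))
    # AR(1) in time; rho = 1 - 1/correlation_time so ct=1 -> independent frames.
    rho = max(0.0, 1.0 - 1.0 / spec.correlation_time)
    if rho > 0:
        scale = np.sqrt(1.0 - rho**2)
        for k in range(1, spec.n_frames):
            noise[k] = rho * noise[k - 1] + scale * noise[k]
    if spec.correlation_length > 0:
        ndimage.gaussian_filter(
            noise, sigma=(0.0, spec.correlation_length, spec.correlation_length),
            output=noise, mode="nearest",
        )
    cut = np.quantile(noise, 1.0 - spec.on_fraction)
    return BinaryMovie(
        frames=noise >= cut,
        frame_interval=1.0 / 150.0,
        mm_per_cell=spec.mm_per_cell,
        threshold_used=float(cut),
        meta={"generator": "irregular", "seed": spec.seed},
    )
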