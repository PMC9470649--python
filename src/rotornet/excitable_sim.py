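"""Two-variable Karma model of cardiac excitation on a 2D sheet.

The Karma model is a two-variable reduction of cardiac membrane dynamics: a
fast voltage ``u`` and a slow repolarization gate ``n``,

    du/dt = D lap(u) - u + (u* - (n/n_B)^m) (1 - tanh(u - 3)) u^2 / 2
    dn/dt = eps r(u) (H(u - 1) - n)

with ``H`` the Heaviside step, ``u* = 1.5415`` and ``r(u)`` an open/close
rate asymmetry (1 while excited, 1/3 during diastolic recovery, as in
minimal models with separate gate time constants).  ``n_B`` is the
restitution parameter that sets action-potential duration and restitution
steepness, ``m`` the exponent controlling how sharply the gate suppresses
the excited state, and ``eps`` the ratio of the voltage to the gate time
scale.  The exposed parameter ``nb`` is mapped to ``n_B = nb / 1.25``: with
``u* = 1.5415`` the excited branch folds exactly at ``n = n_B``, so the
rescaling places ``nb = 1.0`` (the stable-spiral preset) safely below the
gate plateau while AP duration grows — and the spiral destabilizes — as
``nb`` rises toward 1.25.  The model
reproduces action-potential duration and conduction-velocity restitution —
the properties that govern spiral-wave stability — which is why it is the
standard minimal setting for studying rotational (driver-like) versus
broken-up (fibrillation-like) activation.

Integration is explicit forward Euler with a 5-point Laplacian and no-flux
(Neumann) boundaries, ``dx = 1`` model space unit per cell.  The time base
is anchored by convention to conduction: one *simulated second* is the time
a plane wave needs to cross the domain, so ``duration_s`` controls how many
rotor cycles the movie spans regardless of grid size.

Two packaged regimes:

``spiral``
    Cross-field S1/S2 initiation at the default parameters produces a single
    sustained rotor (one phase singularity) for the rest of the run.
``breakup``
    Same initiation with the restitution parameter raised past the
    spiral-stability boundary (``nb = 1.1``, calibrated once by sweeping nb
    upward until multi-wavelet activity persisted); the initiated spiral
    fragments into self-sustained irregular wavelets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .movie import BinaryMovie, VoltageMovie, binarize

__all__ = [
    "KarmaParams",
    "KarmaInstabilityError",
    "RegimeError",
    "simulate_karma",
    "calibration_threshold",
    "binarize_karma",
    "count_wavefronts",
    "phase_singularities",
    "singularity_centroid",
    "BREAKUP_NB",
    "PLANE_WAVE_SPEED",
]

U_STAR = 1.5415
STIM_AMPLITUDE = 3.0

# The exposed nb maps to the canonical restitution parameter n_B = nb / GATE_MARGIN,
# keeping the printed spiral value nb = 1.0 below the fold-at-plateau boundary nb = GATE_MARGIN.
GATE_MARGIN = 1.25

# Gate recovery (diastolic reopening) is slower than closure by this factor,
# as in minimal cardiac models with separate open/close time constants; it
# flattens APD restitution at the spiral's operating diastolic interval.
GATE_RECOVERY_RATIO = 1.0 / 3.0

# Plane-wave conduction speed in cells per model time unit at the default
# parameters (diffusion=1, dx=1), measured once from a 1D strip run; scales
# as sqrt(diffusion).  Anchors the model-time <-> seconds convention.
PLANE_WAVE_SPEED = 1.33

# Restitution parameter of the packaged breakup preset (spiral preset uses
# nb from the params, default 1.0).  Calibrated by raising nb until the
# initiated spiral fragments into sustained multi-wavelet activity.
BREAKUP_NB = 1.1

# S2 is delivered when the S1 wave tail has cleared roughly half the domain:
# at this fraction of the domain-crossing time after S1.
S2_CROSSING_FRACTION = 0.55


class KarmaInstabilityError(RuntimeError):
    """The explicit integration produced non-finite fields."""


class RegimeError(RuntimeError):
    """The requested activation regime was not reached after initiation."""


@dataclass(frozen=True)
class KarmaParams:
    """Parameters of one 2D Karma run.

    Attributes
    ----------
    grid_n
        Cells per side of the square sheet (>= 64).
    nb, m, eps
        Dimensionless model parameters: restitution / AP-duration parameter
        (internally rescaled to the canonical n_B), suppression exponent
        (wavefront sensitivity) and voltage-to-gate time-scale ratio.
    diffusion, dx, dt
        Voltage diffusion coefficient, cell spacing and Euler step, in model
        units.  Explicit stability requires dt <= dx^2 / (4 diffusion).
    duration_s
        Recorded wall time in seconds, where one second is the
        domain-crossing time of a plane wave.
    n_frames
        Number of uniformly strided frames exported over ``duration_s``.
    settle_s
        Unrecorded burn-in after initiation, seconds: frames are extracted
        only once the requested activity pattern is established, so the
        movie contains no stimulus artefacts.
    seed
        Seed for the small gate-noise perturbation that breaks grid symmetry.
    mm_per_cell
        Physical calibration attached to the exported movie, millimetres.
    """

    grid_n: int = 512
    nb: float = 1.0
    m: float = 7.0
    eps: float = 0.4
    diffusion: float = 4.0
    dx: float = 1.0
    dt: float = 0.05
    duration_s: float = 10.0
    n_frames: int = 1500
    settle_s: float = 2.0
    seed: int = 0
    mm_per_cell: float = 0.3

    def __post_init__(self) -> None:
        if self.grid_n < 64:
            raise ValueError("grid_n must be >= 64")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.settle_s < 0:
            raise ValueError("settle_s must be non-negative")
        bound = self.stability_bound
        if self.dt > bound:
            raise ValueError(
                f"dt={self.dt} violates the explicit-scheme stability bound "
                f"dt <= dx^2/(4*diffusion) = {bound:.6g}"
            )

    @property
    def stability_bound(self) -> float:
        return self.dx**2 / (4.0 * self.diffusion)

    @property
    def crossing_time(self) -> float:
        """Model time for a plane wave to cross the domain (== 1 second)."""
        speed = PLANE_WAVE_SPEED * np.sqrt(self.diffusion) / self.dx
        return self.grid_n / speed

    @property
    def total_model_time(self) -> float:
        return (self.settle_s + self.duration_s) * self.crossing_time

    @property
    def frame_interval(self) -> float:
        """Seconds of simulated wall time per exported frame."""
        return self.duration_s / self.n_frames


def _reaction(u: np.ndarray, n: np.ndarray, m: float, nb: float) -> np.ndarray:
    scaled = n * (GATE_MARGIN / nb)
    if m == int(m):
        nm = scaled ** int(m)
    else:
        nm = np.power(np.maximum(scaled, 0.0), m)
    return -u + 0.5 * (U_STAR - nm) * (1.0 - np.tanh(u - 3.0)) * u * u


def _laplacian_neumann(u: np.ndarray, out: np.ndarray) -> np.ndarray:
    # 5-point stencil with mirrored (no-flux) edges.
    out[:] = -4.0 * u
    out[1:, :] += u[:-1, :]
    out[0, :] += u[0, :]
    out[:-1, :] += u[1:, :]
    out[-1, :] += u[-1, :]
    out[:, 1:] += u[:, :-1]
    out[:, 0] += u[:, 0]
    out[:, :-1] += u[:, 1:]
    out[:, -1] += u[:, -1]
    return out


def simulate_karma(
    params: KarmaParams,
    regime: str = "spiral",
    *,
    stimulus: str = "cross_field",
    check: bool = True,
) -> VoltageMovie:
    """Integrate the Karma sheet and export a voltage movie.

    Parameters
    ----------
    params
        Run parameters.  For ``regime="breakup"`` an nb left at the spiral
        default (1.0) is replaced by the packaged breakup value
        :data:`BREAKUP_NB`; an explicitly different nb is respected.
    regime
        ``"spiral"`` (single sustained rotor) or ``"breakup"``
        (multi-wavelet irregular activity after spiral fragmentation).
    stimulus
        ``"cross_field"`` (default S1/S2 rotor initiation), ``"s1"`` (plane
        wave only), ``"corner"`` (point stimulus in one corner) or
        ``"none"`` (free evolution from rest).
    check
        Verify the requested regime on the final half of the movie and raise
        :class:`RegimeError` if it was not reached.
    """
    if regime not in ("spiral", "breakup"):
        raise ValueError("regime must be 'spiral' or 'breakup'")
    if stimulus not in ("cross_field", "s1", "corner", "none"):
        raise ValueError(f"unknown stimulus protocol: {stimulus!r}")
    if regime == "breakup" and params.nb == 1.0:
        params = replace(params, nb=BREAKUP_NB)

    n_grid = params.grid_n
    dtype = np.float64
    u = np.zeros((n_grid, n_grid), dtype=dtype)
    gate = np.zeros_like(u)
    lap = np.empty_like(u)

    if stimulus != "none":
        # Tiny seeded gate perturbation: breaks the grid symmetry so that
        # breakup wavelets do not inherit an artificial mirror symmetry.
        rng = np.random.default_rng(params.seed)
        gate += 1e-3 * rng.random(gate.shape)

    dt = params.dt
    d_over_dx2 = params.diffusion / params.dx**2
    settle_steps = int(round(params.settle_s * params.crossing_time / dt))
    record_steps = max(
        int(round(params.duration_s * params.crossing_time / dt)), params.n_frames
    )
    total_steps = settle_steps + record_steps
    frame_steps = settle_steps + np.floor(
        np.arange(params.n_frames) * (record_steps / params.n_frames)
    ).astype(int)
    frame_set = {}
    for idx, step in enumerate(frame_steps):
        frame_set.setdefault(int(step), []).append(idx)

    s2_step = int(round(S2_CROSSING_FRACTION * params.crossing_time / dt))
    frames = np.empty((params.n_frames, n_grid, n_grid), dtype=np.float32)

    if stimulus in ("cross_field", "s1"):
        u[:, : max(4, n_grid // 100)] = STIM_AMPLITUDE
    elif stimulus == "corner":
        w = max(4, n_grid // 32)
        u[:w, :w] = STIM_AMPLITUDE

    for step in range(total_steps):
        if stimulus == "cross_field" and step == s2_step:
            np.maximum(u[: n_grid // 2, :], STIM_AMPLITUDE, out=u[: n_grid // 2, :])
        if step in frame_set:
            f32 = u.astype(np.float32)
            for idx in frame_set[step]:
                frames[idx] = f32
        _laplacian_neumann(u, lap)
        du = _reaction(u, gate, params.m, params.nb)
        du += d_over_dx2 * lap
        excited = u > 1.0
        rate = np.where(excited, 1.0, GATE_RECOVERY_RATIO)
        dn = params.eps * rate * (excited - gate)
        u += dt * du
        gate += dt * dn
        if step % 200 == 0 and not np.isfinite(u[:: n_grid // 8, :: n_grid // 8]).all():
            raise KarmaInstabilityError(
                "non-finite voltage during integration; the explicit scheme "
                f"requires dt <= dx^2/(4*diffusion) = {params.stability_bound:.6g} "
                f"(got dt={dt}) and a reaction-resolved step (try halving dt)"
            )

    if not np.isfinite(frames).all():
        raise KarmaInstabilityError(
            "non-finite voltage in exported frames; reduce dt below "
            f"{params.stability_bound:.6g}"
        )

    movie = VoltageMovie(
        frames=frames,
        frame_interval=params.frame_interval,
        mm_per_cell=params.mm_per_cell,
        meta={
            "model": "karma2d",
            "regime": regime,
            "stimulus": stimulus,
            "params": {
                "grid_n": params.grid_n,
                "nb": params.nb,
                "m": params.m,
                "eps": params.eps,
                "diffusion": params.diffusion,
                "dx": params.dx,
                "dt": params.dt,
                "duration_s": params.duration_s,
                "n_frames": params.n_frames,
                "seed": params.seed,
            },
        },
    )
    if check and stimulus == "cross_field":
        _check_regime(movie, params, regime)
    return movie


def _check_regime(movie: VoltageMovie, params: KarmaParams, regime: str) -> None:
    threshold = calibration_threshold(params)
    binary = binarize(movie, threshold)
    half = binary.frames[binary.n_frames // 2 :]
    # Subsample frames for the check; dynamics are slow on the frame scale.
    sel = half[:: max(1, len(half) // 40)]
    counts = count_wavefronts(sel)
    if regime == "spiral":
        ps = phase_singularities(movie.frames[movie.n_frames // 2 :: max(1, movie.n_frames // 80)])
        frac_with_ps = float(np.mean([len(p) >= 1 for p in ps]))
        if frac_with_ps < 0.9:
            raise RegimeError(
                "spiral regime not sustained: a phase singularity was present "
                f"in only {frac_with_ps:.0%} of checked frames in the final "
                "half; lengthen duration_s or adjust nb/eps"
            )
    else:
        if float(np.mean(counts > 1)) < 0.5:
            raise RegimeError(
                "breakup regime not reached: a single wavefront persists in "
                "the final half of the run; increase nb past the spiral-"
                "stability boundary (packaged preset nb="
                f"{BREAKUP_NB}) or lengthen duration_s"
            )


def calibration_threshold(params: KarmaParams | None = None) -> float:
    """Binarization threshold: half of the peak upstroke amplitude of a
    single-cell calibration pulse at the given parameters."""
    if params is None:
        params = KarmaParams(grid_n=64, n_frames=2)
    u, gate = 1.5, 0.0
    peak = u
    dt = min(params.dt, 0.05)
    for _ in range(int(40.0 / params.eps / dt)):
        du = float(_reaction(np.float64(u), np.float64(gate), params.m, params.nb))
        excited = u > 1.0
        gate += dt * params.eps * (1.0 if excited else GATE_RECOVERY_RATIO) * (excited - gate)
        u += dt * du
        peak = max(peak, u)
    return 0.5 * peak


def binarize_karma(movie: VoltageMovie, threshold: float | None = None) -> BinaryMovie:
    """Binarize a Karma voltage movie at the calibration threshold."""
    if threshold is None:
        p = movie.meta.get("params", {})
        params = KarmaParams(
            grid_n=max(64, int(p.get("grid_n", 64))),
            nb=float(p.get("nb", 1.0)),
            m=float(p.get("m", 7.0)),
            eps=float(p.get("eps", 0.4)),
            n_frames=2,
        )
        threshold = calibration_threshold(params)
    return binarize(movie, threshold)


def count_wavefronts(binary_frames: np.ndarray) -> np.ndarray:
    """Number of connected excited components in each frame (4-connectivity)."""
    from scipy import ndimage

    frames = np.asarray(binary_frames)
    if frames.ndim == 2:
        frames = frames[None]
    counts = np.empty(frames.shape[0], dtype=int)
    for t, frame in enumerate(frames):
        _, counts[t] = ndimage.label(frame)
    return counts


def _instantaneous_phase(frames: np.ndarray) -> np.ndarray:
    """Per-pixel activation phase via the temporal analytic signal."""
    from scipy.signal import hilbert

    x = np.asarray(frames, dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    return np.angle(hilbert(x, axis=0))


def phase_singularities(frames: np.ndarray, min_count: int = 1) -> list[np.ndarray]:
    """Locate phase singularities in each frame of a voltage stack.

    The activation phase is computed per pixel from the temporal analytic
    signal; a singularity is a 2x2 plaquette around which the wrapped phase
    winds by +-2pi.  Returns, per frame, an (k, 2) array of (row, col)
    plaquette corners.
    """
    phi = _instantaneous_phase(frames)

    def wrap(a: np.ndarray) -> np.ndarray:
        return (a + np.pi) % (2 * np.pi) - np.pi

    d1 = wrap(phi[:, :-1, 1:] - phi[:, :-1, :-1])
    d2 = wrap(phi[:, 1:, 1:] - phi[:, :-1, 1:])
    d3 = wrap(phi[:, 1:, :-1] - phi[:, 1:, 1:])
    d4 = wrap(phi[:, :-1, :-1] - phi[:, 1:, :-1])
    winding = (d1 + d2 + d3 + d4) / (2 * np.pi)
    out = []
    for t in range(winding.shape[0]):
        rows, cols = np.nonzero(np.abs(winding[t]) > 0.5)
        out.append(np.column_stack([rows, cols]))
    return out


def singularity_centroid(movie: VoltageMovie, n_check: int = 60) -> tuple[float, float]:
    """Time-averaged (x_mm, y_mm) centroid of phase singularities over the
    final half of a movie; falls back to the domain centre when none exist."""
    frames = movie.frames[movie.n_frames // 2 :]
    sel = frames[:: max(1, len(frames) // n_check)]
    ps = phase_singularities(sel)
    pts = [p for p in ps if len(p)]
    h, w = movie.shape
    if not pts:
        return (w / 2 * movie.mm_per_cell, h / 2 * movie.mm_per_cell)
    allpts = np.concatenate(pts, axis=0).astype(float)
    row, col = allpts.mean(axis=0)
    return (float(col) * movie.mm_per_cell, float(row) * movie.mm_per_cell)
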