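# Methods

This note documents the models, estimators and numerical choices behind
`rotornet`, and what the packaged tests do and do not establish.

## Overview of the pipeline

The package quantifies how *organized* regional cardiac activation is, as
seen by a high-resolution mapping catheter, using an information-theoretic
network statistic:

1. obtain a binary activation movie (simulated 2D excitable sheet,
   analytic fixture, or imported frames);
2. sample 48 electrode time series at one or more catheter positions;
3. estimate pairwise mutual information (MI) between electrodes;
4. threshold the MI matrix into graphs keeping the top q% most-informative
   electrode pairs, for q on a grid from 2 to 100 %;
5. compute mean local efficiency of each graph, fit a cubic in q, and
   summarize each position by the fitted curve's average derivative over
   the 40–80 % window;
6. compare groups of positions (rotational vs irregular activation) with
   Welch's t-test and t-based 95 % confidence intervals.

A *small* window derivative means adding weakly informative connections
barely improves the network's fault tolerance — the signature of a rotor's
strongly ordered communication structure. Irregular, collision-dominated
activation gains efficiency steadily as edges are added, giving a larger
derivative.

## The excitable-tissue model

### Equations

The two-variable Karma model reduces cardiac membrane dynamics to a fast
voltage `u` and a slow repolarization gate `n`:

    du/dt = D ∇²u − u + ½ (u* − (n/n_B)^m) (1 − tanh(u − 3)) u²
    dn/dt = eps · r(u) · (H(u − 1) − n)

with `H` the Heaviside step, `u* = 1.5415`, and `r(u)` an open/close rate
asymmetry (1 while excited, 1/3 while recovering). The three exposed
dimensionless parameters are `nb` (action-potential duration and
restitution steepness), `m` (sharpness of gate suppression of the excited
state, i.e. wavefront sensitivity) and `eps` (voltage-to-gate time-scale
ratio). Defaults: `nb = 1.0`, `m = 7.0`, `eps = 0.4`.

Two internal constants complete the parameterization and were fixed once,
by qualitative regime behaviour only:

- **Gate margin (1.25).** `u* = 1.5415` places the fold of the excited
  branch exactly at `(n/n_B)^m = 1`, so a parameterization with
  `n_B = nb = 1.0` sits precisely on the boundary where cells latch and
  never repolarize. The exposed `nb` is therefore mapped to
  `n_B = nb/1.25`, which puts `nb = 1.0` safely inside the stable-spiral
  regime while AP duration grows — and the spiral destabilizes — as `nb`
  rises toward 1.25.
- **Recovery ratio (1/3).** Gate reopening during diastole is three times
  slower than closure during the plateau, the standard open/close
  asymmetry of minimal cardiac models. It flattens APD restitution at the
  spiral's operating diastolic interval; with a symmetric gate no stable
  spiral exists anywhere near `nb = 1.0` in this formulation (the
  initiated spiral either fragments immediately or activity dies out).

### Regimes

`simulate_karma(params, regime)` packages two presets:

- **spiral** — cross-field S1/S2 initiation (plane wave from the left
  edge; a half-plane stimulus at 55 % of the domain-crossing time) at the
  default parameters produces a single rotor whose phase singularity
  persists for the rest of the run. At these settings the rotor rotates
  rigidly (core excursion ≲ 1 cell over 10 s); parameterizations that
  meander were found in calibration but do not keep a single persistent
  singularity, so the rigid preset is packaged.
- **breakup** — the same initiation with `nb = 1.1` (the smallest tested
  increment sustaining multi-wavelet activity at the default scale;
  `nb ≥ 1.15` quenches — wavelets die out). The spiral fragments into
  self-sustained irregular wavelets (~25–35 simultaneous wavefronts on a
  256² sheet). The post-breakup state is *not* spatially homogeneous: the
  wavelets circulate along persistent channels, and patches of tissue can
  stay quiescent for the whole recording. This matters for sampling (see
  Limitations).

A seeded perturbation of amplitude 1e-3 in the initial gate field breaks
the grid symmetry; identical parameters and seed reproduce movies
bit-for-bit.

### Numerics and calibration

- Forward Euler, 5-point Laplacian, no-flux boundaries, `dx = 1` cell.
  Stability requires `dt ≤ dx²/(4·diffusion)`; the constructor rejects
  violating configurations, and non-finite fields during integration raise
  an error naming the bound. Defaults `diffusion = 4`, `dt = 0.05`
  (bound 0.0625): the diffusion level keeps the upstroke front ~1.5 cells
  wide so the explicit scheme resolves it, with a wavelength of ~15–20
  cells.
- **Time base.** One simulated "second" is defined as the time a plane
  wave needs to cross the domain (conduction-anchored convention); the
  plane-wave speed constant (1.33·√D cells per model time unit) was
  measured once from a 1D strip run. `duration_s = 10` with
  `n_frames = 1500` then spans ~100–200 rotor cycles at ~9 frames per
  cycle.
- **Burn-in.** `settle_s` (default 2 s) of unrecorded integration follows
  initiation, so exported frames contain only established spiral or
  post-breakup activity, no stimulus artefacts.
- **Binarization.** Movies are thresholded at half the peak upstroke
  amplitude of a single-cell calibration pulse (~1.89 in model voltage
  units at the defaults), computed on demand for the run's parameters.
- **Phase singularities** are located per frame as 2×2 plaquettes around
  which the per-pixel analytic-signal phase winds by ±2π; the spiral
  regime check requires one in ≥90 % of checked final-half frames, and the
  time-averaged singularity centroid serves as the default catheter
  reference point in the spiral regime.

## Catheter geometries and sampling

Both investigational 48-electrode layouts are built in mm about the
catheter centre:

- **flower**: 8 radial 2 cm splines at 45°, 6 electrodes per spline at
  radii 10–20 mm in 2 mm steps (the innermost radius is not constrained by
  the hardware description; 10 mm places the outermost electrode exactly
  at the spline tip).
- **grid**: 6 parallel splines at 2.14 mm pitch, 8 electrodes per spline
  at ±1, ±3, ±5, ±7 mm along the spline.

Sampling converts each electrode's mm position to fractional cell
coordinates (cell (0,0) centred at the top-left), averages the surrounding
2×2 cell block per frame, and rounds half-up (block mean ≥ 0.5 → 1). The
500 µm physical electrode length is represented only through this
four-cell footprint. Placements are validated so that every electrode's
block lies inside the domain; `around_point` draws centres uniformly from
a seeded disc (default radius 10 mm) about the reference point.

## Mutual information and graphs

MI between two binary sequences is the plug-in estimate from the 2×2 joint
histogram, in nats, identical to the sample-average log-ratio form. For
binary signals the two fixed-width bins make the estimator exact given the
empirical distribution, so no binning parameter is exposed. No small-sample
bias correction is applied (at the packaged 1500-frame movies the plug-in
bias for a 2×2 table, ~(levels−1)²/2T ≈ 3e-4 nats, is far below the
structure being ranked — and graphs depend only on MI *ranks*, which bias
shifts almost uniformly). Matrix diagonals carry each signal's entropy.

An edge-fraction threshold q keeps the top ⌈q/100 · 1128⌉ of the 1128
electrode pairs, ranked by MI descending with ties broken by ascending
(i, j) lexicographic order — making edge sets nested across q, graphs
invariant to any positive rescaling of MI, and every run reproducible.
When many pairs tie at exactly zero MI (positions containing
never-activated electrodes), the tie rule concentrates those edges on
low-index nodes; such positions are flagged `degenerate` in study output.

## Local efficiency and the window derivative

Local efficiency at node i is the Latora–Marchiori form: mean inverse
shortest-path length over ordered pairs of i's neighbours, paths
restricted to the neighbour-induced subgraph with i removed, 1/∞ = 0.
Nodes with fewer than two neighbours contribute 0 and stay in the
48-node mean, keeping the normalization fixed across thresholds (the mean
is therefore exactly 1 for the complete graph and 0 for the empty one).
Shortest paths use breadth-first search (scipy.sparse.csgraph); an
exhaustive pure-Python BFS oracle and networkx cross-check pin the
implementation in the tests.

The efficiency curve is swept on q = 2, 4, …, 100 (50 points; the grid the
hardware plots suggest is dense but is not stated anywhere, so this is a
package default). A third-degree polynomial is least-squares fitted to the
*full* curve (numpy Polynomial with internal domain mapping, so the fit is
well-conditioned), and the summary statistic is the mean of its analytic
derivative over the window [40, 80] %, i.e. (P(80) − P(40))/40.

**Fit-range sensitivity (important limitation).** Below roughly q = 10 %
the graphs are sparse — most nodes isolated, efficiency dominated by
tie-ranked cliques — and mean local efficiency jumps violently with q.
These few points carry large leverage on a global cubic: with them the
rotational derivative is ~0.0004 and the irregular ~0.0015–0.0036; fitting
from q ≥ 10 % instead gives ~0.0024 and ~0.0034 with much smaller
position-to-position spread. Reported window derivatives should therefore
only be compared between analyses using an identical grid and fit range.
The package default (full-grid fit) is kept deliberately; `q_grid` is a
config field for users who want the restricted variant.

## Group comparison

`compare_groups` applies Welch's unequal-variance two-sample t-test
(two-sided) and per-group t-based 95 % CIs (mean ± t₀.₉₇₅,ₙ₋₁·s/√n). Two
zero-variance groups with equal means report t = 0, p = 1 by convention.
The pooled-variance test was considered and rejected as the default: at
n = 6 per group with visibly unequal spreads Welch is the safer choice.

## Synthetic fixtures

`synthetic_movies` renders the two activation archetypes analytically so
every downstream stage has closed-form expectations:

- **spiral**: a rigidly rotating Archimedean phase field; pixel on iff
  frac((θ − ωt + kr)/2π) < duty. Defaults: 64² cells, ω = 2π/25 per frame,
  wavelength 60 cells (18 mm at 0.3 mm/cell — large against the 2 mm
  electrode pitch, as for a physiological rotor under a mapping catheter),
  duty 0.35. Every pixel is exactly periodic; equal-radius pixels are
  circular time shifts of each other.
- **irregular**: white Gaussian noise with AR(1) temporal smoothing
  (ρ = 1 − 1/correlation_time, so correlation_time = 1 means independent
  frames), isotropic Gaussian spatial smoothing (σ = correlation_length),
  thresholded at the movie-wide quantile giving the requested on-fraction.
  Defaults: correlation length 3 cells, correlation time 3 frames,
  on-fraction 0.35 (matched to the spiral's duty cycle).

These fixtures carry the *dependence structure* the statistic exploits
(phase-graded MI for the spiral; distance-decaying, near-baseline MI for
the noise), but no physiology: no restitution, no conduction, no
refractoriness, no wavefront curvature. Tests passing on them demonstrate
that the pipeline separates phase-organized from incoherent activation —
not that it would separate any particular real recording.

## The packaged default experiment

`headline_study_configs(seed)` builds the rotational-vs-irregular
comparison: 2D Karma movies at 256² cells (10 s, 1500 frames, 2 s settle),
grid catheter, six placements drawn from a 10 mm disc about the rotor's
phase-singularity centroid (spiral) or the domain centre (breakup), MI
graphs on the 2–100 % grid, full-grid cubic fit, 40–80 % window. The 256²
sheet preserves the wavelength-to-catheter relationship of a 512² run at a
quarter of the cost (~1.5 min for the whole experiment on one CPU); all
randomness derives from the single seed. `scripts/acceptance.py` runs
exactly this and writes the two group means.

Typical behaviour across seeds: the rotational group mean is ~2–7e-4, the
irregular ~1.2–3.6e-3, the ordering rotational < irregular holds at every
seed tested, and the Welch p ranges from <1e-4 to ~0.06 depending on how
the six random positions land on the spatially heterogeneous post-breakup
state.

## Known limitations

- The packaged rotor rotates rigidly; meandering or drifting rotors
  (common in this model class) would weaken the long-range phase locking
  and raise the rotational derivative.
- The post-breakup state is spatially patchy; positions straddling
  quiescent channels produce zero-entropy electrodes and inflate
  irregular-group variance. With six random positions the group
  comparison's significance is seed-dependent.
- The window-derivative statistic depends strongly on the threshold grid
  and fit range (see above); absolute values are not comparable across
  analysis variants.
- AP voltages are analysed directly; no unipolar/bipolar electrogram
  synthesis, no 3D anatomy, fibres or anisotropy, and no Ca²⁺-handling
  remodeling model — remodeled-tissue comparisons are supported only via
  imported binary movies.
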