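# rotornet

Regional mutual-information networks for discriminating rotational from
irregular cardiac activation.

## The problem

Atrial fibrillation can be sustained by *drivers* — rotors, i.e. spiral
waves of electrical activation circling an unexcited core — embedded in
tissue that otherwise shows irregular, collision-dominated wavelets.
Identifying driver regions from the small patch (~2–7 cm²) covered by a
high-resolution multi-spline mapping catheter is hard: cycle-length
variability and tissue heterogeneity obscure re-entry in raw electrograms.

`rotornet` implements a network statistic that separates the two
activation patterns from nothing but binarized activation movies. For a
48-electrode catheter (flower-shaped radial splines or grid-type parallel
splines) it:

1. extracts one binary time series per electrode (2×2-cell neighbourhood
   average, rounded);
2. estimates pairwise mutual information with the plug-in histogram
   estimator, I(X;Y) = Σ_{a,b} p̂(a,b) ln [ p̂(a,b) / (p̂(a) p̂(b)) ];
3. builds graphs keeping the top q % most-informative electrode pairs,
   for q from 2 to 100 %;
4. computes mean local efficiency
   E_loc(i) = (1/(|G_i|(|G_i|−1))) Σ_{j≠k∈G_i} 1/L_{j,k}
   (shortest paths inside the neighbour subgraph of i, node i removed),
   fits a cubic to the curve E(q), and summarizes each catheter position
   by the fitted curve's mean derivative on the 40–80 % window;
5. compares position groups with Welch's t-test and 95 % CIs.

Rotational activation yields a *flatter* efficiency curve in the window —
adding weakly informative connections barely improves fault tolerance in
a rotor's strongly ordered communication network — so its window
derivative is significantly smaller than that of irregular activation.

Activation movies come from a built-in 2D Karma-model reaction–diffusion
simulation (stable-spiral and spiral-breakup regimes), from analytic
fixture generators (rigid spiral / correlated noise), or from imported
TIFF/PNG stacks (e.g. externally binarized 3D-model or clinical LAT
videos). See `docs/methods.md` for the model equations, calibration and
limitations.

## Worked example

Six catheter positions on each of two analytic fixture movies — a rotating
spiral and matched correlated noise:

```python
from rotornet import StudyConfig, run_study

rotational = StudyConfig(
    movie={"kind": "synthetic", "generator": "spiral", "grid_n": 64, "n_frames": 600},
    group="rotational", n_positions=6, radius_mm=1.5, placement_seed=7,
)
irregular = StudyConfig(
    movie={"kind": "synthetic", "generator": "irregular", "grid_n": 64,
           "n_frames": 600, "seed": 7},
    group="irregular", n_positions=6, radius_mm=1.5, placement_seed=7,
)
res_rot, res_irr, comp = run_study(rotational, irregular, "study_out")
print(f"rotational window derivative: {comp.mean_a:.6f} "
      f"(95% CI {comp.ci_a[0]:.6f}..{comp.ci_a[1]:.6f})")
print(f"irregular  window derivative: {comp.mean_b:.6f} "
      f"(95% CI {comp.ci_b[0]:.6f}..{comp.ci_b[1]:.6f})")
print(f"Welch t = {comp.t_statistic:.2f}, p = {comp.p_value:.2g}")
```

prints

```
rotational window derivative: 0.000243 (95% CI -0.000065..0.000551)
irregular  window derivative: 0.004855 (95% CI 0.004522..0.005188)
Welch t = -26.14, p = 1.7e-10
```

The rotational group's efficiency curve has already plateaued across the
40–80 % threshold window (derivative ≈ 2e-4 per threshold-percent), while
the irregular group keeps gaining local efficiency (≈ 5e-3); at six
positions per group the difference is highly significant. `study_out/`
receives per-position curve CSVs, the group-comparison CSV, the Welch-test
JSON, and two figures (efficiency curves with cubic fits; group means with
95 % CI error bars).

The same pipeline runs from the shell:

```sh
rotornet simulate --regime spiral --grid 256 --duration 10 --frames 1500 \
    --seed 1 --binary --out spiral.tif
rotornet sample --movie spiral.tif --geometry grid --positions 6 \
    --radius-mm 10 --seed 2 --out signals/
rotornet minet --signals signals/signals_pos0.csv --out net0/
```

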