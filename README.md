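# sptkit

Analysis toolkit for 2D single-particle tracking (SPT) of membrane
proteins labelled with quantum dots or comparable emitters. Given
trajectory tables (track id, frame, x, y in μm) from any tracker, it
computes per-track diffusion and shape metrics, classifies each track's
motion type against a simulation-calibrated null, segments tracks into
discrete diffusive states with a hidden Markov model, and produces the
median/IQR group tables and distribution tests used to compare
experimental conditions. A fully seeded synthetic-trajectory generator
with known ground truth backs the calibration and every test.

## What it computes

For a reindexed track of N positions sampled every δt seconds, the
time-averaged mean-squared displacement at lag n is

    ⟨r²(nδt)⟩ = 1/(N−n) · Σ_{j=0}^{N−n−1} [x((j+n)δt)−x(jδt)]² + [y((j+n)δt)−y(jδt)]²

From it:

* **D₂₋₄** — short-lag diffusion coefficient from the OLS fit
  ⟨r²(t)⟩ = 4·D₂₋₄·t + offset over lags 1–4 (the initial MSD slope is 4D
  for every motion mode; the offset absorbs the ≈4σ² localization-noise
  floor).
* **α, D_α** — anomalous exponent from ⟨r²(t)⟩ = 4·D_α·t^α
  (α < 1: subdiffusion/confinement; α ≈ 1: Brownian).
* **D_MLE** — maximum-likelihood diffusion coefficient from the exact
  Gaussian displacement likelihood accounting for static localization
  error σ (default 25 nm) and camera motion blur R (default 1/6):
  per-dimension displacement variance 2DΔt + 2σ² − 4RDΔt with lag-one
  covariance −(σ² − 2RDΔt). Tracks with D_MLE < 5×10⁻⁴ μm²/s (the 95th
  percentile of substrate-fixed emitters) are called **immobile**.
* **RD(N, 25)** — relative deviation MSD(25δt)/(4·D₂₋₄·25δt), ≈ 1 for
  free diffusion, < 1 under confinement. Monte-Carlo calibration of
  Brownian tracks (D = 0.1 μm²/s, lengths 100–600) gives the 2.5th/97.5th
  percentile null band per track length; tracks below the line fitted to
  the 2.5th-percentile points are **restricted**, all others **free**.
* **Geometry** — aspect ratio of the minimum-area rotated bounding box,
  and explored area = convex-hull area / number of time points.
* **Diffusive states** — per-frame displacements Δr_t modelled as an
  isotropic Gaussian HMM with per-state σ² = 2·D_k·Δt (optional drift
  μ = v·Δt); EM fitting with seeded restarts, Viterbi decoding, and BIC
  selection over the state count K and emission form.

## Worked example

```python
import sptkit as sk

calib = sk.calibrate_cutoffs(seed=0)           # RD null band, lengths 100-600

free = sk.simulate_brownian(sk.SimConfig(n_tracks=100, n_steps=300, dt=0.1,
                                         D=0.05, seed=1))
trapped = sk.simulate_confined(sk.SimConfig(n_tracks=50, n_steps=300, dt=0.1,
                                            D=0.01, mode="confined_square",
                                            L=0.2, seed=2))
fixed = sk.add_localization_noise(
    sk.simulate_brownian(sk.SimConfig(n_tracks=10, n_steps=100, dt=0.1,
                                      D=0.0, seed=3)), 0.025, seed=4)

tracks = sk.TrackSet(
    [sk.Trajectory(f"{g}{tr.track_id}", tr.frames, tr.x, tr.y, dt=tr.dt)
     for g, ts in (("free", free), ("trap", trapped), ("fix", fixed))
     for tr in ts])

result = sk.run_pipeline(tracks, sk.PipelineConfig(calibration=calib))
print(result.counts)
```

prints

```
{'too_short': 0, 'immobile': 10, 'unclassifiable': 0, 'restricted': 55, 'free': 95}
```

— the 10 substrate-fixed emitters are caught by the D_MLE cutoff, all 50
trapped tracks are called restricted, and 95/100 Brownian tracks are
called free (5 fall below the calibrated lower RD boundary, the expected
lower-tail rate). Summarizing the mobile tracks:

```python
mobile = result.metrics.query("category in ('restricted', 'free')")
s = sk.summarize_group(mobile["D_mle"], "mobile", "D_mle")
# mobile D_mle median 0.0632 um^2/s, IQR [0.0044, 0.0678], N=150
```

The low 25th percentile reflects the trapped subpopulation, whose
apparent diffusivity inside 0.2 μm domains is far below its microscopic
D. Fitting a two-state displacement HMM to a switching track:

```python
tr, truth = sk.simulate_switching(
    sk.SimConfig(n_tracks=1, n_steps=1500, dt=0.1, seed=5),
    [0.01, 0.2], [[0.98, 0.02], [0.02, 0.98]])
print(sk.fit_hmm(tr[0], K=2, n_restarts=5, seed=6).summary())
```

```
Displacement HMM Results
====================================================
states (K)                     2
emission model                 D
n displacements             1499
log-likelihood             2812.5227
BIC                       -5588.4827
converged                   True
----------------------------------------------------
state    D (um^2/s)          v (um/s)   occupancy
1           0.01016            (0, 0)       0.539
2           0.20418            (0, 0)       0.461
```

recovering both diffusivities (0.01 / 0.2 μm²/s) within 2 %.

A `sptkit` console command exposes the same steps from the shell
(`simulate`, `calibrate`, `analyze`, `classify`, `hmm`, `report`); run
`sptkit --help`.

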