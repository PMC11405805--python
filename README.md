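# smtirf

Analysis of single-molecule TIRF experiments on supported lipid bilayers
(SLBs): membrane **dwell-time survival analysis**, **step-size diffusion
fitting**, and **association-rate (k_ON) estimation** for peripheral
membrane-binding proteins such as the PIP5K/PIP4K lipid kinases — together
with a ground-truthed simulator so every fitted parameter can be validated
by parameter recovery.

In these experiments a fluorescently labeled protein in solution binds a
planar membrane, is visible only while membrane-bound (TIRF illumination),
diffuses laterally, and unbinds. From detected and tracked single
molecules the package computes:

- **Dwell times.** The survival function S(t) = 1 − CDF(t) of dwell times,
  binned at the frame interval and displayed as log₁₀ S(t), is fit with

  S(t) = e^(−t/τ)  or  S(t) = α·e^(−t/τ₁) + (1−α)·e^(−t/τ₂),

  where α is the fraction of the fast-dissociating population (τ₁ ≤ τ₂).
  Model order is chosen by an extra sum-of-squares F-test with a
  degeneracy guard.
- **Lateral diffusion.** Pooled frame-to-frame step lengths r over lag τ
  are binned at 0.01 μm and the probability density is fit with the 2D
  Brownian (Rayleigh-type) models

  f(r) = r/(2Dτ)·e^(−r²/4Dτ)  (one species)

  and the two-species mixture with fraction α of species 1 (D₁ ≤ D₂).
  For one species the mean step is √(πDτ).
- **Association kinetics.** The binding frequency at each solution
  concentration is the regression slope of cumulative binding events vs
  time per membrane area (events·μm⁻²·s⁻¹); k_ON is the zero-intercept
  regression slope of frequency against concentration, in events per
  (μM·μm²·s) (per-nM values are exactly 10³ smaller).
- **Bulk kinetics.** Recruitment fold change, reaction half-time of
  intensity traces, and lipid surface densities from molar composition
  (0.72 nm² DOPC footprint → 4 mol% ≈ 5.6 × 10⁴ lipids/μm²).

The package also contains the upstream steps — Laplacian-of-Gaussian spot
detection with sub-pixel refinement, Hungarian frame-to-frame linking, and
the standard trajectory hygiene filters (movie-boundary tracks, tracks ≤ 2
detections, immobilized particles with < 0.1 μm displacement, edge tracks)
— and a simulator producing trajectories, TrackMate-dialect CSVs, and
rendered 16-bit TIFF movies with per-molecule ground truth.

## Worked example

```python
from smtirf import (BindingModel, build_survival, select_model,
                    simulate_dwell_times)

model = BindingModel(alpha_fast=0.95, tau_fast=0.815, tau_slow=3.09)
_, dwells = simulate_dwell_times(14_950, model, frame_interval=0.052, seed=1)
order, fit = select_model(build_survival(dwells, 0.052))
print(order, fit.tau1, fit.tau2, fit.alpha)
```

Running `python examples/dwell_time_analysis.py` (the same computation with
reporting) prints:

```
n = 14950 molecules, 495 survival bins
selected model order: 2
tau1  = 0.821 +/- 0.001 s  (fast population)
tau2  = 3.095 +/- 0.042 s  (slow population)
alpha = 0.957 +/- 0.001   (fast fraction)
model mean dwell = 0.919 s
transient events (< 104 ms): 5.7%
```

The fitted time constants and fast fraction recover the generating values
(0.815 s, 3.09 s, 0.95) within sampling error; the mean dwell is
α·τ₁ + (1−α)·τ₂; the transient fraction is the share of molecules gone
within two frames. The other scripts in `examples/` walk through the full
movie → tracks pipeline, diffusion fitting, k_ON estimation, and bulk
kinetics, each printing the numbers it computes and what they mean.

A thin CLI mirrors the stages:

```bash
smtirf simulate --kon 184 --tau-fast 0.9 --seed 1 --out-prefix sim
smtirf dwell sim_tracks.csv --frame-interval 0.052 --order auto
smtirf diffusion sim_tracks.csv --order 1
```

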