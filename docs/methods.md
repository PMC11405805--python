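# Methods

## The measurement being modeled

A protein at picomolar concentration binds a supported lipid bilayer
imaged by TIRF microscopy. Only membrane-bound molecules fluoresce, so a
binding event is an appearance, the dwell is the run of frames the
molecule stays detected, and the disappearance is unbinding (or
photobleaching — see censoring below). Three observables summarize the
kinetics: how often molecules arrive (association), how long they stay
(dissociation), and how they move while bound (diffusion).

## Generative model (the simulator)

Arrivals are a homogeneous Poisson process with intensity
`kon · C · A` (events/s) for concentration C (μM) and membrane area A
(μm²); over duration T the count is Poisson with mean `kon·C·A·T`.
Dwell times are drawn from the exponential mixture
`α·Exp(τ₁) + (1−α)·Exp(τ₂)` (α the fast fraction, τ₁ ≤ τ₂); an optional
first-order photobleaching clock with rate b censors each dwell to
`min(dwell, Exp(1/b))`, so a single-exponential dweller with bleaching is
observed as exponential with rate `1/τ + b`. Lateral motion is 2D
Brownian: each frame-to-frame increment per axis is Gaussian with variance
`2DΔt`, giving Rayleigh-distributed step lengths with mean `√(πDΔt)`. The
population can mix two mobile species plus an immobile fraction.

Detection discretization: a molecule is recorded in frame k if it is alive
at that frame's temporal midpoint, which makes observed dwell counts
`ceil(dwell/Δt)` frames; observed positions carry independent Gaussian
localization error σ. Boundaries are reflecting — the field is a small
window on an effectively unbounded bilayer, and reflection preserves
density at the edges; the edge filter removes residual artifacts. Movies
are rendered as symmetric 2D Gaussian spots (total photons per spot on a
constant background) with Poisson shot noise, 16-bit.

All randomness flows from a single `numpy.random.Generator` (PCG64)
seeded from the configuration; sub-processes draw in a fixed documented
order (arrivals → dwells/bleach → per-molecule species, start position,
increments, localization noise), so a fixed seed reproduces every output
bit-for-bit across platforms.

What the simulator does *not* emulate: camera EM-gain noise statistics,
photophysics beyond a visible-fraction/bleach-rate parameter (no
blinking, no green→red photoconversion kinetics), 3D/astigmatic PSFs,
drift, or the product-feedback reaction mechanism that couples binding to
catalysis. Passing recovery tests therefore demonstrates the estimators
are correct for the assumed statistical structure, not that real movies
satisfy that structure.

## Detection, linking, filtering

Spots are local maxima of the scale-normalized negative
Laplacian-of-Gaussian response at `σ = radius/√2`, thresholded on the
response amplitude ("quality") and refined to sub-pixel positions by an
intensity-weighted centroid in a 5×5 window after local background
subtraction (adequate for symmetric synthetic PSFs; no Gaussian MLE
fitting). Quality thresholds are movie-dependent user inputs — there is
no universal default.

Linking solves, per consecutive frame pair, the assignment minimizing
total squared displacement with a distance gate (Hungarian algorithm;
default gate 0.5 μm/frame, which covers >99.9% of steps at the
diffusivities simulated here). No gap closing, splitting, or merging;
ties are broken deterministically by spot order.

Trajectory filters, applied before any kinetic analysis, remove tracks
that (i) start in the first movie frame or (ii) reach the last one (their
dwell is censored by the movie), (iii) have fewer than 3 detections,
(iv) never move ≥ 0.1 μm from their start ("immobilized" — displacement
is interpreted as maximum excursion from the first position, in μm),
(v) come within 1.0 μm of the field border, or (vi, optional, off by
default) exceed a duration cap for singular extra-long tracks. The
filter reports per-rule removal counts and is idempotent. The boundary
filters are also the package's censoring treatment: no censored
likelihood is used downstream, so dwell estimates remain biased low by
any photobleaching that occurs within the movie — a deliberate,
documented limitation of the protocol being reproduced.

## Dwell-time survival fitting

Dwell = (detections − 1) × Δt. The empirical survival S(t) = 1 − CDF(t)
is evaluated at every multiple of Δt; for frame-quantized dwells this
grid makes S at bin edges an unbiased estimate of the continuous-time
survival, so no discretization correction is needed. The default fit
objective is unweighted least squares of S(t) against the exponential
(-mixture) model **on the linear scale**, although the diagnostic curve
is displayed as log₁₀ S. Rationale: an unweighted log-scale fit is
dominated by the last few surviving molecules, whose log-survival
variance diverges. A log₁₀ objective is offered as an alternative and is
inverse-variance weighted (delta method: sd ≈ √((1−S)/(nS))/ln 10).
Neither objective claims to replicate any particular graphing package's
fit bit-for-bit. Optimization uses bounded trust-region least squares
from a moment-based start (τ₁ ← median/ln 2, τ₂ ← 5τ₁, α ← 0.8) plus
three jittered restarts, keeping the best weighted RSS; parameters are
reported with Jacobian-based standard errors and re-ordered so τ₁ ≤ τ₂
with α the fast fraction. Non-convergence from every start raises an
explicit error, never a silent NaN.

Model order (1 vs 2) is chosen by the extra sum-of-squares F-test at
p < 0.01 plus a degeneracy guard: τ₂/τ₁ ≥ 2 and α ∈ [0.05, 0.99].
Survival points are serially correlated, which makes the nominal F-test
strongly anti-conservative; with a 1% fraction floor, genuinely
single-exponential samples at n = 10⁴ acquired a spurious 2–4% fast
component in ~14% of replicates. The 5% floor restores measured
selection accuracy to ≥ 95% for both pure single exponentials and
well-separated mixtures at n = 10⁴ while still accepting mixtures with a
5% slow minority (α = 0.95). Never more than two components are
considered.

Transient events are dwells strictly below a threshold, default 104 ms =
two frames at the 52 ms acquisition interval. Per-cell analysis fits one
survival curve per cell, summarizes groups by mean ± SD of cell-level
τ₁, and compares two groups with the standard pooled-variance unpaired
two-tailed t-test; unfittable cells are excluded and logged.

## Step-size diffusion fitting

Displacements are pooled across filtered tracks at lag 1 only (one lag
time; MSD-vs-lag analysis is out of scope), binned at 0.01 μm with
zero-count bins retained, normalized to probability density, and fit with
the one- or two-species Rayleigh model by bounded least squares from a
moment start (`D₀ = mean²/πτ`) with restarts. An order-2 fit is flagged
degenerate when a component carries < 5% weight (or its weight is within
2 SE of 0 or 1) or when D₂/D₁ < 1.5. No immobile term appears in the
model — immobile particles are expected to be pre-removed by the
displacement filter. With localization error σ the apparent coefficient
is inflated to ≈ D + σ²/τ; the package does not correct for this, but
the property suite verifies the relation on simulated data.

## Association kinetics

Binding frequency = OLS slope of cumulative event count vs event time,
divided by area (events·μm⁻²·s⁻¹). k_ON is the zero-intercept regression
slope of frequency on concentration — frequency must vanish at zero
concentration, so the intercept is fixed at the origin; a free-intercept
OLS is attached as a diagnostic. Canonical unit: events per (μM·μm²·s);
per-nM output is exactly 10³ smaller. When counting events from real
trajectory tables, an event is the first frame of a track that survives
the movie-boundary filters; the immobile filter is optional there
(immobile nonspecific particles may or may not be counted, user's
choice). Fewer than 10 events triggers a warning; a single concentration
degrades to the flagged ratio f/C.

## Bulk kinetics

Plateau = mean of the final 10% of samples unless an explicit window is
given (with a warning in the implicit case). Fold change = plateau /
reference level. Half-time = first crossing of the midpoint between the
initial level (mean of first 10%, symmetric with the plateau estimate so
a pure ramp reports its exact midpoint) and the final plateau, after a
centered moving-average smooth (default width 5), linearly interpolated
and measured from the first sample; multiple crossings are reported as
the first with a warning. The synthetic bulk trace is a phenomenological
Hill sigmoid `plateau · t^h / (t^h + t_half^h)` (default h = 4)
crossing half-maximum exactly at t_half — a
stand-in for reaction traces, not a mechanistic product-feedback model,
which is out of scope. Lipid density = molar fraction / footprint with
the nm²→μm² conversion; default footprint 0.72 nm² (DOPC), one leaflet.

## Problem sizes and defaults

Recovery suites run at the published scales: 14,950 / 13,117 / 3,993
dwell times per sample for the two- and one-exponential fits, 10,000–
30,000 pooled displacements for diffusion fits, and concentration series
of 5–80 pM Poisson event streams of ~10²–10⁴ events each. The
observation area used for frequency normalization defaults to 6400 μm²
(an ~80 × 80 μm field, i.e. a 512×512 EMCCD at 0.16 μm/pixel through a
100× objective) — the field size is a configuration parameter, not a
physical constant. Frame interval defaults to 52 ms (19 fps), the faster
of the two standard acquisition settings (52/102 ms). Statistical
property tests use 50–200 seeded replicates.

## Known limitations

- No censored-likelihood dwell estimation: photobleaching and
  movie-length truncation bias τ estimates low; only the boundary
  filters mitigate this.
- The F-test p-value for model order is nominal, not calibrated; the
  degeneracy guard, not the p-value, carries most of the selection
  specificity.
- Sub-pixel localization by windowed centroid is biased for overlapping
  or edge-clipped spots; dense fields need a proper PSF-fitting
  localizer.
- The simulator's uniform background and ideal Gaussian PSF make
  detection much easier than in real EMCCD data; detection thresholds
  tuned on simulations will not transfer to experiments.
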