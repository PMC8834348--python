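# Methods

## Microscopic model

The membrane is a periodic square box (default 3 µm) containing
non-overlapping circular trapping domains of common radius (default 40 nm,
below the <100 nm scale of raft nanodomains) placed by rejection sampling
to a target area fraction (the disk count is round(f·L²/(πr²)), which keeps
the achieved fraction within 1 % of the target). Probes take isotropic
Gaussian steps with per-axis standard deviation √(2·D·dt), with D = d_out
outside domains and d_in ≤ d_out inside. A step that would cross a domain
boundary is accepted with probability p_enter (entering) or p_escape
(leaving) and otherwise reflected radially off the circle; reflection
rather than rejection-resampling approximately preserves detailed balance
at small dt. Positions wrap periodically.

This disk-with-crossing-probabilities mechanism is the simplest one that
produces transient trapping and hence a positive diffusion-law intercept;
it is the standard construction in the svFCS methodological literature. Two
derived quantities characterize it:

* equilibrium partitioning K ≈ (p_enter/p_escape)·√(d_out/d_in), giving a
  domain occupancy φ = K·f / (K·f + 1 − f);
* the mean residence time per visit, controlled by p_escape, d_in and the
  radius.

Calibration findings from building the pipeline: a measurable positive t₀
requires residence times of ~15–30 ms (comparable to the spot transit
time) at moderate occupancy (φ ≈ 0.4–0.6). Fast exchange (residence ≪ τ_d)
only rescales the slope (lower D_eff, t₀ ≈ 0); very slow exchange
(residence ≳ 50 ms) or occupancy ≳ 0.8 drowns the intercept in noise
because few independent trapping events occur per run. The intercept's
signal-to-noise also scales with the number of domains under a spot, so
the strongly confined presets use dense domain packings (area fraction up
to ~0.2) rather than stickier sparse ones. The per-condition parameters in
`src/raftdyn/data/presets.yaml` were tuned once against this behavior and
are ordered so that confinement strength follows
Thy1_control > SM_control > SM_rescue > SM_ZA_Myr ≳ SM_KnD, with the
phosphatidylcholine (non-raft) presets having no trapping at all. Domain
density, size and probe mobility are not measured quantities for these
cells; the presets are calibrated stand-ins, not measurements.

Numerical guards: dt is chosen per condition so the rms step is at most a
quarter of the domain radius (no tunneling through domains) and at most a
tenth of the box; the box (≥ 3 µm) keeps the largest spot (ω = 0.35 µm)
far from its periodic images. Random variates are pre-drawn in float32
from a seeded PCG64 generator (halving RNG cost; step precision ~10⁻⁷
relative is irrelevant at these statistics), and the update loop is a
numba kernel with an O(1) spatial-hash domain lookup. A memory guard
rejects ensembles beyond ~2.4 GB; longer acquisitions are simulated as
consecutive segments carrying the particle state forward, with a burn-in
(0.5 s for trapped presets) so the domain occupancy relaxes to its
stationary value before recording.

## Virtual detection and correlation

A Gaussian confocal spot of 1/e² radius ω weights each particle by
exp(−2·d²/ω²) at its minimum-image distance d from the spot center.
Expected counts per sampling bin are background + brightness·Σweights
(brightness: counts per particle at center per bin; default 2.0 with 0
background), and detected counts are Poisson. Default sampling matches the
simulation step (25–50 µs), resolving τ_d ≈ 5–30 ms by two to three
decades.

The correlator is a multi-tau scheme with m = 16 channels per stage:
stage 0 evaluates lags 1..16 at native resolution, each further stage
halves the resolution and evaluates lags 9..16 in doubled units — the
classic hardware-correlator layout (the lag grid is an implementation
choice recorded in output metadata). All estimates use symmetric
normalization G(τ) = ⟨F₁F₂⟩/(⟨F₁⟩⟨F₂⟩) − 1 over the overlapping halves,
which suppresses slow-drift inflation. A brute-force O(N·k) estimator with
the same normalization serves as the test oracle; the two agree to well
below 1 % on shared lags. Constant traces raise a degenerate-input error.

## ACF model fit

The fitted model is the minimal single-component 2D lateral diffusion ACF,
G(τ) = baseline + amplitude·(1 + τ/τ_d)⁻¹ — no triplet term, no anomalous
exponent. Weighted least squares (lmfit/Levenberg–Marquardt) with weights
1/σ² from across-run standard errors when available; τ_d error from the
fit covariance; a stalled optimizer returns converged=False rather than
raising. Initialization is derivative-free: baseline from the median of
the last lag decade, amplitude from the early plateau, τ_d from the
half-amplitude crossing.

Two conventions matter for accuracy and were set after measurement:

* lags below 3 sampling bins are excluded (conventional guard against
  shot-noise/afterpulsing artifacts at the shortest lags);
* the fit window is set in two passes: a wide-window pilot fit (lags
  ≤ 0.3 s) followed by a final fit on lags ≤ 8·τ_d(pilot). The periodic
  simulation box mixes on the timescale L²/(4π²D), beyond which the
  simulated ACF decays *faster* than the heavy-tailed infinite-plane
  model; fitting deep into that regime biased τ_d down by 6–11 % in a
  2-µm box. The adaptive window keeps free-diffusion fits clear of the
  box tail (boxes are 3–6 µm depending on preset), while for trapped
  motion the slow trapping correlations inflate the pilot τ_d and widen
  the window, so the signal carrying the intercept is not cut off.
  Residual intercept bias for free diffusion is a few tenths of a ms,
  within the per-experiment uncertainty.

Per-cell τ_d is obtained by fitting the run-averaged ACF of that cell
(20 runs of 5 s), not by averaging per-run fits — lower variance at
identical ground truth. In particle mode each run observes the membrane
at a freshly drawn spot position: only a handful of nanodomains sit under
any one spot, so repositioning the beam between acquisitions averages
that quenched spatial disorder, exactly as moving to a new membrane spot
does on a real cell; with a fixed spot the per-cell τ_d of trapped probes
fluctuates by tens of percent from the local domain count alone. Waist calibration inverts the free-diffusion law
for a reference dye: ω = √(4·D_ref·τ_d,ref), with D_ref defaulting to
414 µm²/s (Rhodamine 6G at 25 °C, a literature value; configurable).

## Diffusion law

Mean ± SEM of per-cell τ_d (ms) at each waist is regressed on ω² by
weighted linear least squares (weights 1/SEM² when all SEMs are positive,
unweighted otherwise). t₀ is the intercept; D_eff = 1000/(4·slope)
converts the ms/µm² slope to µm²/s; D_eff's SEM is d_eff·slope_sem/slope.
Because the weights are true standard errors of the per-waist means, the
parameter covariance is reported at unit scale ((XᵀWX)⁻¹, "absolute
sigma") rather than rescaled by the reduced χ²: with four nearly collinear
points the rescaled errors collapse toward zero and misclassify free
diffusion as weakly hindered. Unweighted fits keep the usual
residual-scaled OLS errors. A non-positive slope raises an unphysical-law
error rather than reporting a negative D_eff.

The regime rule is t₀ > 2·SEM → "trapped", t₀ < −2·SEM → "meshwork", else
"free". The sources state only sign criteria; the 2σ rule is the minimal
principled threshold and the multiplier is exposed as a parameter. The
meshwork regime is classified but never generated (no cytoskeleton model —
a deliberate non-goal).

The law-level generator draws per-cell diffusion times from
Normal(t₀ + 1000·ω²/(4·D_eff), (cv·mean)²) with redrawing of (rare)
negative values. Its defaults — four waists {0.20, 0.25, 0.30, 0.35} µm
(plausible spans for 488 nm illumination; the measured waists were not
published), 15 cells (middle of the 10–20 convention), cv = 0.15 — are the
study conditions for all round-trip experiments; cv = 0.15 reproduces
printed intercept SEMs of ~1.4–2.5 ms under the regression convention
above.

## FRAP

The generator produces a 2.5-µm circular-ROI bleach with 5 pre-bleach
frames at 1, full or partial bleach depth, and 100 post-bleach frames at
1.5 s intervals (so the series spans ~150 s ≫ t₁/₂): post-bleach signal
(1 − depth) + depth·(M/100)·f(t), with f the Soumpasis uniform-disk
recovery with τ_D = r²/(4D), plus multiplicative Gaussian noise of chosen
CV. Normalization anchors the mean pre-bleach level to 1 and the first
post-bleach frame to 0, with no acquisition-bleaching correction (none was
applied in the reference protocol). The fit estimates M ∈ [0, 1] and τ_D
by least squares; t₁/₂ is where the fitted curve reaches M/2 — for the
disk model t₁/₂ = (2/x*)·τ_D ≈ 0.8946·τ_D with x* solving
e^(−x)(I₀(x)+I₁(x)) = ½ (Bessel terms evaluated with exponentially scaled
`scipy.special.ive` for stability at small t). A single-exponential
fallback (t₁/₂ = τ·ln 2) is selectable; both give identical half-times on
round trips. The instrument software's exact normalization and half-time
definitions are unknown, so recovered values are interpreted as round-trip
targets, not re-derivations of instrument output. A flat post-bleach curve
reports mobile fraction 0 with undefined (NaN) half-time. The closed form
was validated against an independent finite-difference diffusion solution
of the bleached disk on a 256² grid (agreement within 2 %).

## Experiment orchestration

Two fidelity tiers share the inference code path: `law_level` (seconds;
draws per-cell τ_d from the ground-truth line) and `particle` (minutes;
the full microscopic chain per cell and waist). All randomness derives
from one root seed via `SeedSequence` child streams, recorded with a
config hash in each report, so any report is exactly reproducible.
Condition comparisons are reported descriptively (means ± SEM/SD and
ratios); no packaged hypothesis test.

## Problem sizes used by the test and acceptance runs

Law-level round trips use 100 replicates of (4 waists × 15 cells,
cv = 0.15); FRAP round trips use 50 curves at 2 % noise. The
particle-mode checks use 10 cells × 20 runs × 5 s for the free preset,
10 cells × 8 runs for the trapped preset, and one pooled two-waist
experiment of 12 cells × 3 runs per p_escape value for the monotonicity
check (pooling all cells into a single law fit per grid value gives far
better intercept SNR than averaging many tiny replicate fits) — sizes
chosen to keep the whole suite in the tens of minutes on one core while
leaving each statistical margin comfortably wider than the observed
spread.

## What the generators do and do not emulate

The synthetic data reproduce the acquisition geometry (waists, run
structure, cell counts, bleach geometry), Poisson photon statistics,
cell-to-cell variability, and the trapping mechanism. They do not include
triplet photophysics, detector afterpulsing, photobleaching within FCS
runs, membrane curvature or 3D diffusion, cytoskeletal meshes,
reaction-dominant FRAP binding, or polarized cap-shaped probe
distributions. Passing round trips therefore demonstrate that the
estimators are unbiased under the stated model at realistic noise — not
that living-cell measurements are free of these unmodeled effects.
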