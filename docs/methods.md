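# Methods

This note documents the models behind `rodspt`, the parameters that matter,
what the synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open. Units throughout: lengths
in μm, times in s, rates in 1/s; intensities are arbitrary units.

## Diffusion-state decomposition

High-frequency trajectories (frame interval τ ≈ 60 ms) are decomposed into a
bound (D = 0) and one or two diffusive populations from the distribution of
jump magnitudes. For a molecule in state j with diffusion constant D_j and
isotropic per-coordinate localization error σ, the jump magnitude at lag Δt
follows

    P(r, Δt) = r / (2 s_j) · exp(−r² / (4 s_j)),   s_j = D_j Δt + σ²,

and a k-state mixture is the f_j-weighted sum. The model neglects state
transitions within a track (the no-transition approximation) and axial
motion. We fit binned empirical densities at lags 1–5 jointly by trust-region
least squares with f ∈ [0,1], D ∈ [0, 0.5] μm²/s, σ ∈ [0, 0.1] μm, shared σ,
ten seeded restarts, and tolerances 1e-12 on the objective; the bound state's
D is pinned at zero by default and its weight is the bound fraction b. The
normalized residual `chi2_norm` is the residual sum of squares divided by the
number of bins and the number of lags. Jump histograms use a 10 nm bin width
(exposed as a parameter; the resolution of the analysis is insensitive to it
between 5 and 20 nm).

Uncertainties: per-bin counting statistics understate the fit uncertainty
because jumps within a track share the molecule's state and localization
noise, and overlapping lags reuse the same coordinates. The
`fit_diffusion_with_bootstrap` path therefore resamples whole tracks and
refits each resample from the full-data estimate; its percentile intervals
are the ones to report. The naive Gauss–Newton intervals are retained on the
plain fit but are several-fold too narrow for track data.

The complementary D_eff-based method computes, per track, the slope of the
time-averaged MSD over the first four steps (MSD = 4 D_eff t + 4σ²; D_eff
may be negative) and decomposes the D_eff histogram (bins of 0.005 μm²/s
over [−0.015, 0.055]) as b·p(D_eff | 0, σ) + (1−b)·p(D_eff | D, σ) with
reference distributions simulated on a grid (D ∈ [0.015, 0.06] step 0.005;
σ ∈ [0, 40] nm step 5 nm). b is set by matching the two bins flanking
D_eff = 0; (D, σ) minimize the residual sum of squares, with a warning when
the minimum sits on the grid boundary. σ is weakly identified by this
method — the immobile D_eff peak is narrower than the bin width for all σ in
the grid — so resolving it at the 5 nm grid spacing requires on the order of
10⁴–10⁵ tracks; D is well identified already at a few thousand.

## Motion-state classification and switching rates

Low-frequency imaging (τ = 3.6 s) resolves bound molecules as immobile or
persistently moving. The smoothed speed at point t is
v(t) = |r(t+w/2) − r(t−w/2)| / (wτ) with window w = 4 steps, and a point is
persistent iff v(t) strictly exceeds v_thr = 8 nm/s (a tie counts as
immobile; the window must fit inside the track, so two points at each end
are not evaluated). The (w, v_thr) defaults are calibrated by grid search on
simulated pure-immobile and pure-persistent tracks at the study conditions
(v = 14 nm/s, σ = 25 nm, exponential track lengths of mean 3.5 steps),
where they classify ≈99.5% of evaluated points correctly in both classes.
Accuracy is reported per evaluated time point; a segment-level accuracy can
be derived from the returned label series but is not the primary metric.

Switching rates divide transition counts by dwell time in the source state,
after interior single-point segments are merged into their flanking state.
Known limitation: the windowed speed smears transitions over ±w/2 steps and
the single-step merge removes genuine one-frame excursions, which biases
both rates low by roughly 25% at (k_ip, k_pi) ≈ (0.03, 0.02) s⁻¹. The bias
shrinks as dwell times grow relative to the window; rate comparisons between
conditions analyzed identically are unaffected to first order.

Per-track velocities come from the quadratic MSD fit ⟨x²⟩ = v²t² + b using
at least four and at most ten lags (longer tracks are capped to avoid
biasing the selection toward slow molecules that stay in the evanescent
field longer); persistent tracks are conventionally those with R² ≥ 0.9.

## Binding and unbinding kinetics

Observed track-length distributions decay as P(n) ∝ q(τ)ⁿ with per-frame
survival q(τ) = (1 − p_b)·exp(−k_a τ): bleaching consumes one factor per
exposure regardless of the interval, while termination (unbinding plus
field-of-view escape) accrues with real time. Two histograms at distinct
intervals (1 s and 12 s) therefore separate p_b from k_a exactly: the two
count-weighted log-linear slopes over the window n ∈ [3, 7] give a closed-
form solution. Confidence intervals come from a multinomial bootstrap
(200 resamples). A single interval leaves a flat direction — any
(p_b, k_a) pair with the same q fits equally well — which is why the
constructor refuses identical intervals.

Bound-molecule FRAP: after bleaching, previously bound molecules are dark,
so the measured bound fraction starts near zero and recovers as returning
diffusive molecules bind. The generator simulates the two-state occupancy
mechanistically (binding at k_db, unbinding at the detailed-balance rate
k_bd = k_db(1 − b_eq)/b_eq), for which the relaxation rate of
b(t) = a1 − a2·e^{−rate·t} is rate = k_db + k_bd = k_db/b_eq. The fit
therefore reports both the raw exponential `rate` and the binding rate
k_db = rate × a1 (a1 estimates b_eq), with delta-method intervals; lags are
weighted by inverse binomial variance. A fit with vanishing amplitude a2 is
flagged unidentifiable rather than reported.

Field-of-view Monte Carlo: the TIRF field is a strip bounded in one
coordinate (width 0.6 μm) and unbounded in the other. Molecules start at
uniform positions, switch between immobile and persistent states at
(k_ip, k_pi), and move at constant speed during persistent runs, with a
fresh direction per run (uniform random for the escape-time estimate,
±perpendicular for the unbinding-rate bound, matching the respective
experimental geometries). The integration step is τ/36 = 0.1 s so that
switching within a frame is resolved; exit is the molecule's center crossing
the strip edge. The escape time depends strongly on the switching rates,
which are exposed as parameters. The unbinding-rate bound rescales one
switching rate to hold the persistent fraction at its measured value,
simulates lifetime histograms over a grid of candidate k_bd, extracts the
apparent k_a from the 12 s histogram with the known p_b divided out, and
inverts the monotone k_a(k_bd) map at the measured k_a.

## Encounter-rate simulation

Overdamped Brownian dynamics of N = 100 point enzymes with D = 0.06 μm²/s
on a periodic 3 × 3 μm rectangle (the unrolled side wall of a 1 μm × 3 μm
rod; poles ignored), with n = 10 static reactive discs of diameter
a = 10 nm at random non-overlapping positions. Per-axis Gaussian steps of
s.d. √(2 D dt) with dt = 10⁻⁵ s, so the r.m.s. step (≈1.5 nm) resolves the
discs; the constructor enforces √(4 D dt) ≤ a/2. An enzyme entering a disc
while active registers an encounter and is then inactive for a
deterministic latency t_off ≥ 10⁻⁴ s (it keeps diffusing). The per-site
encounter rate γ = encounters / (n_sites · T) is compared with the
cross-linking rate λ = speed / cross-link spacing = 15 s⁻¹ at 30 nm/s and
2 nm.

Model choice — post-reaction release: after a registered reaction the
enzyme is displaced by 2a in a random direction (the same displacement
scale used for knocking enzymes off filaments) before the latency starts.
Without it, the recurrence of two-dimensional diffusion at the disc edge
makes same-site rebinding dominate the count at small latencies (mean
successive-run lengths above ten and an order-of-magnitude dependence of γ
on t_off), which contradicts the weak t_off-dependence and the minor
rebinding fraction this model family is meant to exhibit. With the release
offset, γ varies only about two-fold over t_off ∈ [10⁻⁴, 10⁻¹] s and
λ/γ ≥ 5 across the whole range. Re-registration at the same site
additionally requires exiting and re-entering the disc.

Facilitated mode attaches an impenetrable filament of length l along y to
every site. A free enzyme whose step segment crosses a filament attaches at
the crossing point; on the filament it diffuses in 1D with the same D,
detaches at the ends, or is displaced off sideways by 2a at rate k_off;
hitting the central site registers an encounter as above. Facilitation
raises γ and makes the recorded (unwrapped) per-axis MSD anisotropic
(faster along the filament axis) — the signature the experimental
anisotropy test looks for and does not find in the data, which is the
argument against facilitated sliding.

Successive-reaction runs: consecutive encounters of one enzyme at one site,
ended when that enzyme reacts at a different site; runs still open at the
end of the simulation are counted (censored).

## Curvature–intensity analysis

Contour curvature is the signed three-point circumscribed-circle curvature,
Gauss-filtered circularly with σ = 2 contour steps; positive at poles and
bulges, negative at indentations. Centerline curvature is computed from the
Gauss-smoothed centerline (σ = 3.5 steps, 32 nm spacing); cells bent to the
right of the direction of travel have positive κ, and contour points carry
a side label (+1 right, −1 left) from the sign convention of the offset.
Side-wall masks remove the pole caps, 2 μm of centerline arclength from
each pole, and a 650 nm window at mid-cell; straight segments additionally
require |κ| < 0.05 μm⁻¹.

A rod of width w bent with centerline curvature κ has side-wall contour
curvature −κ/(1 − κw/2) on the concave (inner) face and +κ/(1 + κw/2) on
the convex (outer) face. The curvature correction subtracts exactly this
per-side geometric term (the per-side single-denominator form ±κ/(1 − κw/2)
agrees to second order in κw; the exact form makes pure bending correct to
zero identically). The intensity correction divides by the first-order
modulation 1 + side·α·κ·w with α = 0.2 by default. Both require
|κ|w/2 < 1. Enrichment curves bin normalized intensity by contour curvature
(0.1 μm⁻¹ bins centered on multiples of the bin width), normalize by the
mean over |c| < 0.05 μm⁻¹ (falling back to the masked mean for uniformly
bent cells with no near-straight contour), and drop bins holding less than
0.1% of the points; filtering always precedes masking, and pooling across
cells normalizes per cell first.

Boundary sampling interpolates a Gauss-smoothed image (σ = 0.5 px, 65 nm
pixels) at the contour shifted by a registration offset Δr (default zero
for synthetic fields; microscope-specific in practice) and s = 140 nm
inward along the outward normal, averaging the values at the corrected
point and ±65 nm along the normal. Peak statistics subtract the per-contour
median and keep positive local maxima above three times the noise floor,
estimated as the standard deviation of the difference between σ = 0.5 px
and σ = 3 px filtered versions of the image.

## Synthetic-data generators

All generators take an integer seed, use one `numpy.random.Generator` per
call, and are bit-reproducible. Track lengths are rounded exponentials with
mean 3.5 steps (low-frequency) or 10 steps (high-frequency), redrawn until
at least one step — the observed length distributions under bleaching.
Localization noise is applied to every point, including the first.

* `simulate_tracked_population`: immobile molecules plus pure Brownian
  walks; defaults are the reference condition (b = 0.22, D = 0.042 μm²/s,
  σ = 25 nm, τ = 60 ms).
* `simulate_bound_motion_tracks`: continuous-time two-state switching with
  exponential dwells; persistent runs at constant speed along +x
  (calibration), ±x, or uniform random directions; optional per-frame
  bleaching, unbinding, and strip-exit termination. Ground-truth state
  labels are recorded at each frame instant.
* `simulate_track_lifetimes`: geometric observed lengths at per-frame
  survival (1 − p_b)·e^{−k_a τ}, capped at the simulated horizon.
* `simulate_frap_experiment`: exact-jump two-state occupancy per molecule;
  the measured bound fraction is the binomial state count, so the fit stage
  is tested against a process it does not assume.
* `generate_synthetic_cell`: a bent rod with hemispherical poles; the
  centerline follows a prescribed κ(s), side walls are offset by w/2, and
  boundary intensity is I₀(1 + side·α·κ·w)(1 + noise). Curvature-neutral
  bulges and indentations are Gaussian bumps applied along the outward
  normal that deform the contour without entering the intensity coupling.

What the generators do not emulate: fluorophore blinking and photophysics
beyond one bleaching probability per frame, three-dimensional membrane
geometry and the out-of-plane motion it induces, point-spread-function
rendering (tracking-stage tests render idealized Gaussian spots directly),
segmentation error in contours, and spatial heterogeneity of binding sites.
Passing tests therefore demonstrate correctness of the estimators under the
stated statistical models, not robustness to these real-data effects.

## Problem sizes and test design

The default test and reproduction runs use 10⁴ tracks for classifier
accuracies, 6 × 10³–4 × 10⁴ tracks for diffusion fits (the larger size only
where σ-resolution on the reference grid is the point), 1.2 × 10⁵ tracks
per lifetime histogram, and 3–20 s of simulated time for the
Brownian-dynamics runs — sizes at which the measured quantities are stable
to well within the tolerances asserted, while a full run of suite plus
reproduction script stays in the minutes range on a single core. Monte
Carlo standard errors are reported from ten molecule batches. Statistical
recovery tests use fixed seeds; interval-based checks on the nine-point
diffusion parameter sweep apply a Hotelling-corrected, Bonferroni-adjusted
ellipsoid so the family of nine checks holds jointly at the 95% level.
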