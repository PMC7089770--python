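# rodspt

Single-particle-tracking analysis for bacterial cell-wall enzymes — built
around the question of how the transpeptidase PBP2 finds and feeds the
peptidoglycan-synthesizing Rod complex in *E. coli*.

Fluorescently tagged PBP2 imaged by sptPALM in TIRF mode shows two
populations: fast-diffusing molecules searching the membrane, and bound
molecules that are either immobile or moving persistently at Rod-complex
speed (~10–40 nm/s). `rodspt` implements the full quantitative chain for
this kind of experiment:

* **Tracking** (`rodspt.tracking`) — spot detection by bandpass filtering and
  2D Gaussian refinement, conservative nearest-neighbour linking (a track is
  discontinued on any ambiguity), and localization-accuracy estimation from
  immobile tracks (σ = σ_d/√2).
* **Diffusion decomposition** (`rodspt.diffusion`) — the jump-length
  distribution at lag Δt for a k-state diffusion mixture with localization
  error σ,

  ```
  P(r, Δt) = Σ_j f_j · r / (2 (D_j Δt + σ²)) · exp(−r² / (4 (D_j Δt + σ²)))
  ```

  fitted jointly over lags 1–5 with the bound state pinned at D = 0, so the
  bound fraction is b = f_{D=0}; plus the complementary per-track
  effective-diffusion-constant method (MSD = 4 D_eff t + 4σ², grid
  decomposition against simulated reference distributions).
* **Motion-state kinetics** (`rodspt.motion`) — sliding-window speed
  classification of bound molecules into immobile and persistent states
  (v(t) = |r(t+w/2) − r(t−w/2)|/(wτ), persistent iff v > v_thr), classifier
  calibration on simulated tracks, per-track velocity from the quadratic MSD
  fit ⟨x²⟩ = v²t² + b, and switching rates k_ip, k_pi from transition counts
  over dwell times.
* **Binding kinetics** (`rodspt.kinetics`) — the joint two-interval lifetime
  fit separating per-frame bleaching p_b from the apparent termination rate
  k_a via q(τ) = (1 − p_b)·e^{−k_a τ}; bound-molecule-FRAP recovery fits for
  the binding rate k_db; the detailed-balance relation
  k_bd = k_db (1 − b)/b; and strip Monte-Carlo estimates of field-of-view
  escape and of the upper bound on the true unbinding rate.
* **Encounter-rate simulation** (`rodspt.encounter`) — overdamped Brownian
  dynamics of N enzymes on a periodic 3 × 3 μm membrane patch with small
  reactive discs, testing whether free diffusion can sustain the
  cross-linking rate λ = (synthesis speed)/(cross-link spacing) ≈ 15 s⁻¹;
  optional facilitated 1D diffusion along filaments.
* **Curvature correlations** (`rodspt.curvature`) — contour and centerline
  curvature of segmented rod cells, boundary-intensity sampling, pole/septum
  and straight-segment masks, the two bending corrections
  (c ∓ κ/(1 ∓ κw/2) and I/(1 ± ακw)), curvature–intensity enrichment
  curves, boundary peak statistics and per-cell Pearson colocalization.
* **Synthetic data** (`rodspt.simulate`) — seeded generators for every one of
  those stages: diffusive/bound track mixtures, two-state motion tracks,
  lifetime and FRAP datasets, and bent synthetic cells with
  curvature-coupled boundary intensity.

All lengths are in μm, times in s, rates in 1/s.

## Worked example

Simulate a mixed population at the reference condition — bound fraction
0.22, diffusive D = 0.042 μm²/s, σ = 25 nm, 60 ms frame interval — and
decompose it again from the jump-length distributions:

```
$ cat pop.json
{"b": 0.22, "d_states": [[0.78, 0.042]], "sigma_loc": 0.025,
 "tau": 0.06, "n_tracks": 8000, "mean_steps": 10}
$ rodspt simulate --config pop.json --seed 7 --out tracks.csv
wrote 8000 tracks to tracks.csv
$ rodspt diffusion-fit tracks.csv --interval 0.06 --states 2
{
  "n_states": 2,
  "fractions": [0.2259, 0.7741],
  "d_values_um2_s": [0.0, 0.0415],
  "bound_fraction": 0.2259,
  "sigma_um": 0.0252,
  "chi2_norm": 0.0019,
  ...
}
```

The fit recovers the generating parameters: 22.6% of molecules in the
immobile (bound) state against a ground truth of 22%, a diffusive
D = 0.0415 μm²/s against 0.042, and a localization error of 25.2 nm
against 25 nm. `chi2_norm` is the residual sum divided by the number of
histogram bins and lags. The same workflow in Python:

```python
from rodspt import (PopulationSimConfig, simulate_tracked_population,
                    jump_length_distributions, fit_multistate_diffusion)

tracks = simulate_tracked_population(PopulationSimConfig(seed=7))
fit = fit_multistate_diffusion(jump_length_distributions(tracks))
print(fit.bound_fraction, fit.d_values, fit.sigma)
```

The back-of-envelope table is available as `rodspt examples`:

```
$ rodspt examples
2000 monomers/cell, 40 monomers/filament -> 50 filaments
11000 monomers/cell, 40 monomers/filament -> 275 filaments
RodA:PBP2 at t=0 under 3x overexpression: 0.45
RodA per bound PBP2 at observed depletion ratio 0.1 (b=0.19): 0.53
```

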