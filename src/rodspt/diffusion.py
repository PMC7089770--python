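"""Bound/diffusive decomposition of high-frequency track data.

Two complementary routes:

1. Jump-length-distribution mixture fitting (:func:`fit_multistate_diffusion`)
   — the displacement-magnitude distribution at lag ``dt`` for a k-state,
   no-transition diffusion mixture with localization error ``sigma`` is

       P(r, dt) = sum_j f_j * r / (2 (D_j dt + sigma^2))
                          * exp(-r^2 / (4 (D_j dt + sigma^2)))

   fitted jointly over lags 1..5; the bound fraction is the weight of the
   D = 0 state.

2. The per-track effective-diffusion-constant method
   (:func:`effective_diffusion_constants` / :func:`fit_deff_mixture`) —
   each track's first 4 steps give a linear-MSD slope
   ``MSD = 4 D_eff t + 4 sigma^2``; the D_eff histogram is decomposed as
   ``b p(D_eff | 0, sigma) + (1 - b) p(D_eff | D, sigma)`` against
   simulated reference distributions on a (D, sigma) grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .tracks import TrackSet


# --------------------------------------------------------------------------
# jump-length histograms
# --------------------------------------------------------------------------

@dataclass
class JumpLengthData:
    """Per-lag histograms of jump magnitudes."""

    bin_edges: np.ndarray          # shared edges, um
    counts: np.ndarray             # (n_lags, n_bins)
    lag_times: np.ndarray          # m * tau for m = 1..max_lag, s
    n_jumps: np.ndarray            # jumps per lag
    n_tracks: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def densities(self) -> np.ndarray:
        """Per-lag empirical probability densities."""
        return self.counts / (self.n_jumps[:, None] * self.bin_width)


def jump_length_distributions(tracks: TrackSet, max_lag: int = 5,
                              min_len: int = 4, bin_width: float = 0.010,
                              r_max: float | None = None) -> JumpLengthData:
    """Histograms of displacement magnitudes at lags 1..max_lag.

    ``min_len`` is the minimum number of localizations per track (4 for
    PAmCherry-like, 7 for GFP-like data).  Displacements at lag m are taken
    from all (overlapping) start points.
    """
    jumps = [[] for _ in range(max_lag)]
    n_used = 0
    for pos in tracks.iter_positions(min_length=min_len):
        n_used += 1
        for m in range(1, min(max_lag, len(pos) - 1) + 1):
            d = pos[m:] - pos[:-m]
            jumps[m - 1].append(np.hypot(d[:, 0], d[:, 1]))
    if n_used == 0:
        raise ValueError(f"no tracks with >= {min_len} localizations")
    jumps = [np.concatenate(j) if j else np.empty(0) for j in jumps]
    if r_max is None:
        top = max((j.max() for j in jumps if j.size), default=bin_width)
        r_max = bin_width * math.ceil(top / bin_width)
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts = np.stack([np.histogram(j, bins=edges)[0] for j in jumps])
    return JumpLengthData(bin_edges=edges, counts=counts.astype(float),
                          lag_times=np.arange(1, max_lag + 1) * tracks.tau,
                          n_jumps=np.array([j.size for j in jumps], dtype=float),
                          n_tracks=n_used)


# --------------------------------------------------------------------------
# mixture model fit
# --------------------------------------------------------------------------

@dataclass
class DiffusionFit:
    """k-state jump-length mixture fit result."""

    n_states: int
    fractions: np.ndarray          # sums to 1; index 0 = bound when fixed
    d_values: np.ndarray           # um^2/s, same order as fractions
    sigma: float                   # localization error, um
    chi2_norm: float               # RSS / (n_bins * n_lags)
    ci: dict = field(default_factory=dict)
    success: bool = True
    message: str = ""
    raw_params: np.ndarray | None = None   # optimizer-space parameter vector

    @property
    def bound_fraction(self) -> float:
        zero = np.isclose(self.d_values, 0.0)
        return float(self.fractions[zero].sum())


def mixture_density(r, dt, fractions, d_values, sigma):
    """Analytic jump-magnitude density of a no-transition diffusion mixture."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for f, d in zip(fractions, d_values):
        s = d * dt + sigma ** 2
        if s <= 0:
            continue
        out += f * r / (2 * s) * np.exp(-r ** 2 / (4 * s))
    return out


def sample_mixture(rng, n, dt, fractions, d_values, sigma):
    """Draw jump magnitudes from the analytic mixture (for self-consistency tests)."""
    states = rng.choice(len(fractions), size=n, p=np.asarray(fractions))
    s = np.array([d * dt + sigma ** 2 for d in d_values])[states]
    # magnitude of a 2D isotropic Gaussian with per-axis variance 2s
    return np.sqrt(2 * s) * np.sqrt(rng.standard_normal(n) ** 2
                                    + rng.standard_normal(n) ** 2)


def _unpack(theta, n_states, fix_bound_zero):
    if fix_bound_zero:
        if n_states == 2:
            b, d1, sig = theta
            return np.array([b, 1 - b]), np.array([0.0, d1]), sig
        b, g, d1, d2, sig = theta
        return (np.array([b, (1 - b) * g, (1 - b) * (1 - g)]),
                np.array([0.0, d1, d2]), sig)
    if n_states == 2:
        f1, d1, d2, sig = theta
        return np.array([f1, 1 - f1]), np.array([d1, d2]), sig
    f1, g, d1, d2, d3, sig = theta
    return (np.array([f1, (1 - f1) * g, (1 - f1) * (1 - g)]),
            np.array([d1, d2, d3]), sig)


def fit_multistate_diffusion(data: JumpLengthData, n_states: int = 2,
                             fix_bound_zero: bool = True,
                             n_restarts: int = 10, seed: int = 0,
                             d_max: float = 0.5,
                             sigma_max: float = 0.1,
                             starts=None) -> DiffusionFit:
    """Least-squares fit of the k-state mixture to binned jump densities.

    The localization error ``sigma`` is shared across lags and states; with
    ``fix_bound_zero`` the first state is pinned at D = 0 and its weight is
    the bound fraction.  Multi-start (``n_restarts`` seeded restarts) trust
    region optimization; the normalized residual is RSS divided by the
    number of bins and the number of lags.
    """
    if n_states not in (2, 3):
        raise ValueError("n_states must be 2 or 3")
    if len(data.lag_times) < 2:
        raise ValueError("need at least 2 lags")
    dens = data.densities()
    if not np.any(dens > 0):
        raise ValueError("degenerate data: all-zero jump histograms")
    centers = data.bin_centers

    def residuals(theta):
        fractions, ds, sig = _unpack(theta, n_states, fix_bound_zero)
        res = [dens[i] - mixture_density(centers, dt, fractions, ds, sig)
               for i, dt in enumerate(data.lag_times)]
        return np.concatenate(res)

    # crude moment guesses for informed starts
    msj = float(np.sum(dens[0] * centers ** 2) * data.bin_width)
    d_guess = min(max(msj / (4 * data.lag_times[0]), 1e-4), d_max * 0.9)
    rng = np.random.default_rng(seed)
    if fix_bound_zero:
        if n_states == 2:
            lo, hi = [0, 0, 0], [1, d_max, sigma_max]
            informed = [[0.3, d_guess, 0.02]]
        else:
            lo, hi = [0, 0, 0, 0, 0], [1, 1, d_max, d_max, sigma_max]
            informed = [[0.3, 0.5, d_guess / 2, d_guess * 2, 0.02]]
    else:
        if n_states == 2:
            lo, hi = [0, 0, 0, 0], [1, d_max, d_max, sigma_max]
            informed = [[0.3, 1e-4, d_guess, 0.02]]
        else:
            lo, hi = [0, 0, 0, 0, 0, 0], [1, 1, d_max, d_max, d_max, sigma_max]
            informed = [[0.3, 0.5, 1e-4, d_guess / 2, d_guess * 2, 0.02]]
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    if starts is None:
        starts = list(informed)
        for _ in range(max(n_restarts - len(starts), 0)):
            starts.append(lo + rng.random(len(lo)) * (hi - lo))

    best = None
    for s0 in starts:
        try:
            res = optimize.least_squares(residuals, np.clip(s0, lo, hi),
                                         bounds=(lo, hi), xtol=1e-12,
                                         ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("multistate diffusion fit failed to converge "
                           "from every start point")

    fractions, ds, sig = _unpack(best.x, n_states, fix_bound_zero)
    # sort mobile states by D, keeping a fixed bound state first
    if fix_bound_zero:
        order = np.concatenate([[0], 1 + np.argsort(ds[1:])])
    else:
        order = np.argsort(ds)
    fractions, ds = fractions[order], ds[order]
    rss = 2 * best.cost
    chi2_norm = rss / (dens.shape[1] * dens.shape[0])

    ci = {}
    try:
        dof = max(best.fun.size - best.x.size, 1)
        cov = np.linalg.pinv(best.jac.T @ best.jac) * rss / dof
        err = np.sqrt(np.clip(np.diag(cov), 0, None))
        names = (["b", "D", "sigma"] if (fix_bound_zero and n_states == 2) else None)
        if names:
            for name, val, e in zip(names, best.x, err):
                ci[name] = (val - 1.96 * e, val + 1.96 * e)
    except np.linalg.LinAlgError:
        pass
    return DiffusionFit(n_states=n_states, fractions=fractions, d_values=ds,
                        sigma=float(sig), chi2_norm=float(chi2_norm), ci=ci,
                        success=bool(best.success), message=str(best.message),
                        raw_params=best.x.copy())


def fit_diffusion_with_bootstrap(tracks: TrackSet, n_states: int = 2,
                                 fix_bound_zero: bool = True, max_lag: int = 5,
                                 min_len: int = 4, bin_width: float = 0.010,
                                 n_boot: int = 40, seed: int = 0,
                                 n_restarts: int = 10):
    """Mixture fit with track-level bootstrap uncertainties.

    Jumps within a track share the molecule's state and its localization
    noise, so per-bin counting statistics understate the fit uncertainty;
    resampling whole tracks respects those correlations.  Refits start from
    the full-data estimate.  Returns ``(DiffusionFit, boot_params)`` where
    ``boot_params`` is the (n_boot, n_params) array of bootstrap estimates
    in the order (bound fraction, D_1.., sigma); percentile CIs are stored
    on the fit under ``b``, ``D<j>`` and ``sigma``.
    """
    data = jump_length_distributions(tracks, max_lag=max_lag, min_len=min_len,
                                     bin_width=bin_width)
    fit = fit_multistate_diffusion(data, n_states=n_states,
                                   fix_bound_zero=fix_bound_zero,
                                   n_restarts=n_restarts, seed=seed)
    # per-track per-lag histogram counts on the shared edges
    per_track = []
    for pos in tracks.iter_positions(min_length=min_len):
        mats = []
        for m in range(1, max_lag + 1):
            if len(pos) - 1 >= m:
                d = pos[m:] - pos[:-m]
                r = np.hypot(d[:, 0], d[:, 1])
                mats.append(np.histogram(r, bins=data.bin_edges)[0])
            else:
                mats.append(np.zeros(len(data.bin_edges) - 1, dtype=int))
        per_track.append(np.stack(mats))
    per_track = np.stack(per_track)          # (n_tracks, n_lags, n_bins)

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(per_track), len(per_track))
        counts = per_track[idx].sum(axis=0).astype(float)
        bdata = JumpLengthData(data.bin_edges, counts, data.lag_times,
                               counts.sum(axis=1).clip(min=1), len(idx))
        bfit = fit_multistate_diffusion(bdata, n_states=n_states,
                                        fix_bound_zero=fix_bound_zero,
                                        starts=[fit.raw_params])
        boots.append(np.concatenate([[bfit.bound_fraction],
                                     bfit.d_values[1:] if fix_bound_zero
                                     else bfit.d_values,
                                     [bfit.sigma]]))
    boots = np.asarray(boots)
    names = (["b"] + [f"D{j}" for j in range(1, boots.shape[1] - 1)]
             + ["sigma"])
    for k, name in enumerate(names):
        fit.ci[name] = tuple(np.percentile(boots[:, k], [2.5, 97.5]))
    return fit, boots


# --------------------------------------------------------------------------
# D_eff-based method
# --------------------------------------------------------------------------

def effective_diffusion_constants(tracks: TrackSet, n_steps: int = 4) -> np.ndarray:
    """Per-track effective diffusion constants from the first ``n_steps`` steps.

    Linear fit of the time-averaged single-track MSD at lags 1..n_steps
    (``MSD = 4 D_eff t + 4 sigma^2``); D_eff may be negative.  Tracks with
    fewer than ``n_steps + 1`` localizations are skipped.
    """
    lags = np.arange(1, n_steps + 1) * tracks.tau
    out = []
    for pos in tracks.iter_positions(min_length=n_steps + 1):
        pos = pos[:n_steps + 1]
        msd = np.array([np.mean(np.sum((pos[m:] - pos[:-m]) ** 2, axis=1))
                        for m in range(1, n_steps + 1)])
        slope = np.polyfit(lags, msd, 1)[0]
        out.append(slope / 4.0)
    return np.asarray(out)


def _default_reference_sim(tau: float, n_steps: int = 4):
    """Reference D_eff sampler: noisy Brownian tracks at given (D, sigma)."""

    def sim(d, sigma, n_tracks, rng):
        steps = rng.normal(0.0, math.sqrt(max(2 * d * tau, 0.0)),
                           (n_tracks, n_steps, 2))
        pos = np.concatenate([np.zeros((n_tracks, 1, 2)),
                              np.cumsum(steps, axis=1)], axis=1)
        pos = pos + rng.normal(0.0, sigma, pos.shape)
        lags = np.arange(1, n_steps + 1) * tau
        msd = np.stack([np.mean(np.sum((pos[:, m:] - pos[:, :-m]) ** 2, axis=2),
                                axis=1) for m in range(1, n_steps + 1)], axis=1)
        t_c = lags - lags.mean()
        slope = (msd * t_c).sum(axis=1) / (t_c ** 2).sum()
        return slope / 4.0

    return sim


@dataclass
class DeffMixtureFit:
    """Grid decomposition of a D_eff distribution."""

    b: float
    d: float
    sigma: float
    rss_surface: np.ndarray        # (len(d_grid), len(sigma_grid))
    d_grid: np.ndarray
    sigma_grid: np.ndarray
    b_surface: np.ndarray
    boundary_solution: bool = False


def fit_deff_mixture(deff_values: np.ndarray, tau: float,
                     reference_sim=None,
                     d_grid=None, sigma_grid=None,
                     bin_width: float = 0.005,
                     deff_range=(-0.015, 0.055),
                     n_ref: int = 4000, seed: int = 0) -> DeffMixtureFit:
    """Decompose a D_eff distribution into bound + diffusive components.

    For every (D, sigma) on the grid, reference distributions
    ``p(D_eff | D, sigma)`` and ``p(D_eff | 0, sigma)`` are simulated; the
    bound fraction b is set by matching the histogram density in the two
    bins adjacent to D_eff = 0, and the (D, sigma) pair minimizing the RSS
    over the histogram window is returned.  Default grids: D in
    [0.015, 0.06] step 0.005 um^2/s, sigma in [0, 40] step 5 nm.
    """
    deff_values = np.asarray(deff_values, dtype=float)
    if d_grid is None:
        d_grid = np.arange(0.015, 0.0601, 0.005)
    if sigma_grid is None:
        sigma_grid = np.arange(0.0, 0.0401, 0.005)
    d_grid = np.asarray(d_grid, float)
    sigma_grid = np.asarray(sigma_grid, float)
    if reference_sim is None:
        reference_sim = _default_reference_sim(tau)

    edges = np.arange(deff_range[0], deff_range[1] + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    zero_bins = np.argsort(np.abs(centers))[:2]   # the two bins flanking 0

    def hist_density(values):
        counts, _ = np.histogram(values, bins=edges)
        return counts / (len(values) * bin_width)

    data_d = hist_density(deff_values)
    rss = np.full((len(d_grid), len(sigma_grid)), np.inf)
    b_sur = np.zeros_like(rss)
    for j, sig in enumerate(sigma_grid):
        rng = np.random.default_rng([seed, j])
        p0 = hist_density(reference_sim(0.0, sig, n_ref, rng))
        for i, d in enumerate(d_grid):
            pd = hist_density(reference_sim(d, sig, n_ref, rng))
            denom = p0[zero_bins].mean() - pd[zero_bins].mean()
            if denom <= 0:
                continue
            b = float(np.clip((data_d[zero_bins].mean() - pd[zero_bins].mean())
                              / denom, 0.0, 1.0))
            model = b * p0 + (1 - b) * pd
            rss[i, j] = float(np.sum((data_d - model) ** 2))
            b_sur[i, j] = b
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    boundary = (i in (0, len(d_grid) - 1)) or (j in (0, len(sigma_grid) - 1))
    if boundary:
        warnings.warn("D_eff grid minimum on the boundary; widen the grid")
    return DeffMixtureFit(b=float(b_sur[i, j]), d=float(d_grid[i]),
                          sigma=float(sigma_grid[j]), rss_surface=rss,
                          d_grid=d_grid, sigma_grid=sigma_grid,
                          b_surface=b_sur, boundary_solution=bool(boundary))
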