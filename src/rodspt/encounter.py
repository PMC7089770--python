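"""Brownian-dynamics target-search simulation on the cell surface.

Can freely diffusing enzymes sustain the physiological cross-linking rate
of a processive cell-wall synthesis site?  N enzymes diffuse on a periodic
rectangle (the unrolled cylindrical cell surface); small static discs
represent cross-linking sites.  Entering a disc while active registers an
encounter, after which the enzyme is inactive for a deterministic latency
t_off (it keeps diffusing).  Optional facilitated mode adds an impenetrable
filament of length l through each site, oriented along y: enzymes that hit
a filament attach, diffuse 1D along it with the same D, leave at the ends,
or are knocked off sideways by 2a at rate k_off.

The per-site encounter rate gamma = encounters / (n_sites * T) is compared
with the cross-linking rate lambda = speed / cross-link spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .tracks import TrackSet

_RUN_CAP = 200  # longest successive-reaction run tracked in the histogram


@dataclass
class EncounterConfig:
    n_enzymes: int = 100
    d_coef: float = 0.06          # um^2/s
    domain: tuple = (3.0, 3.0)    # um, periodic
    n_sites: int = 10
    a: float = 0.010              # site diameter, um
    t_off: float = 1e-3           # latency, s (>= 1e-4)
    dt: float = 1e-5              # integration step, s
    t_total: float = 10.0         # simulated time, s
    facilitated: bool = False
    fil_length: float = 0.5       # um
    k_off: float = 0.0            # 1/s, sideways detachment
    record_stride: int = 2000     # steps between trajectory records
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_off < 1e-4:
            raise ValueError("latency t_off must be >= 1e-4 s")
        rms = math.sqrt(4 * self.d_coef * self.dt)
        if self.n_sites > 0 and rms > self.a / 2:
            raise ValueError(
                f"dt too coarse: rms step {rms:.2e} um exceeds half the "
                f"site diameter {self.a / 2:.2e} um")


@dataclass
class EncounterResult:
    gamma: float                    # encounters per site per second
    n_encounters: int
    run_length_hist: np.ndarray     # run_length_hist[k] = runs of k+1 reactions
    msd_lags: np.ndarray            # s
    msd_x: np.ndarray               # um^2, per-axis
    msd_y: np.ndarray
    config: EncounterConfig = field(repr=False, default=None)


@njit(cache=True)
def _mi(d, L):
    """Minimum-image displacement on a period-L axis."""
    return d - L * round(d / L)


@njit(cache=True)
def _bd_kernel(seed, pos, sites, Lx, Ly, a_rad, a_diam, sd, dt, n_steps,
               t_off_steps, facilitated, fil_half, k_off, stride, traj):
    np.random.seed(seed)
    n = pos.shape[0]
    n_sites = sites.shape[0]
    upos = pos.copy()
    latency = np.zeros(n, dtype=np.int64)
    blocked = np.full(n, -1, dtype=np.int64)
    on_fil = np.full(n, -1, dtype=np.int64)
    last_site = np.full(n, -1, dtype=np.int64)
    run_len = np.zeros(n, dtype=np.int64)
    run_hist = np.zeros(_RUN_CAP, dtype=np.int64)
    p_off = k_off * dt
    encounters = 0
    rec = 0
    for step in range(n_steps):
        if stride > 0 and step % stride == 0 and rec < traj.shape[0]:
            for i in range(n):
                traj[rec, i, 0] = upos[i, 0]
                traj[rec, i, 1] = upos[i, 1]
            rec += 1
        for i in range(n):
            hit = -1
            if on_fil[i] >= 0:
                j = on_fil[i]
                dy = sd * np.random.randn()
                pos[i, 1] += dy
                upos[i, 1] += dy
                rel = _mi(pos[i, 1] - sites[j, 1], Ly)
                if abs(rel) > fil_half:
                    # step past a filament end: return to 2D at the end
                    shift = (fil_half if rel > 0 else -fil_half) - rel
                    pos[i, 1] += shift
                    upos[i, 1] += shift
                    on_fil[i] = -1
                elif p_off > 0 and np.random.rand() < p_off:
                    sign = 1.0 if np.random.rand() < 0.5 else -1.0
                    pos[i, 0] += sign * 2 * a_diam
                    upos[i, 0] += sign * 2 * a_diam
                    on_fil[i] = -1
                else:
                    if abs(rel) < a_rad and latency[i] == 0 and blocked[i] != j:
                        hit = j
            else:
                dx = sd * np.random.randn()
                dy = sd * np.random.randn()
                attached = False
                if facilitated and dx != 0.0:
                    best_frac = 2.0
                    best_j = -1
                    for j in range(n_sites):
                        rx0 = _mi(pos[i, 0] - sites[j, 0], Lx)
                        rx1 = rx0 + dx
                        if rx0 == 0.0 or rx0 * rx1 > 0.0:
                            continue
                        frac = abs(rx0) / abs(dx)
                        ycross = pos[i, 1] + frac * dy
                        if abs(_mi(ycross - sites[j, 1], Ly)) <= fil_half:
                            if frac < best_frac:
                                best_frac = frac
                                best_j = j
                    if best_j >= 0:
                        mx = -_mi(pos[i, 0] - sites[best_j, 0], Lx)
                        pos[i, 0] += mx
                        pos[i, 1] += best_frac * dy
                        upos[i, 0] += mx
                        upos[i, 1] += best_frac * dy
                        on_fil[i] = best_j
                        attached = True
                if not attached:
                    pos[i, 0] += dx
                    pos[i, 1] += dy
                    upos[i, 0] += dx
                    upos[i, 1] += dy
                # wrap into the periodic box
                pos[i, 0] -= Lx * math.floor(pos[i, 0] / Lx)
                pos[i, 1] -= Ly * math.floor(pos[i, 1] / Ly)
                for j in range(n_sites):
                    ddx = _mi(pos[i, 0] - sites[j, 0], Lx)
                    ddy = _mi(pos[i, 1] - sites[j, 1], Ly)
                    if ddx * ddx + ddy * ddy < a_rad * a_rad:
                        if blocked[i] == j:
                            break
                        if latency[i] == 0:
                            hit = j
                        break
            if hit >= 0:
                encounters += 1
                latency[i] = t_off_steps
                blocked[i] = hit
                # post-reaction release: the enzyme is displaced by 2a in a
                # random direction (same displacement scale as filament
                # knock-off), so rebinding is not dominated by the
                # recurrence of 2D diffusion at the disc edge
                phi = 2 * math.pi * np.random.rand()
                pos[i, 0] += 2 * a_diam * math.cos(phi)
                pos[i, 1] += 2 * a_diam * math.sin(phi)
                upos[i, 0] += 2 * a_diam * math.cos(phi)
                upos[i, 1] += 2 * a_diam * math.sin(phi)
                pos[i, 0] -= Lx * math.floor(pos[i, 0] / Lx)
                pos[i, 1] -= Ly * math.floor(pos[i, 1] / Ly)
                on_fil[i] = -1
                if last_site[i] == hit:
                    run_len[i] += 1
                else:
                    if last_site[i] >= 0:
                        k = min(run_len[i], _RUN_CAP) - 1
                        run_hist[k] += 1
                    last_site[i] = hit
                    run_len[i] = 1
            elif latency[i] > 0:
                latency[i] -= 1
            # clear the same-site block once the enzyme has left the disc
            if blocked[i] >= 0:
                j = blocked[i]
                ddx = _mi(pos[i, 0] - sites[j, 0], Lx)
                ddy = _mi(pos[i, 1] - sites[j, 1], Ly)
                if ddx * ddx + ddy * ddy >= a_rad * a_rad:
                    blocked[i] = -1
    for i in range(n):                 # censored runs count
        if run_len[i] > 0:
            k = min(run_len[i], _RUN_CAP) - 1
            run_hist[k] += 1
    return encounters, run_hist, rec


def _place_sites(rng, cfg: EncounterConfig) -> np.ndarray:
    lx, ly = cfg.domain
    sites = np.empty((cfg.n_sites, 2))
    placed = 0
    while placed < cfg.n_sites:
        cand = rng.uniform([0, 0], [lx, ly])
        ok = True
        for k in range(placed):
            dx = _mi(cand[0] - sites[k, 0], lx)
            dy = _mi(cand[1] - sites[k, 1], ly)
            if math.hypot(dx, dy) < 2 * cfg.a:   # overlapping sites re-drawn
                ok = False
                break
        if ok:
            sites[placed] = cand
            placed += 1
    return sites


def run_encounter_simulation(cfg: EncounterConfig) -> EncounterResult:
    """Run the Brownian-dynamics simulation and summarize encounters.

    Returns the per-site encounter rate gamma, the histogram of successive
    reactions by the same enzyme at the same site (runs end when the enzyme
    reacts at a different site; runs still open at simulation end are
    counted as censored), and per-axis MSD curves from the recorded
    (unwrapped) trajectory.
    """
    rng = np.random.default_rng(cfg.seed)
    lx, ly = cfg.domain
    pos = rng.uniform([0, 0], [lx, ly], (cfg.n_enzymes, 2))
    sites = _place_sites(rng, cfg) if cfg.n_sites else np.empty((0, 2))
    n_steps = int(round(cfg.t_total / cfg.dt))
    sd = math.sqrt(2 * cfg.d_coef * cfg.dt)
    stride = cfg.record_stride
    n_rec = n_steps // stride + 1 if stride > 0 else 0
    traj = np.zeros((n_rec, cfg.n_enzymes, 2))
    kernel_seed = int(rng.integers(0, 2 ** 31 - 1))
    encounters, run_hist, rec = _bd_kernel(
        kernel_seed, pos, sites, lx, ly, cfg.a / 2, cfg.a, sd, cfg.dt,
        n_steps, int(round(cfg.t_off / cfg.dt)), cfg.facilitated,
        cfg.fil_length / 2, cfg.k_off, stride, traj)
    traj = traj[:rec]
    gamma = encounters / (cfg.n_sites * cfg.t_total) if cfg.n_sites else 0.0
    # per-axis MSD from the recorded trajectory
    if rec > 2:
        max_lag = min(rec - 1, 50)
        lags = np.unique(np.linspace(1, max_lag, min(max_lag, 20)).astype(int))
        msd_x = np.array([np.mean((traj[m:, :, 0] - traj[:-m, :, 0]) ** 2)
                          for m in lags])
        msd_y = np.array([np.mean((traj[m:, :, 1] - traj[:-m, :, 1]) ** 2)
                          for m in lags])
        lag_times = lags * stride * cfg.dt
    else:
        lag_times = msd_x = msd_y = np.empty(0)
    return EncounterResult(gamma=float(gamma), n_encounters=int(encounters),
                           run_length_hist=run_hist, msd_lags=lag_times,
                           msd_x=msd_x, msd_y=msd_y, config=cfg)


def crosslink_rate(speed: float, crosslink_spacing: float) -> float:
    """Cross-linking rate lambda = synthesis speed / cross-link spacing (1/s)."""
    if crosslink_spacing <= 0:
        raise ValueError("cross-link spacing must be positive")
    if speed < 0:
        raise ValueError("speed must be non-negative")
    return speed / crosslink_spacing


def displacement_anisotropy(tracks: TrackSet, cell_axis, max_lag: int = 4):
    """Per-axis effective diffusion constants along and across the cell axis.

    Displacements are projected on the cell axis (x) and its perpendicular
    (y); per-axis MSDs at lags 1..max_lag are fit linearly and the slopes
    divided by 2 (1D).  Returns (D_x, D_y) in um^2/s.
    """
    axis = np.asarray(cell_axis, dtype=float)
    norm = np.hypot(*axis)
    if norm == 0:
        raise ValueError("cell axis must be a nonzero vector")
    axis = axis / norm
    perp = np.array([-axis[1], axis[0]])
    sq_x = [[] for _ in range(max_lag)]
    sq_y = [[] for _ in range(max_lag)]
    for pos in tracks.iter_positions(min_length=max_lag + 1):
        u = pos @ axis
        v = pos @ perp
        for m in range(1, max_lag + 1):
            sq_x[m - 1].append((u[m:] - u[:-m]) ** 2)
            sq_y[m - 1].append((v[m:] - v[:-m]) ** 2)
    if not sq_x[0]:
        raise ValueError("no tracks long enough for the anisotropy estimate")
    lags = np.arange(1, max_lag + 1) * tracks.tau
    msd_x = np.array([np.concatenate(s).mean() for s in sq_x])
    msd_y = np.array([np.concatenate(s).mean() for s in sq_y])
    dx = np.polyfit(lags, msd_x, 1)[0] / 2.0
    dy = np.polyfit(lags, msd_y, 1)[0] / 2.0
    return float(dx), float(dy)


def axis_diffusion_from_trajectory(traj: np.ndarray, record_dt: float,
                                   max_lag: int = 10):
    """(D_x, D_y) from a recorded (T, N, 2) unwrapped trajectory."""
    t_len = traj.shape[0]
    lags = np.arange(1, min(max_lag, t_len - 1) + 1)
    msd_x = np.array([np.mean((traj[m:, :, 0] - traj[:-m, :, 0]) ** 2)
                      for m in lags])
    msd_y = np.array([np.mean((traj[m:, :, 1] - traj[:-m, :, 1]) ** 2)
                      for m in lags])
    t = lags * record_dt
    return (float(np.polyfit(t, msd_x, 1)[0] / 2.0),
            float(np.polyfit(t, msd_y, 1)[0] / 2.0))
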