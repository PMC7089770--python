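"""Synthetic-data generators for every pipeline stage.

All generators draw from a single :class:`numpy.random.Generator` seeded per
call, so identical configurations and seeds reproduce outputs bit for bit.
Units: lengths in um, times in s, rates in 1/s.

The generators emulate

* mixed populations of immobile and Brownian molecules with isotropic
  Gaussian localization noise (:func:`simulate_tracked_population`),
* bound molecules switching between an immobile state and persistent runs
  at constant speed (:func:`simulate_bound_motion_tracks`),
* geometric/exponential track termination from per-frame bleaching and an
  apparent termination rate (:func:`simulate_track_lifetimes`),
* bound-fraction recovery after bleaching, simulated mechanistically as a
  two-state occupancy process (:func:`simulate_frap_experiment`),
* bent rod-shaped cells whose boundary intensity couples to centerline
  curvature, plus curvature-neutral bulges (:func:`generate_synthetic_cell`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .curvature import CellGeometry
from .kinetics import FRAPData, LifetimeHistogram
from .tracks import TrackSet, tracks_from_arrays


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------

@dataclass
class MotionSimConfig:
    """Bound-molecule motion simulation (low-frequency imaging conditions).

    Defaults are the study conditions of the classifier-calibration
    experiment: 3.6 s frame interval, 25 nm localization accuracy, 14 nm/s
    persistent speed, exponential track lengths of mean 3.5 steps.
    """

    tau: float = 3.6
    n_tracks: int = 1000
    mean_steps: float = 3.5
    sigma_loc: float = 0.025
    v: float = 0.014
    k_ip: float = 0.03
    k_pi: float = 0.02
    k_bd: float = 0.0
    p_b: float = 0.0
    fov_width: float | None = None
    direction: str = "x"            # 'x', 'pm_x', or 'random'
    initial_state: str = "stationary"  # 'immobile', 'persistent', 'stationary'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.mean_steps <= 0:
            raise ValueError("tau and mean_steps must be positive")
        if min(self.k_ip, self.k_pi, self.k_bd, self.v, self.sigma_loc) < 0:
            raise ValueError("rates, speed and noise must be non-negative")
        if not 0.0 <= self.p_b <= 1.0:
            raise ValueError("p_b must lie in [0, 1]")
        if self.direction not in ("x", "pm_x", "random"):
            raise ValueError("direction must be 'x', 'pm_x' or 'random'")
        if self.initial_state not in ("immobile", "persistent", "stationary"):
            raise ValueError("bad initial_state")


@dataclass
class PopulationSimConfig:
    """Mixture of immobile (bound) and Brownian molecules.

    ``d_states`` lists ``(fraction, D)`` pairs for the mobile states; the
    mobile fractions must sum to ``1 - b``.  Defaults emulate high-frequency
    imaging: 60 ms interval, 25 nm noise, tracks of ~10 steps.
    """

    b: float = 0.22
    d_states: tuple = ((0.78, 0.042),)
    sigma_loc: float = 0.025
    tau: float = 0.06
    n_tracks: int = 5000
    mean_steps: float = 10.0
    box: tuple = (10.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("b must lie in [0, 1]")
        if self.tau <= 0 or self.mean_steps <= 0:
            raise ValueError("tau and mean_steps must be positive")
        fracs = sum(f for f, _ in self.d_states)
        if self.d_states and abs(fracs - (1.0 - self.b)) > 1e-6:
            raise ValueError("mobile fractions must sum to 1 - b")
        if not self.d_states and self.b != 1.0:
            raise ValueError("empty mobile-state list requires b = 1")
        if any(d < 0 for _, d in self.d_states):
            raise ValueError("diffusion constants must be non-negative")


@dataclass
class CellSimConfig:
    """Bent rod-shaped cell with curvature-coupled boundary intensity."""

    length: float = 10.0
    width: float = 1.0
    kappa: object = 0.0             # scalar, callable kappa(s), or array
    alpha: float = 0.2
    bulge_amplitude: float = 0.0
    n_bulges: int = 0
    contour_step: float = 0.032
    intensity_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 2 * self.width / 2:
            raise ValueError("cell length must exceed its width")
        if self.width <= 0 or self.contour_step <= 0:
            raise ValueError("width and contour_step must be positive")


# --------------------------------------------------------------------------
# track-length draws
# --------------------------------------------------------------------------

def _draw_track_lengths(rng, mean_steps: float, n: int) -> np.ndarray:
    """Rounded exponential lengths (steps), redrawn until >= 1."""
    out = np.rint(rng.exponential(mean_steps, n)).astype(np.int64)
    bad = out < 1
    while bad.any():
        out[bad] = np.rint(rng.exponential(mean_steps, int(bad.sum()))).astype(np.int64)
        bad = out < 1
    return out


# --------------------------------------------------------------------------
# diffusive population
# --------------------------------------------------------------------------

def simulate_tracked_population(cfg: PopulationSimConfig) -> TrackSet:
    """Tracks of a bound/diffusive mixture with localization noise.

    Bound tracks are perfectly immobile; mobile tracks are pure Brownian
    walks with per-axis step s.d. sqrt(2 D tau).  Isotropic Gaussian noise
    of s.d. ``sigma_loc`` is added to every localization.  The per-track
    ground-truth state is recorded in the ``true_state`` column
    (``'bound'`` or ``'mobile<j>'``).
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = _draw_track_lengths(rng, cfg.mean_steps, cfg.n_tracks)
    probs = [cfg.b] + [f for f, _ in cfg.d_states]
    ds = [0.0] + [d for _, d in cfg.d_states]
    states = rng.choice(len(probs), size=cfg.n_tracks, p=np.asarray(probs) / sum(probs))
    positions, labels = [], []
    for i in range(cfg.n_tracks):
        n = lengths[i]
        start = rng.uniform([0, 0], cfg.box)
        d = ds[states[i]]
        if d > 0:
            steps = rng.normal(0.0, math.sqrt(2 * d * cfg.tau), (n, 2))
            pos = start + np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        else:
            pos = np.tile(start, (n + 1, 1))
        if cfg.sigma_loc > 0:
            pos = pos + rng.normal(0.0, cfg.sigma_loc, pos.shape)
        positions.append(pos)
        labels.append("bound" if states[i] == 0 else f"mobile{states[i] - 1}")
    meta = {"config": cfg, "state_d": ds}
    return tracks_from_arrays(positions, cfg.tau, true_states=labels, meta=meta)


# --------------------------------------------------------------------------
# bound-molecule motion
# --------------------------------------------------------------------------

def _new_direction(rng, mode: str) -> np.ndarray:
    if mode == "x":
        return np.array([1.0, 0.0])
    if mode == "pm_x":
        return np.array([rng.choice([-1.0, 1.0]), 0.0])
    theta = rng.uniform(0, 2 * np.pi)
    return np.array([math.cos(theta), math.sin(theta)])


def simulate_bound_motion_tracks(cfg: MotionSimConfig) -> TrackSet:
    """Tracks alternating immobile and persistent-run segments.

    Dwell times are exponential at ``k_ip`` / ``k_pi``; persistent runs move
    at constant speed ``v`` along a direction set by ``cfg.direction``
    (fixed +x for calibration, +/-x or uniform random per run for the
    field-of-view geometries).  Localization noise is added to every point.
    Per-point ground-truth labels (state at the frame instant) are recorded.
    Optional terminations: per-frame bleaching ``p_b``, unbinding ``k_bd``,
    and exit from a strip of width ``fov_width`` (bounded in x).
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = _draw_track_lengths(rng, cfg.mean_steps, cfg.n_tracks)
    if cfg.initial_state == "stationary":
        total = cfg.k_ip + cfg.k_pi
        p_start = cfg.k_ip / total if total > 0 else 0.0
    else:
        p_start = 1.0 if cfg.initial_state == "persistent" else 0.0

    positions, labels = [], []
    for i in range(cfg.n_tracks):
        n = int(lengths[i])
        if cfg.p_b > 0:
            n = min(n, int(rng.geometric(cfg.p_b)) - 1)
        if cfg.k_bd > 0:
            n = min(n, int(rng.exponential(1.0 / cfg.k_bd) / cfg.tau))
        persistent = rng.random() < p_start
        direction = _new_direction(rng, cfg.direction)
        if cfg.fov_width is not None:
            pos = np.array([rng.uniform(0, cfg.fov_width), 0.0])
        else:
            pos = np.zeros(2)
        pts = [pos.copy()]
        labs = ["persistent" if persistent else "immobile"]

        def dwell(is_persistent):
            rate = cfg.k_pi if is_persistent else cfg.k_ip
            return rng.exponential(1.0 / rate) if rate > 0 else math.inf

        t_next = dwell(persistent)
        for _ in range(n):
            remaining = cfg.tau
            while t_next <= remaining:
                if persistent:
                    pos = pos + cfg.v * t_next * direction
                remaining -= t_next
                persistent = not persistent
                if persistent:
                    direction = _new_direction(rng, cfg.direction)
                t_next = dwell(persistent)
            if persistent:
                pos = pos + cfg.v * remaining * direction
            t_next -= remaining
            if cfg.fov_width is not None and not 0.0 <= pos[0] <= cfg.fov_width:
                break
            pts.append(pos.copy())
            labs.append("persistent" if persistent else "immobile")
        pts = np.asarray(pts)
        if cfg.sigma_loc > 0:
            pts = pts + rng.normal(0.0, cfg.sigma_loc, pts.shape)
        positions.append(pts)
        labels.append(np.asarray(labs))
    return tracks_from_arrays(positions, cfg.tau, true_states=labels,
                              meta={"config": cfg})


# --------------------------------------------------------------------------
# lifetimes and FRAP
# --------------------------------------------------------------------------

def simulate_track_lifetimes(p_b: float, k_a: float, tau: float,
                             n_tracks: int, seed: int = 0,
                             max_steps: int = 200) -> LifetimeHistogram:
    """Observed track lengths under bleaching + apparent termination.

    Per-frame survival is ``q = (1 - p_b) exp(-k_a tau)``; observed lengths
    are geometric, ``P(n) = q^n (1 - q)``, capped at ``max_steps`` (the
    simulated horizon).
    """
    if not 0.0 <= p_b <= 1.0:
        raise ValueError("p_b must lie in [0, 1]")
    if k_a < 0 or tau <= 0:
        raise ValueError("k_a must be >= 0 and tau > 0")
    rng = np.random.default_rng(seed)
    q = (1.0 - p_b) * math.exp(-k_a * tau)
    if q >= 1.0:
        lengths = np.full(n_tracks, max_steps, dtype=np.int64)
    else:
        lengths = np.minimum(rng.geometric(1.0 - q, n_tracks) - 1, max_steps)
    counts = np.bincount(lengths, minlength=max_steps + 1)
    return LifetimeHistogram(tau, counts)


def simulate_frap_experiment(k_db: float, b_eq: float, lags,
                             n_molecules: int = 2000, seed: int = 0) -> FRAPData:
    """Bound-fraction recovery after bleaching, simulated mechanistically.

    All observable molecules start diffusive (the previously bound ones were
    bleached).  Each molecule runs a two-state jump process — binding at
    ``k_db``, unbinding at the detailed-balance rate
    ``k_bd = k_db (1 - b_eq) / b_eq`` — until the lag time, and the bound
    fraction at each lag is the binomially sampled state occupancy.
    """
    if k_db < 0:
        raise ValueError("k_db must be non-negative")
    if not 0.0 < b_eq < 1.0:
        raise ValueError("b_eq must lie in (0, 1)")
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0:
        raise ValueError("empty lag list")
    k_bd = k_db * (1.0 - b_eq) / b_eq
    rng = np.random.default_rng(seed)
    fractions = np.empty(len(lags))
    for j, lag in enumerate(lags):
        bound_now = 0
        for _ in range(n_molecules):
            t, bound = 0.0, False
            while True:
                rate = k_bd if bound else k_db
                if rate == 0:
                    break
                t += rng.exponential(1.0 / rate)
                if t >= lag:
                    break
                bound = not bound
            bound_now += bound
        fractions[j] = bound_now / n_molecules
    return FRAPData(lags, fractions, np.full(len(lags), n_molecules))


# --------------------------------------------------------------------------
# synthetic cells
# --------------------------------------------------------------------------

def _kappa_profile(cfg: CellSimConfig, s: np.ndarray) -> np.ndarray:
    if callable(cfg.kappa):
        return np.asarray([cfg.kappa(si) for si in s], dtype=float)
    arr = np.asarray(cfg.kappa, dtype=float)
    if arr.ndim == 0:
        return np.full(len(s), float(arr))
    return np.interp(s, np.linspace(0, s[-1], len(arr)), arr)


def generate_synthetic_cell(cfg: CellSimConfig):
    """Closed contour of a bent rod with hemispherical poles, plus intensity.

    The centerline runs pole tip to pole tip (arclength 0..length) with the
    prescribed curvature profile.  Side walls are offset by width/2 along
    the local normal; pole caps are semicircles.  Boundary intensity is
    ``I = I0 (1 + side * alpha * kappa * width) * (1 + noise)`` — enriched on
    the concave (inner) face of a bent cell — with optional curvature-neutral
    bulges/indentations (normal displacement bumps that deform the contour
    without entering the intensity coupling).

    Returns ``(CellGeometry, intensity array)`` with ground-truth centerline
    curvature, side labels and pole flags recorded in the geometry.
    """
    rng = np.random.default_rng(cfg.seed)
    h = cfg.contour_step
    half_w = cfg.width / 2.0
    L = cfg.length

    # centerline over full arclength 0..L
    n_cl = max(int(round(L / h)) + 1, 9)
    s_cl = np.linspace(0.0, L, n_cl)
    kap = _kappa_profile(cfg, s_cl)
    if np.any(np.abs(kap) * half_w >= 1.0):
        raise ValueError("centerline curvature too high for the cell width "
                         "(|kappa| * width / 2 >= 1)")
    # heading: positive kappa bends to the right (clockwise turning)
    theta = np.concatenate([[0.0], np.cumsum(-kap[:-1] * np.diff(s_cl))])
    tangents = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    centerline = np.concatenate(
        [[[0.0, 0.0]], np.cumsum(tangents[:-1] * np.diff(s_cl)[:, None], axis=0)])
    centerline = centerline + np.array([L, L])  # keep coordinates positive

    # side walls over s in [w/2, L - w/2]
    sel = (s_cl >= half_w) & (s_cl <= L - half_w)
    s_side = s_cl[sel]
    c_side = centerline[sel]
    t_side = tangents[sel]
    normal_left = np.stack([-t_side[:, 1], t_side[:, 0]], axis=1)
    left = c_side + half_w * normal_left
    right = c_side - half_w * normal_left

    def cap(center, tangent, start_angle_vec, sweep):
        """Semicircular pole cap sampled at the contour step."""
        n_arc = max(int(round(math.pi * half_w / h)), 4)
        phi0 = math.atan2(start_angle_vec[1], start_angle_vec[0])
        phis = phi0 + sweep * np.linspace(0, math.pi, n_arc + 2)[1:-1]
        return center + half_w * np.stack([np.cos(phis), np.sin(phis)], axis=1)

    # traverse: left side (s increasing) -> far cap -> right side (s
    # decreasing) -> near cap; closed polygon, orientation handled by sign
    # conventions downstream
    far_cap = cap(c_side[-1], t_side[-1], normal_left[-1], -1.0)
    near_cap = cap(c_side[0], t_side[0], -normal_left[0], -1.0)
    contour = np.concatenate([left, far_cap, right[::-1], near_cap])
    n_left, n_far, n_right, n_near = len(left), len(far_cap), len(right), len(near_cap)
    side = np.concatenate([np.full(n_left, -1), np.zeros(n_far),
                           np.full(n_right, 1), np.zeros(n_near)]).astype(int)
    arc = np.concatenate([s_side, np.full(n_far, L), s_side[::-1],
                          np.zeros(n_near)])
    pole_mask = side == 0
    kappa_side = _kappa_profile(cfg, np.where(pole_mask, 0.0, arc))
    kappa_true = np.where(pole_mask, 0.0, kappa_side)

    # curvature-neutral bulges / indentations: radial bumps on the side walls
    if cfg.n_bulges > 0 and cfg.bulge_amplitude != 0:
        normals = np.concatenate([normal_left, np.zeros((n_far, 2)),
                                  -normal_left[::-1], np.zeros((n_near, 2))])
        margin = 0.15 * L
        centers = rng.uniform(margin, L - margin, cfg.n_bulges)
        which_side = rng.choice([-1, 1], cfg.n_bulges)
        signs = np.resize([1.0, -1.0], cfg.n_bulges)  # alternate bulge/indent
        width_b = 0.15
        for s0, sd, sg in zip(centers, which_side, signs):
            bump = (sg * cfg.bulge_amplitude
                    * np.exp(-0.5 * ((arc - s0) / width_b) ** 2))
            on = (side == sd) & ~pole_mask
            contour[on] += bump[on, None] * normals[on]

    widths = np.full(len(contour), cfg.width)
    intensity = 1.0 + side * cfg.alpha * kappa_true * widths
    if cfg.intensity_noise > 0:
        intensity = intensity * (1.0 + rng.normal(0.0, cfg.intensity_noise,
                                                  len(intensity)))
    geometry = CellGeometry(contour=contour, centerline=centerline,
                            widths=widths, side=side, arclength=arc,
                            pole_mask=pole_mask, kappa_true=kappa_true,
                            meta={"config": cfg})
    return geometry, intensity
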