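"""Immobile/persistent classification of bound-molecule tracks.

Low-frequency imaging (3.6 s interval) shows bound molecules either sitting
still or moving directionally at Rod-complex speed (~10-40 nm/s).  A
sliding-window speed threshold separates the two locally in time: the
smoothed speed at point t is the displacement across the surrounding w
steps divided by w*tau, and the point is persistent iff that speed strictly
exceeds v_thr (a tie counts as immobile).  The window and threshold are
calibrated on simulated tracks; transition rates come from counting label
changes and dividing by the dwell time in the source state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import TrackSet


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class MSDCurve:
    lags: np.ndarray        # s
    msd: np.ndarray         # um^2
    n_pairs: np.ndarray


@dataclass
class MotionStateSeries:
    """Per-evaluated-point motion-state labels for one track."""

    indices: np.ndarray     # track point indices where the window fits
    persistent: np.ndarray  # bool labels
    speeds: np.ndarray      # smoothed speeds, um/s
    w: int
    v_thr: float
    tau: float


@dataclass
class TransitionRates:
    k_ip: float | None      # 1/s, None when undefined
    k_pi: float | None
    n_ip: int
    n_pi: int
    t_immobile: float       # total dwell time, s
    t_persistent: float
    persistent_fraction: float


# --------------------------------------------------------------------------
# MSD and velocity
# --------------------------------------------------------------------------

def single_track_msd(positions: np.ndarray, tau: float) -> MSDCurve:
    """Time-averaged MSD of one track over all start points per lag."""
    pos = np.asarray(positions, dtype=float)
    if len(pos) < 2:
        raise ValueError("track needs at least 2 points")
    n = len(pos)
    msd = np.empty(n - 1)
    pairs = np.empty(n - 1, dtype=int)
    for m in range(1, n):
        d2 = np.sum((pos[m:] - pos[:-m]) ** 2, axis=1)
        msd[m - 1] = d2.mean()
        pairs[m - 1] = d2.size
    return MSDCurve(lags=np.arange(1, n) * tau, msd=msd, n_pairs=pairs)


def fit_track_velocity(msd: MSDCurve, min_steps: int = 4, max_steps: int = 10):
    """Quadratic MSD fit ``MSD = v^2 t^2 + b`` -> (v, R^2, offset).

    Uses at most ``max_steps`` lags (long tracks would otherwise bias the
    selection towards slow molecules); requires at least ``min_steps``.
    """
    n = len(msd.lags)
    if n < min_steps:
        raise ValueError(f"track too short: {n} steps < {min_steps}")
    use = slice(0, min(n, max_steps))
    t = msd.lags[use]
    y = msd.msd[use]
    design = np.stack([t ** 2, np.ones_like(t)], axis=1)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ coef
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    v = float(np.sqrt(max(coef[0], 0.0)))
    if not np.isfinite(v):
        raise ValueError("non-finite velocity fit")
    return v, r2, float(coef[1])


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def classify_states(positions: np.ndarray, tau: float, w: int = 4,
                    v_thr: float = 0.008) -> MotionStateSeries:
    """Label each evaluable track point immobile or persistent.

    Smoothed speed at point i: |r[i + w/2] - r[i - w/2]| / (w tau); points
    within w/2 steps of either track end are not evaluated.  Persistent
    requires speed strictly above the threshold.
    """
    pos = np.asarray(positions, dtype=float)
    half = w // 2
    n = len(pos)
    if n < w + 1:
        return MotionStateSeries(np.empty(0, int), np.empty(0, bool),
                                 np.empty(0), w, v_thr, tau)
    idx = np.arange(half, n - half)
    disp = pos[idx + half] - pos[idx - half]
    speeds = np.hypot(disp[:, 0], disp[:, 1]) / (w * tau)
    return MotionStateSeries(idx, speeds > v_thr, speeds, w, v_thr, tau)


def classify_trackset(tracks: TrackSet, w: int = 4, v_thr: float = 0.008):
    """Classify every track; returns a list of MotionStateSeries."""
    return [classify_states(pos, tracks.tau, w=w, v_thr=v_thr)
            for pos in tracks.iter_positions()]


def classification_accuracy(tracks: TrackSet, expect_persistent: bool,
                            w: int = 4, v_thr: float = 0.008) -> float:
    """Fraction of evaluated points labeled as the expected class."""
    good = total = 0
    for _, sub in tracks.iter_tracks():
        series = classify_states(sub[["x", "y"]].to_numpy(), tracks.tau,
                                 w=w, v_thr=v_thr)
        total += len(series.persistent)
        good += int(np.sum(series.persistent == expect_persistent))
    if total == 0:
        raise ValueError("no evaluable points (all tracks shorter than w + 1)")
    return good / total


@dataclass
class CalibrationResult:
    table: pd.DataFrame                 # w, v_thr, acc_immobile, acc_persistent
    qualifying: list = field(default_factory=list)
    selected: tuple | None = None


def calibrate_classifier(cfg, w_grid, vthr_grid, target: float = 0.99,
                         n_tracks: int | None = None) -> CalibrationResult:
    """Grid-search (w, v_thr) on simulated immobile and persistent tracks.

    ``cfg`` is a :class:`rodspt.simulate.MotionSimConfig` holding the
    simulation conditions (speed, noise, interval, length distribution);
    pure-immobile and pure-persistent track sets are generated from it.
    Returns the per-combination accuracy table, the combinations reaching
    ``target`` on both classes, and the qualifying combination with the
    highest worst-class accuracy (ties broken towards small w, then small
    v_thr).
    """
    from dataclasses import replace

    from .simulate import simulate_bound_motion_tracks

    if len(w_grid) == 0 or len(vthr_grid) == 0:
        raise ValueError("empty calibration grid")
    n = n_tracks or cfg.n_tracks
    imm = simulate_bound_motion_tracks(replace(
        cfg, n_tracks=n, k_ip=0.0, k_pi=0.0, initial_state="immobile",
        seed=cfg.seed))
    per = simulate_bound_motion_tracks(replace(
        cfg, n_tracks=n, k_ip=0.0, k_pi=0.0, initial_state="persistent",
        direction="x", seed=cfg.seed + 1))
    rows = []
    for w in w_grid:
        for v_thr in vthr_grid:
            rows.append({
                "w": int(w), "v_thr": float(v_thr),
                "acc_immobile": classification_accuracy(imm, False, w, v_thr),
                "acc_persistent": classification_accuracy(per, True, w, v_thr),
            })
    table = pd.DataFrame(rows)
    ok = table[(table.acc_immobile >= target) & (table.acc_persistent >= target)]
    qualifying = [(int(r.w), float(r.v_thr)) for r in ok.itertuples()]
    if qualifying:
        ok = ok.assign(worst=np.minimum(ok.acc_immobile, ok.acc_persistent))
        ok = ok.sort_values(["worst", "w", "v_thr"],
                            ascending=[False, True, True])
        selected = (int(ok.iloc[0].w), float(ok.iloc[0].v_thr))
    else:
        best = table.assign(worst=np.minimum(table.acc_immobile,
                                             table.acc_persistent))
        row = best.sort_values("worst", ascending=False).iloc[0]
        selected = (int(row.w), float(row.v_thr))
    return CalibrationResult(table=table, qualifying=qualifying,
                             selected=selected)


# --------------------------------------------------------------------------
# transition rates
# --------------------------------------------------------------------------

def merge_single_step_segments(labels: np.ndarray) -> np.ndarray:
    """Absorb interior single-point runs into their flanking state."""
    labels = np.asarray(labels, dtype=bool).copy()
    n = len(labels)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        if j == i and 0 < i and j < n - 1:   # interior run of length 1
            labels[i] = labels[i - 1]
        i = j + 1
    return labels


def estimate_transition_rates(series_list, tau: float) -> TransitionRates:
    """Count immobile<->persistent transitions and divide by dwell times.

    Interior single-point segments are merged into the flanking state
    before counting.  Dwell time accrues per evaluated step (pairs of
    consecutive evaluated points); a state with zero dwell time has an
    undefined rate (None).
    """
    n_ip = n_pi = 0
    t_imm = t_per = 0.0
    pts_per = pts_total = 0
    for series in series_list:
        labels = series.persistent
        if len(labels) == 0:
            continue
        labels = merge_single_step_segments(labels)
        pts_per += int(labels.sum())
        pts_total += len(labels)
        for a, b in zip(labels[:-1], labels[1:]):
            if a:
                t_per += tau
            else:
                t_imm += tau
            if a != b:
                if a:
                    n_pi += 1
                else:
                    n_ip += 1
    k_ip = n_ip / t_imm if t_imm > 0 else None
    k_pi = n_pi / t_per if t_per > 0 else None
    frac = pts_per / pts_total if pts_total else float("nan")
    return TransitionRates(k_ip=k_ip, k_pi=k_pi, n_ip=n_ip, n_pi=n_pi,
                          t_immobile=t_imm, t_persistent=t_per,
                          persistent_fraction=frac)


# --------------------------------------------------------------------------
# orientation
# --------------------------------------------------------------------------

def orientation_distribution(position_list, cell_axis) -> np.ndarray:
    """Angles (degrees, 0..90) between track end-to-end vectors and the cell axis."""
    axis = np.asarray(cell_axis, dtype=float)
    norm = np.hypot(*axis)
    if norm == 0:
        raise ValueError("cell axis must be a nonzero vector")
    axis = axis / norm
    angles = []
    for pos in position_list:
        pos = np.asarray(pos, dtype=float)
        u = pos[-1] - pos[0]
        lu = np.hypot(*u)
        if lu == 0:
            continue
        cosang = abs(float(u @ axis)) / lu
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return np.asarray(angles)
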