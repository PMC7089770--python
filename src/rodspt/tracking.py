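"""Spot detection, nearest-neighbour linking, and localization accuracy.

Detection: local maxima of a bandpass (difference-of-Gaussians) filtered
image above a noise-scaled threshold are refined by 2D Gaussian fits and
quality-filtered.  Linking: conservative nearest-neighbour — a trajectory
is discontinued as soon as more than one candidate lies within the linking
radius (no gap closing, no multi-hypothesis tracking).  The localization
accuracy sigma is estimated from per-axis displacements of immobile tracks.

Image dialect: single-channel arrays ``image[row, col]`` with origin at the
top-left, x = column, pixel centers at integer (0-based) coordinates;
pixel size 65 nm by default.  Track math is in micrometres.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from .tracks import TrackSet, tracks_from_arrays

PIXEL_SIZE_UM = 0.065


@dataclass
class Localization:
    frame: int
    x: float                  # um
    y: float                  # um
    intensity: float          # fitted amplitude, a.u.
    fit_sd: float             # Gaussian-fit s.d., pixels
    fit_residual_ratio: float  # mean |residual| / peak intensity

    def __post_init__(self) -> None:
        if self.frame < 0 or self.fit_sd < 0:
            raise ValueError("frame and fit_sd must be non-negative")


def _gaussian2d(params, xx, yy):
    amp, x0, y0, sd, off = params
    return off + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sd ** 2))


def _fit_gaussian_spot(image, row, col, radius=3):
    """Refine one candidate peak with a 2D Gaussian fit on a local window.

    Returns (x_px, y_px, amplitude, sd_px, residual_ratio) or None when the
    fit fails.
    """
    r0, r1 = max(row - radius, 0), min(row + radius + 1, image.shape[0])
    c0, c1 = max(col - radius, 0), min(col + radius + 1, image.shape[1])
    win = image[r0:r1, c0:c1].astype(float)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    off0 = float(win.min())
    amp0 = float(win.max() - off0)
    if amp0 <= 0:
        return None
    p0 = np.array([amp0, col, row, 1.2, off0])

    def resid(p):
        return (_gaussian2d(p, xx, yy) - win).ravel()

    try:
        res = optimize.least_squares(
            resid, p0,
            bounds=([0, c0 - 1, r0 - 1, 0.3, -np.inf],
                    [np.inf, c1, r1, 10.0, np.inf]))
    except Exception:
        return None
    amp, x0, y0, sd, _ = res.x
    if amp <= 0:
        return None
    residual_ratio = float(np.mean(np.abs(res.fun)) / amp)
    return float(x0), float(y0), float(amp), float(sd), residual_ratio


def detect_spots(image, band_low: float = 1.0, band_high: float = 5.0,
                 intensity_factor: float = 3.5, max_fit_sd: float = 3.0,
                 max_residual_ratio: float = 0.2,
                 min_neighbor_dist: float = 3.5,
                 snr_min: float | None = None,
                 drop_brightest_frac: float = 0.0,
                 pixel_size: float = PIXEL_SIZE_UM,
                 frame: int = 0) -> list[Localization]:
    """Detect and localize fluorescent spots in one image.

    Candidates are local maxima of the difference-of-Gaussians filtered
    image exceeding ``intensity_factor`` times the robust background noise
    (MAD-based).  Each candidate is refined by a 2D Gaussian fit; peaks with
    fit s.d. above ``max_fit_sd`` pixels or residual ratio above
    ``max_residual_ratio`` are removed, as are peaks closer than
    ``min_neighbor_dist`` pixels to another peak.  Optional filters: peak
    signal-to-local-noise above ``snr_min`` and removal of the brightest
    ``drop_brightest_frac`` of peaks (likely molecule clusters).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    band = (ndimage.gaussian_filter(img, band_low)
            - ndimage.gaussian_filter(img, band_high))
    noise = 1.4826 * np.median(np.abs(band - np.median(band)))
    threshold = max(intensity_factor * noise, 1e-12)
    coords = peak_local_max(band, min_distance=2, threshold_abs=threshold,
                            exclude_border=max(int(round(band_high)), 1))
    spots = []
    for row, col in coords:
        fit = _fit_gaussian_spot(img, row, col)
        if fit is None:
            continue
        x_px, y_px, amp, sd, rr = fit
        if sd > max_fit_sd or rr > max_residual_ratio:
            continue
        if snr_min is not None:
            rows, cols = np.ogrid[:img.shape[0], :img.shape[1]]
            dist = np.hypot(rows - y_px, cols - x_px)
            ring = img[(dist >= 3) & (dist <= 4)]
            if ring.size and ring.std() > 0 and amp / ring.std() <= snr_min:
                continue
        spots.append(Localization(frame=frame, x=x_px * pixel_size,
                                  y=y_px * pixel_size, intensity=amp,
                                  fit_sd=sd, fit_residual_ratio=rr))
    # nearest-neighbour exclusion (in pixels)
    if len(spots) > 1 and min_neighbor_dist > 0:
        pts = np.array([[s.x, s.y] for s in spots]) / pixel_size
        d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                     pts[:, None, 1] - pts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        spots = [s for s, dmin in zip(spots, d.min(axis=1))
                 if dmin > min_neighbor_dist]
    if drop_brightest_frac > 0 and spots:
        cut = np.quantile([s.intensity for s in spots], 1 - drop_brightest_frac)
        spots = [s for s in spots if s.intensity < cut]
    return spots


def detect_spots_stack(stack, **kwargs) -> list[Localization]:
    """Detect spots frame by frame in an image stack.

    ``stack`` may be a (T, H, W) array or the path of a single-channel TIFF
    stack (16-bit, origin top-left, x = column).
    """
    if isinstance(stack, (str, os.PathLike)):
        stack = tifffile.imread(stack)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("expected a (T, H, W) single-channel stack")
    out = []
    for frame, img in enumerate(stack):
        out.extend(detect_spots(img, frame=frame, **kwargs))
    return out


# --------------------------------------------------------------------------
# linking
# --------------------------------------------------------------------------

def link_localizations(locs, tau: float, max_disp: float = 0.600) -> TrackSet:
    """Nearest-neighbour linking with ambiguity termination.

    ``locs``: either a list of :class:`Localization` or an (n, 3) array-like
    of ``(frame, x, y)``.  A localization links to the single candidate in
    the next frame within ``max_disp`` (um); a track is discontinued when
    more than one candidate is in range, and symmetrically when a candidate
    is claimed by more than one track.  Unclaimed localizations start new
    tracks.  Default thresholds by interval: 0.600 um (60 ms), 0.1125 um
    (1 s), 0.225 um (3.6 s).
    """
    if len(locs) and isinstance(locs[0], Localization):
        table = np.array([[l.frame, l.x, l.y] for l in locs], dtype=float)
    else:
        table = np.asarray(locs, dtype=float)
    if table.ndim != 2 or table.shape[1] < 3:
        raise ValueError("expected (frame, x, y) rows")
    frames = table[:, 0].astype(int)
    order = np.argsort(frames, kind="stable")
    table, frames = table[order], frames[order]

    by_frame = {f: table[frames == f, 1:3] for f in np.unique(frames)}
    all_frames = sorted(by_frame)
    open_tracks = {}      # track_id -> list of (frame, x, y)
    closed = []
    next_id = 0
    prev_frame = None
    for f in all_frames:
        pts = by_frame[f]
        if prev_frame is not None and f == prev_frame + 1 and open_tracks:
            tids = list(open_tracks)
            ends = np.array([open_tracks[t][-1][1:] for t in tids])
            d = np.hypot(ends[:, None, 0] - pts[None, :, 0],
                         ends[:, None, 1] - pts[None, :, 1])
            in_range = d <= max_disp
            cand_count = in_range.sum(axis=1)          # per track
            claim_count = in_range.sum(axis=0)         # per localization
            used = np.zeros(len(pts), dtype=bool)
            for i, tid in enumerate(tids):
                if cand_count[i] != 1:
                    closed.append(open_tracks.pop(tid))
                    continue
                j = int(np.argmax(in_range[i]))
                if claim_count[j] != 1:
                    closed.append(open_tracks.pop(tid))
                    continue
                open_tracks[tid].append((f, pts[j, 0], pts[j, 1]))
                used[j] = True
            new_pts = pts[~used]
        else:
            closed.extend(open_tracks.values())
            open_tracks = {}
            new_pts = pts
        for p in new_pts:
            open_tracks[next_id] = [(f, p[0], p[1])]
            next_id += 1
        prev_frame = f
    closed.extend(open_tracks.values())

    positions, starts = [], []
    for trk in closed:
        arr = np.asarray(trk, dtype=float)
        positions.append(arr[:, 1:3])
        starts.append(int(arr[0, 0]))
    ts = tracks_from_arrays(positions, tau, start_frames=starts,
                            meta={"max_disp": max_disp})
    return ts


# --------------------------------------------------------------------------
# localization accuracy
# --------------------------------------------------------------------------

def estimate_localization_accuracy(tracks: TrackSet,
                                   max_end_to_end: float = 0.200,
                                   min_steps: int = 7,
                                   min_tracks: int = 20) -> float:
    """Localization accuracy sigma (um) from immobile tracks.

    Immobile rule: end-to-end distance below ``max_end_to_end`` for tracks
    of at least ``min_steps`` steps.  Pooled per-axis displacements of those
    tracks have s.d. sigma_d = sqrt(2) sigma, so sigma = sigma_d / sqrt(2).
    """
    disps = []
    n_immobile = 0
    for pos in tracks.iter_positions(min_length=min_steps + 1):
        if np.hypot(*(pos[-1] - pos[0])) < max_end_to_end:
            n_immobile += 1
            disps.append((pos[1:] - pos[:-1]).ravel())
    if n_immobile < min_tracks:
        raise ValueError(f"only {n_immobile} immobile tracks "
                         f"(need >= {min_tracks})")
    sigma_d = float(np.concatenate(disps).std(ddof=1))
    return sigma_d / np.sqrt(2.0)
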