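"""Trajectory container shared by every analysis stage.

A :class:`TrackSet` wraps a tidy :class:`pandas.DataFrame` of localizations
(one row per frame per molecule) together with the acquisition interval
``tau``.  All positions are in micrometres, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

#: canonical column order for track tables
TRACK_COLUMNS = ["track_id", "frame", "t", "x", "y"]


@dataclass
class TrackSet:
    """A collection of single-molecule trajectories.

    Parameters
    ----------
    data:
        DataFrame with columns ``track_id, frame, t, x, y`` and optionally
        ``true_state`` (ground-truth label from a simulator) and ``cell_id``.
    tau:
        Frame interval in seconds.
    meta:
        Free-form acquisition / simulation metadata (seeds, parameters).
    """

    data: pd.DataFrame
    tau: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def __len__(self) -> int:
        return self.n_tracks

    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    def positions(self, track_id) -> np.ndarray:
        """(n, 2) array of x, y for one track, ordered by frame."""
        sub = self.data[self.data["track_id"] == track_id].sort_values("frame")
        return sub[["x", "y"]].to_numpy()

    def iter_tracks(self) -> Iterator[tuple[object, pd.DataFrame]]:
        """Yield ``(track_id, frame-sorted sub-table)`` pairs."""
        for tid, sub in self.data.groupby("track_id", sort=True):
            yield tid, sub.sort_values("frame")

    def iter_positions(self, min_length: int = 1) -> Iterator[np.ndarray]:
        """Yield per-track (n, 2) position arrays with at least ``min_length`` points."""
        for _, sub in self.iter_tracks():
            if len(sub) >= min_length:
                yield sub[["x", "y"]].to_numpy()

    def select_min_length(self, min_points: int) -> "TrackSet":
        """Keep only tracks with at least ``min_points`` localizations."""
        counts = self.data.groupby("track_id")["frame"].size()
        keep = counts.index[counts >= min_points]
        sub = self.data[self.data["track_id"].isin(keep)].reset_index(drop=True)
        return TrackSet(sub, self.tau, dict(self.meta))

    # ------------------------------------------------------------------ IO
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, tau: float) -> "TrackSet":
        return cls(pd.read_csv(path), tau)


def tracks_from_arrays(positions: list[np.ndarray], tau: float,
                       start_frames=None, true_states=None,
                       meta: dict | None = None) -> TrackSet:
    """Build a :class:`TrackSet` from a list of per-track (n, 2) arrays.

    ``true_states`` may be a per-track scalar label or a per-track array of
    per-point labels.
    """
    rows = []
    n = len(positions)
    if start_frames is None:
        start_frames = [0] * n
    for tid, pos in enumerate(positions):
        pos = np.asarray(pos, dtype=float)
        frames = start_frames[tid] + np.arange(len(pos))
        df = pd.DataFrame({
            "track_id": tid,
            "frame": frames,
            "t": frames * tau,
            "x": pos[:, 0],
            "y": pos[:, 1],
        })
        if true_states is not None:
            df["true_state"] = true_states[tid]
        rows.append(df)
    data = (pd.concat(rows, ignore_index=True) if rows
            else pd.DataFrame(columns=TRACK_COLUMNS))
    return TrackSet(data, tau, meta or {})
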