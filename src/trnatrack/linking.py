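"""Frame-to-frame trajectory linking with a fixed displacement window.

Localizations in consecutive frames are linked if they fall within
``max_link_distance`` (7 px ~ 0.67 um by default) of an active track head;
assignment per frame pair is the optimal bipartite matching minimizing total
squared displacement. A track missing a localization survives
``memory_frames`` frames (default 1, absorbing one-frame blinking) before it
terminates; displacements bridged across a gap of g frames must satisfy an
enlarged window ``max_link_distance * gap_window_scale**g``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import TrackingConfig


@dataclass
class Trajectory:
    """One linked trajectory: time-ordered localizations with <=1-frame gaps."""

    traj_id: int
    frames: np.ndarray       # strictly increasing frame indices
    xy: np.ndarray           # (n, 2) um
    loc_index: np.ndarray    # row indices into the input table
    gap_after: np.ndarray    # True where the next link bridges a skipped frame
    cell_id: int | None = None

    def __len__(self) -> int:
        return len(self.frames)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "traj_id": self.traj_id, "frame": self.frames,
            "x_um": self.xy[:, 0], "y_um": self.xy[:, 1],
            "gap_flag": self.gap_after,
            "cell_id": self.cell_id if self.cell_id is not None else -1,
        })


def trajectories_to_table(trajectories: list[Trajectory]) -> pd.DataFrame:
    if not trajectories:
        return pd.DataFrame(columns=["traj_id", "frame", "x_um", "y_um",
                                     "gap_flag", "cell_id"])
    return pd.concat([t.to_frame() for t in trajectories], ignore_index=True)


def link(localizations: pd.DataFrame,
         config: TrackingConfig | None = None) -> list[Trajectory]:
    """Link a localization table (columns frame, x_um, y_um) into trajectories.

    Deterministic: the per-frame-pair assignment is the optimal (minimum
    total squared displacement) matching among pairs within the window, with
    cost ties broken by input order; the output is invariant to permutations
    of rows within a frame. Every localization ends up in exactly one
    trajectory (singletons included).
    """
    config = config or TrackingConfig()
    if len(localizations) == 0:
        return []
    loc = localizations.reset_index(drop=True)
    order = np.lexsort((np.arange(len(loc)), loc["frame"].to_numpy()))
    frames = loc["frame"].to_numpy()[order].astype(int)
    xy = loc[["x_um", "y_um"]].to_numpy()[order]
    orig_idx = np.arange(len(loc))[order]
    has_cell = "cell_id" in loc.columns
    cell_ids = loc["cell_id"].to_numpy()[order] if has_cell else None

    # active track state: list of dicts with head position/frame
    tracks: list[dict] = []
    active: list[int] = []
    BIG = 1e18

    for f in np.unique(frames):
        sel = np.nonzero(frames == f)[0]
        pts = xy[sel]
        # retire tracks whose head is too old
        still = []
        for ti in active:
            if f - tracks[ti]["last_frame"] <= config.memory_frames + 1:
                still.append(ti)
        active = still
        assigned_pts = np.zeros(len(sel), dtype=bool)
        if active and len(sel):
            heads = np.array([tracks[ti]["head"] for ti in active])
            lags = np.array([f - tracks[ti]["last_frame"] for ti in active])
            windows = config.max_link_distance * config.gap_window_scale ** (lags - 1)
            d2 = ((heads[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= windows[:, None] ** 2, d2, BIG)
            rows, cols = linear_sum_assignment(cost)
            for ri, ci in zip(rows, cols):
                if cost[ri, ci] >= BIG:
                    continue
                ti = active[ri]
                gap = f - tracks[ti]["last_frame"] > 1
                tracks[ti]["frames"].append(f)
                tracks[ti]["pts"].append(pts[ci])
                tracks[ti]["idx"].append(orig_idx[sel[ci]])
                tracks[ti]["gaps"].append(gap)
                tracks[ti]["head"] = pts[ci]
                tracks[ti]["last_frame"] = f
                assigned_pts[ci] = True
        # unmatched localizations start new tracks
        for ci in np.nonzero(~assigned_pts)[0]:
            tracks.append({
                "frames": [f], "pts": [pts[ci]], "idx": [orig_idx[sel[ci]]],
                "gaps": [], "head": pts[ci], "last_frame": f,
                "cell_id": int(cell_ids[sel[ci]]) if has_cell else None,
            })
            active.append(len(tracks) - 1)

    out = []
    for tid, t in enumerate(tracks):
        # t["gaps"][i] says whether the link frames[i] -> frames[i+1] bridged
        # a skipped frame; pad with False for the final position
        gaps = np.zeros(len(t["frames"]), dtype=bool)
        gaps[:len(t["gaps"])] = t["gaps"]
        out.append(Trajectory(
            traj_id=tid, frames=np.array(t["frames"], dtype=int),
            xy=np.array(t["pts"]), loc_index=np.array(t["idx"], dtype=int),
            gap_after=gaps, cell_id=t["cell_id"]))
    return out


def link_correctness(D_app: float, dt: float, s_axis: float,
                     window: float) -> float:
    """Probability that a single-species 2D step falls inside the window.

    The measured displacement of a species with apparent diffusion
    coefficient ``D_app`` over one frame has independent per-axis variance
    ``2 D_app dt + 2 s_axis^2`` (diffusion plus localization error at both
    ends); its magnitude is Rayleigh, so

        P(|step| <= w) = 1 - exp(-w^2 / (4 D_app dt + 4 s_axis^2)).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if D_app < 0 or dt < 0 or s_axis < 0:
        raise ValueError("arguments must be >= 0")
    var2 = 4.0 * D_app * dt + 4.0 * s_axis ** 2
    if var2 == 0:
        return 1.0
    return 1.0 - float(np.exp(-window ** 2 / var2))
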