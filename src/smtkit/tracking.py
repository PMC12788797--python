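"""Localization linking and trajectory quality filters.

Tables are pandas DataFrames throughout. A localization table has
columns ``frame, x, y`` (µm) plus optional ``trajectory, cell_id,
day_id``; a jump table has one row per consecutive-frame displacement
with columns ``r_um, dt_s, trajectory, cell_id, day_id``.

The filter chain applied to raw tracking output is:

1. keep only trajectories lying entirely within one and only one
   nuclear mask (:func:`assign_to_masks`);
2. per cell, truncate frames from the start of the movie until every
   remaining frame has at most ``max_per_frame`` localizations
   (:func:`truncate_dense_frames`);
3. drop cells with fewer than 100 displacements
   (:func:`filter_min_displacements`).

The chain is idempotent: applying it twice changes nothing.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "link_localizations",
    "assign_to_masks",
    "truncate_dense_frames",
    "filter_min_displacements",
    "compute_jumps",
    "filter_chain",
]

PIXEL_SIZE_UM = 0.16  # rasterization scale for polygon masks


def link_localizations(locs: pd.DataFrame, search_radius_um: float = 1.0,
                       max_blinks: int = 0) -> pd.DataFrame:
    """Greedy nearest-neighbor linking of localizations into trajectories.

    Localizations in consecutive frames closer than ``search_radius_um``
    are linked; ties are resolved by lowest localization index. With
    ``max_blinks = 0`` a single missed frame terminates the trajectory.
    This is a simplified tracker intended for synthetic data, not a
    replacement for production spot trackers.
    """
    if search_radius_um < 0:
        raise ValueError("search radius must be >= 0")
    if max_blinks != 0:
        raise NotImplementedError("only max_blinks = 0 is supported")
    out = locs.sort_values("frame", kind="stable").reset_index(drop=True)
    n = len(out)
    traj = np.full(n, -1, dtype=int)
    next_id = 0
    frames = out["frame"].to_numpy()
    xy = out[["x", "y"]].to_numpy(dtype=float)
    # group row indices by frame
    by_frame: dict[int, np.ndarray] = {
        f: idx.to_numpy() for f, idx in out.groupby("frame").groups.items()
    }
    for f in sorted(by_frame):
        cur = by_frame[f]
        prev = by_frame.get(f - 1)
        claimed: set[int] = set()
        if prev is not None and len(prev) > 0:
            # deterministic order: lowest current row index links first,
            # and distance ties resolve to the lowest previous row index
            for i in cur:
                dists = np.hypot(*(xy[prev] - xy[i]).T)
                for rk in np.lexsort((prev, dists)):
                    if dists[rk] > search_radius_um:
                        break
                    j = prev[rk]
                    if j in claimed:
                        continue
                    traj[i] = traj[j]
                    claimed.add(j)
                    break
        for i in cur:
            if traj[i] < 0:
                traj[i] = next_id
                next_id += 1
    out["trajectory"] = traj
    return out


def assign_to_masks(locs: pd.DataFrame, masks: np.ndarray,
                    pixel_size_um: float = PIXEL_SIZE_UM) -> pd.DataFrame:
    """Keep trajectories lying entirely within exactly one labeled mask.

    ``masks`` is a labeled integer image (0 = background); a trajectory
    with any point on background, or with points in two different
    labels, is dropped. Survivors get ``cell_id`` set to the mask label.
    Coordinates are µm; the mask is indexed at ``pixel_size_um``/px as
    ``masks[row, col] = masks[y, x]``.
    """
    masks = np.asarray(masks)
    if masks.ndim != 2:
        raise ValueError("masks must be a 2-D labeled image")
    out = locs.copy()
    col = (out["x"].to_numpy(dtype=float) / pixel_size_um).astype(int)
    row = (out["y"].to_numpy(dtype=float) / pixel_size_um).astype(int)
    inside = ((row >= 0) & (row < masks.shape[0])
              & (col >= 0) & (col < masks.shape[1]))
    label = np.zeros(len(out), dtype=masks.dtype)
    label[inside] = masks[row[inside], col[inside]]
    out["_label"] = label
    keys = ["cell_id", "trajectory"] if "cell_id" in out.columns else ["trajectory"]
    per_traj = out.groupby(keys)["_label"].agg(["min", "max"])
    good = per_traj[(per_traj["min"] == per_traj["max"]) & (per_traj["min"] > 0)]
    kept = out.set_index(keys).loc[good.index].reset_index()
    n_dropped = per_traj.shape[0] - good.shape[0]
    if n_dropped:
        logger.info("assign_to_masks: dropped %d trajectories outside or "
                    "straddling masks", n_dropped)
    kept["cell_id"] = kept["_label"].astype(int)
    return kept.drop(columns="_label").reset_index(drop=True)


def truncate_dense_frames(cell_locs: pd.DataFrame,
                          max_per_frame: int = 6) -> pd.DataFrame:
    """Drop a prefix of frames so no remaining frame is over-dense.

    Removes the smallest prefix of frames such that every remaining
    frame holds at most ``max_per_frame`` localizations ("fewer than
    seven"). Truncation is strictly from the beginning of the movie —
    a dense frame late in the movie forces removal of everything before
    and including it. Trajectories losing points are re-split at the
    cut by virtue of the frame gap (handled in :func:`compute_jumps`,
    which never bridges missing frames).
    """
    if len(cell_locs) == 0:
        return cell_locs.copy()
    counts = cell_locs.groupby("frame").size()
    dense = counts[counts > max_per_frame]
    if len(dense) == 0:
        return cell_locs.copy()
    cutoff = dense.index.max()  # all frames <= last dense frame go
    out = cell_locs[cell_locs["frame"] > cutoff].copy()
    return out.reset_index(drop=True)


def filter_min_displacements(locs: pd.DataFrame,
                             min_disp: int = 100) -> pd.DataFrame:
    """Drop cells with fewer than ``min_disp`` displacements.

    Displacements are counted on consecutive-frame pairs after the mask
    and truncation filters; cells with a count strictly below the
    threshold are removed and logged.
    """
    if len(locs) == 0:
        return locs.copy()
    jumps = compute_jumps(locs)
    counts = jumps.groupby("cell_id").size() if len(jumps) else pd.Series(dtype=int)
    keep = set(counts[counts >= min_disp].index)
    removed = sorted(set(locs["cell_id"]) - keep)
    if removed:
        logger.info("filter_min_displacements: removed cells %s "
                    "(< %d displacements)", removed, min_disp)
    return locs[locs["cell_id"].isin(keep)].reset_index(drop=True)


def compute_jumps(locs: pd.DataFrame,
                  frame_interval: float = 0.00748) -> pd.DataFrame:
    """Single-lag jump table from a trajectory table.

    One row per consecutive-frame pair within a trajectory;
    ``r_um`` is the Euclidean 2-D displacement. Frame gaps (e.g. from
    dense-frame truncation) never produce a jump.
    """
    cols = ["r_um", "dt_s", "trajectory", "cell_id", "day_id"]
    if len(locs) == 0:
        return pd.DataFrame({c: pd.Series(dtype=float if c in ("r_um", "dt_s")
                                          else int) for c in cols})
    keys = [k for k in ("cell_id", "trajectory") if k in locs.columns]
    df = locs.sort_values(keys + ["frame"], kind="stable")
    same_traj = (df[keys].shift() == df[keys]).all(axis=1)
    consecutive = df["frame"].diff() == 1
    ok = (same_traj & consecutive).to_numpy()
    dx = df["x"].diff().to_numpy()
    dy = df["y"].diff().to_numpy()
    r = np.hypot(dx, dy)[ok]
    out = pd.DataFrame({
        "r_um": r,
        "dt_s": frame_interval,
        "trajectory": df["trajectory"].to_numpy()[ok],
        "cell_id": (df["cell_id"].to_numpy()[ok] if "cell_id" in df.columns
                    else 0),
        "day_id": (df["day_id"].to_numpy()[ok] if "day_id" in df.columns
                   else 0),
    })
    return out.reset_index(drop=True)


def filter_chain(locs: pd.DataFrame, masks: np.ndarray | None = None,
                 max_per_frame: int = 6, min_disp: int = 100,
                 pixel_size_um: float = PIXEL_SIZE_UM) -> pd.DataFrame:
    """Full QC chain: mask assignment → dense-frame truncation → 100-jump filter."""
    out = locs
    if masks is not None:
        out = assign_to_masks(out, masks, pixel_size_um=pixel_size_um)
    if "cell_id" in out.columns and len(out):
        parts = [truncate_dense_frames(g, max_per_frame=max_per_frame)
                 for _, g in out.groupby("cell_id", sort=False)]
        out = pd.concat(parts, ignore_index=True) if parts else out
    else:
        out = truncate_dense_frames(out, max_per_frame=max_per_frame)
    out = filter_min_displacements(out, min_disp=min_disp)
    return out.reset_index(drop=True)
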