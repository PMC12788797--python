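"""Proximity-assisted photoactivation (PAPA) quantification.

A PAPA acquisition interleaves unsaved shelving/reactivation pulses
with saved stroboscopic readout blocks. Per cycle, four 30-frame blocks
are saved, in order:

1. ``spont1``        — spontaneous reactivation baseline;
2. ``violet_readout`` — molecules reactivated by the preceding violet
   pulse (direct reactivation, proximity-independent);
3. ``spont2``        — second spontaneous baseline;
4. ``papa_readout``  — molecules reactivated by the preceding green
   pulse (proximity-dependent).

The cycle repeats five times (600 saved frames by default). The
corrected green-to-violet ratio of a cell,

    (n_green − n_spont2) / (n_violet − n_spont1),

cancels expression-dependent spontaneous reactivation; dividing by the
aggregate corrected ratio of a same-day non-interacting control yields
the normalized PAPA ratio, whose expectation is 1 in the absence of
interaction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseMap",
    "PapaRatioResult",
    "build_phase_map",
    "count_reactivations",
    "corrected_gv_ratio",
    "normalize_to_control",
    "papa_bootstrap",
    "segregate_papa_trajectories",
]

DEFAULT_BLOCKS = ("spont1", "violet_readout", "spont2", "papa_readout")


@dataclass(frozen=True)
class PhaseMap:
    """Saved-frame index → (phase label, cycle index)."""

    labels: np.ndarray  # str per saved frame
    cycles: np.ndarray  # int per saved frame
    frames_per_block: int
    blocks: tuple[str, ...]
    n_cycles: int

    def phase_of(self, frame: int) -> tuple[str, int]:
        if not 0 <= frame < len(self.labels):
            raise IndexError(f"saved-frame index {frame} outside the "
                             f"{len(self.labels)}-frame acquisition")
        return str(self.labels[frame]), int(self.cycles[frame])


@dataclass
class PapaRatioResult:
    """Per-cell and condition-level normalized PAPA ratios."""

    per_cell: pd.DataFrame  # cell_id, day_id, corrected_gv, normalized
    point_estimate: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    trial_values: np.ndarray = field(default_factory=lambda: np.array([]))
    n_missing_trials: int = 0


def build_phase_map(frames_per_block: int = 30,
                    blocks: tuple[str, ...] = DEFAULT_BLOCKS,
                    cycles: int = 5) -> PhaseMap:
    """Phase map for the saved frames of the PAPA illumination sequence.

    Only readout frames are saved, so the map covers
    ``frames_per_block × len(blocks) × cycles`` saved frames (600 by
    default); the unsaved shelving and reactivation-pulse phases never
    appear in saved data.
    """
    labels = np.array([b for _ in range(cycles) for b in blocks
                       for _ in range(frames_per_block)])
    cyc = np.repeat(np.arange(cycles), frames_per_block * len(blocks))
    return PhaseMap(labels=labels, cycles=cyc,
                    frames_per_block=frames_per_block,
                    blocks=tuple(blocks), n_cycles=cycles)


def count_reactivations(trajs: pd.DataFrame, phase_map: PhaseMap,
                        by_localization: bool = False) -> pd.DataFrame:
    """Tally reactivated molecules per phase per cell.

    A molecule (trajectory) is tallied to the phase containing its
    first localization, summed over cycles; a trajectory spanning a
    phase boundary still counts once, in its first phase (logged).
    With ``by_localization=True`` every localization is tallied to its
    own frame's phase instead.
    """
    cols = {b: f"n_{_short(b)}" for b in phase_map.blocks}
    cells = (sorted(trajs["cell_id"].unique()) if len(trajs) else [])
    if by_localization:
        per = trajs.copy()
        per["_phase"] = [phase_map.phase_of(int(f))[0] for f in per["frame"]]
    else:
        keys = ["cell_id", "trajectory"]
        firsts = (trajs.sort_values("frame", kind="stable")
                  .groupby(keys, as_index=False).first()) if len(trajs) else trajs
        if len(trajs):
            lasts = trajs.groupby(keys)["frame"].max().to_numpy()
            first_f = firsts["frame"].to_numpy()
            block = phase_map.frames_per_block
            spanning = (first_f // block) != (lasts // block)
            if spanning.any():
                logger.info("count_reactivations: %d trajectories span a "
                            "phase boundary; counted at first frame",
                            int(spanning.sum()))
        per = firsts
        if len(per):
            per = per.copy()
            per["_phase"] = [phase_map.phase_of(int(f))[0] for f in per["frame"]]
    out_rows = []
    for cell in cells:
        sub = per[per["cell_id"] == cell]
        day = sub["day_id"].iloc[0] if "day_id" in sub.columns and len(sub) else 0
        row = {"cell_id": cell, "day_id": day}
        for b, col in cols.items():
            row[col] = int((sub["_phase"] == b).sum())
        out_rows.append(row)
    columns = ["cell_id", "day_id"] + list(cols.values())
    return pd.DataFrame(out_rows, columns=columns)


def _short(block: str) -> str:
    return {"violet_readout": "violet", "papa_readout": "green"}.get(block, block)


def corrected_gv_ratio(counts) -> float:
    """Spontaneous-corrected green-to-violet ratio.

    ``(n_green − n_spont2) / (n_violet − n_spont1)`` with numerator and
    denominator floored at zero; returns NaN (missing) when the floored
    denominator is zero — no direct-reactivation excess means the cell
    carries no usable normalization signal.

    ``counts`` is anything with fields ``n_spont1, n_violet, n_spont2,
    n_green`` (a Series, dict, or one-row DataFrame).
    """
    if isinstance(counts, pd.DataFrame):
        if len(counts) != 1:
            raise ValueError("pass a single row; use aggregation for pools")
        counts = counts.iloc[0]
    green = max(float(counts["n_green"]) - float(counts["n_spont2"]), 0.0)
    violet = max(float(counts["n_violet"]) - float(counts["n_spont1"]), 0.0)
    if violet == 0:
        return float("nan")
    return green / violet


def _aggregate_ratio(counts: pd.DataFrame) -> float:
    """Corrected G/V of the summed counts of a pool of cells."""
    summed = counts[["n_spont1", "n_violet", "n_spont2", "n_green"]].sum()
    return corrected_gv_ratio(summed)


def normalize_to_control(cell_counts: pd.DataFrame,
                         control_counts: pd.DataFrame) -> PapaRatioResult:
    """Day-matched normalization of corrected G/V ratios.

    Each day's control aggregate is the corrected G/V of the *summed*
    counts of that day's control cells (robust to low-count cells);
    every experimental cell's normalized ratio is its own corrected
    ratio divided by its day's control aggregate. Cells on days without
    control coverage, or without a defined corrected ratio, are flagged
    missing (NaN) and logged.
    """
    ctrl_by_day = {day: _aggregate_ratio(g)
                   for day, g in control_counts.groupby("day_id")}
    rows = []
    for _, row in cell_counts.iterrows():
        ratio = corrected_gv_ratio(row)
        day = row["day_id"]
        ctrl = ctrl_by_day.get(day, float("nan"))
        if not np.isfinite(ctrl) or ctrl <= 0:
            norm = float("nan")
            if day not in ctrl_by_day:
                logger.warning("normalize_to_control: day %r has no control "
                               "cells; flagged missing", day)
        else:
            norm = ratio / ctrl
        rows.append({"cell_id": row["cell_id"], "day_id": day,
                     "corrected_gv": ratio, "control_aggregate": ctrl,
                     "normalized": norm})
    per_cell = pd.DataFrame(rows)
    return PapaRatioResult(per_cell=per_cell)


def _pooled_normalized_ratio(counts: pd.DataFrame,
                             ctrl_by_day: dict) -> float:
    """Combined normalized G/V of a pool of cells.

    Counts are pooled within each day, the day-wise corrected ratios
    are divided by that day's (fixed) control aggregate, and days are
    combined weighted by their pooled violet-excess counts — the
    denominator statistic that sets each day's information content.
    """
    num = 0.0
    wsum = 0.0
    for day, g in counts.groupby("day_id"):
        ctrl = ctrl_by_day.get(day, float("nan"))
        if not np.isfinite(ctrl) or ctrl <= 0:
            continue
        s = g[["n_spont1", "n_violet", "n_spont2", "n_green"]].sum()
        violet_excess = max(float(s["n_violet"]) - float(s["n_spont1"]), 0.0)
        if violet_excess == 0:
            continue
        ratio = _aggregate_ratio(g) / ctrl
        num += ratio * violet_excess
        wsum += violet_excess
    return num / wsum if wsum > 0 else float("nan")


def papa_bootstrap(cell_counts: pd.DataFrame, control_counts: pd.DataFrame,
                   n_trials: int = 96, seed: int = 0,
                   min_success: int | None = None) -> PapaRatioResult:
    """Cell-wise bootstrap of the condition-level normalized PAPA ratio.

    Control aggregates are computed once per day and held fixed; each
    trial resamples the condition's n cells with replacement, pools
    counts day-wise, and computes the combined normalized ratio. The
    point estimate is the ratio of the full (unresampled) pool; the CI
    is the 2.5–97.5 percentile band over trials. Trials where the pool
    has no violet excess are recorded missing; at least ``min_success``
    (default 90% of ``n_trials``, rounded down, per the 96-trial
    convention of 90 successes) trials must succeed.
    """
    if len(cell_counts) < 1:
        raise ValueError("need at least one cell")
    if min_success is None:
        min_success = min(90, n_trials)
    ctrl_by_day = {day: _aggregate_ratio(g)
                   for day, g in control_counts.groupby("day_id")}
    rng = np.random.default_rng(seed)
    n = len(cell_counts)
    values = np.full(n_trials, np.nan)
    for t in range(n_trials):
        idx = rng.integers(0, n, size=n)
        values[t] = _pooled_normalized_ratio(cell_counts.iloc[idx], ctrl_by_day)
    ok = values[np.isfinite(values)]
    n_missing = n_trials - len(ok)
    if len(ok) < min_success:
        raise RuntimeError(f"only {len(ok)}/{n_trials} bootstrap trials "
                           f"succeeded (need >= {min_success})")
    result = normalize_to_control(cell_counts, control_counts)
    result.point_estimate = _pooled_normalized_ratio(cell_counts, ctrl_by_day)
    result.ci_low = float(np.percentile(ok, 2.5))
    result.ci_high = float(np.percentile(ok, 97.5))
    result.trial_values = values
    result.n_missing_trials = n_missing
    return result


def segregate_papa_trajectories(trajs: pd.DataFrame, phase_map: PhaseMap
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split trajectories into green- and violet-reactivated sets.

    Assignment is by the phase of the trajectory's first frame:
    ``papa_readout`` starts go to the green set, ``violet_readout``
    starts to the violet set, spontaneous-phase starts to neither. The
    two sets can then be fed to diffusion-spectrum inference
    independently to compare the mobility of proximity-reactivated
    versus directly-reactivated molecules.
    """
    if len(trajs) == 0:
        return trajs.copy(), trajs.copy()
    keys = [k for k in ("cell_id", "trajectory") if k in trajs.columns]
    first = (trajs.sort_values("frame", kind="stable")
             .groupby(keys)["frame"].first())
    phases = pd.Series([phase_map.phase_of(int(f))[0] for f in first],
                       index=first.index)
    green_keys = phases[phases == "papa_readout"].index
    violet_keys = phases[phases == "violet_readout"].index
    indexed = trajs.set_index(keys)
    green = indexed.loc[indexed.index.isin(green_keys)].reset_index()
    violet = indexed.loc[indexed.index.isin(violet_keys)].reset_index()
    return green, violet
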