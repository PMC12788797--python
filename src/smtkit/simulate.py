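"""Synthetic data with known ground truth for every analysis stage.

Three generators mirror the three acquisition modes the analysis code
consumes:

* :func:`simulate_smt_dataset` — fast-SMT trajectory tables from a
  mixture of Brownian states in a finite detection slab;
* :func:`simulate_papa_dataset` — per-cell reactivation tallies for the
  phase-structured PAPA illumination sequence;
* :func:`simulate_frap_movie` — FRAP image stacks with exponential
  ground-truth recovery.

Each is deterministic given its config seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, FrapSimConfig, PapaSimConfig, SimulationConfig
from .papa import PhaseMap, build_phase_map

__all__ = [
    "GroundTruth",
    "simulate_smt_dataset",
    "simulate_papa_dataset",
    "simulate_papa_trajectories",
    "simulate_frap_movie",
    "frap_recovery_curve",
]


@dataclass
class GroundTruth:
    """Per-molecule and per-cell truth for an SMT simulation."""

    molecule_states: pd.DataFrame  # cell_id, day_id, molecule, state
    cell_bound_fraction: pd.DataFrame  # cell_id, day_id, bound_fraction
    bound_weight: float  # population-level bound weight of the config


def _simulate_cell(cfg: SimulationConfig, rng: np.random.Generator,
                   cell_id: int, day_id: int, traj_offset: int
                   ) -> tuple[pd.DataFrame, np.ndarray, int]:
    """One cell's localizations. Returns (locs, molecule states, next id)."""
    n_mols = max(0, int(rng.poisson(cfg.mean_mols_per_cell)))
    d_values = np.array([d for d, _ in cfg.states])
    weights = np.array([w for _, w in cfg.states])
    if cfg.cell_weight_concentration is not None:
        alpha = cfg.cell_weight_concentration * weights
        weights = rng.dirichlet(np.maximum(alpha, 1e-6))
    states = rng.choice(len(d_values), size=n_mols, p=weights)
    half = cfg.focal_depth / 2.0
    p_bleach = 1.0 / cfg.bleach_mean_frames
    rows: list[np.ndarray] = []
    next_id = traj_offset
    for m in range(n_mols):
        k = states[m]
        # geometric lifetime in frames (molecule visible from activation
        # until photobleaching or the end of the movie)
        start = (int(rng.integers(0, cfg.n_frames))
                 if cfg.activation == "uniform" else 0)
        life = min(int(rng.geometric(p_bleach)), cfg.n_frames - start)
        x = rng.uniform(0, cfg.fov_size)
        y = rng.uniform(0, cfg.fov_size)
        z = rng.uniform(-half, half)
        step_sd = np.sqrt(2.0 * d_values[k] * cfg.frame_interval)
        cur_traj = -1
        for f in range(start, start + life):
            if cfg.switching_rate > 0 and f > start \
                    and rng.random() < cfg.switching_rate:
                others = [s for s in range(len(d_values)) if s != k]
                k = int(rng.choice(others)) if others else k
                step_sd = np.sqrt(2.0 * d_values[k] * cfg.frame_interval)
            if f > start:
                dx, dy, dz = rng.normal(0.0, step_sd, size=3) if step_sd > 0 \
                    else (0.0, 0.0, 0.0)
                x, y, z = x + dx, y + dy, z + dz
            if abs(z) < half and 0 <= x <= cfg.fov_size and 0 <= y <= cfg.fov_size:
                if cur_traj < 0:
                    cur_traj = next_id
                    next_id += 1
                ox = x + rng.normal(0.0, cfg.sigma_loc) if cfg.sigma_loc else x
                oy = y + rng.normal(0.0, cfg.sigma_loc) if cfg.sigma_loc else y
                rows.append(np.array([f, cur_traj, ox, oy, m]))
            else:
                # out of the slab: with max_blinks 0 downstream, any gap
                # starts a fresh trajectory id on re-entry
                cur_traj = -1
    if rows:
        arr = np.vstack(rows)
        locs = pd.DataFrame({
            "frame": arr[:, 0].astype(int),
            "trajectory": arr[:, 1].astype(int),
            "x": arr[:, 2],
            "y": arr[:, 3],
            "molecule": arr[:, 4].astype(int),
        })
    else:
        locs = pd.DataFrame({"frame": pd.Series(dtype=int),
                             "trajectory": pd.Series(dtype=int),
                             "x": pd.Series(dtype=float),
                             "y": pd.Series(dtype=float),
                             "molecule": pd.Series(dtype=int)})
    locs["cell_id"] = cell_id
    locs["day_id"] = day_id
    return locs, states, next_id


def simulate_smt_dataset(cfg: SimulationConfig
                         ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a multi-day, multi-cell SMT localization dataset.

    Each molecule draws a diffusive state once (fixed for its lifetime
    unless ``switching_rate`` is set), performs 3-D Brownian motion with
    per-axis step variance 2·D·Δt, and is observed — with Gaussian
    localization error on x and y — only on frames where its z position
    lies inside the detection slab. Fluorophore lifetimes are geometric
    with mean ``bleach_mean_frames``; all molecules appear at movie
    start. Trajectory ids are unique across the dataset and never
    bridge a slab exit (matching max_blinks = 0 tracking).
    """
    rng = np.random.default_rng(cfg.seed)
    tables = []
    mol_rows = []
    cell_rows = []
    bound_states = {i for i, (d, _) in enumerate(cfg.states) if d < 0.1}
    next_id = 0
    cell_id = 0
    for day in range(cfg.n_days):
        for _ in range(cfg.cells_per_day):
            locs, states, next_id = _simulate_cell(cfg, rng, cell_id, day, next_id)
            tables.append(locs)
            for m, k in enumerate(states):
                mol_rows.append((cell_id, day, m, int(k)))
            bf = (np.isin(states, list(bound_states)).mean()
                  if len(states) else float("nan"))
            cell_rows.append((cell_id, day, float(bf)))
            cell_id += 1
    locs = pd.concat(tables, ignore_index=True)
    truth = GroundTruth(
        molecule_states=pd.DataFrame(mol_rows, columns=["cell_id", "day_id",
                                                        "molecule", "state"]),
        cell_bound_fraction=pd.DataFrame(cell_rows, columns=["cell_id", "day_id",
                                                             "bound_fraction"]),
        bound_weight=cfg.bound_weight,
    )
    return locs, truth


def simulate_papa_dataset(cfg: PapaSimConfig) -> pd.DataFrame:
    """Per-cell reactivation tallies under the PAPA count model.

    Returns a DataFrame with columns ``cell_id, day_id, n_spont1,
    n_violet, n_spont2, n_green``. Counts are Poisson with the means
    documented on :class:`~smtkit.config.PapaSimConfig`; the exact
    expected corrected G/V is available as
    ``cfg.expected_corrected_gv``. ``cell_rate_cv`` adds lognormal
    cell-to-cell variation of the overall expression level (all four
    means scale together, leaving the expected ratio unchanged).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    if cfg.cell_rate_cv > 0:
        sig = np.sqrt(np.log(1.0 + cfg.cell_rate_cv ** 2))
        scale = rng.lognormal(-sig ** 2 / 2.0, sig, size=n)
    else:
        scale = np.ones(n)
    green_mean = (cfg.spont_rate + cfg.control_ratio * cfg.violet_rate
                  + cfg.interaction * cfg.green_rate)
    day = np.arange(n) % cfg.n_days
    return pd.DataFrame({
        "cell_id": np.arange(n),
        "day_id": day,
        "n_spont1": rng.poisson(cfg.spont_rate * scale),
        "n_violet": rng.poisson((cfg.spont_rate + cfg.violet_rate) * scale),
        "n_spont2": rng.poisson(cfg.spont_rate * scale),
        "n_green": rng.poisson(green_mean * scale),
    })


def simulate_papa_trajectories(cfg: SimulationConfig,
                               phase_map: PhaseMap | None = None,
                               n_green: int = 200, n_violet: int = 200,
                               green_states: tuple[tuple[float, float], ...] | None = None,
                               violet_states: tuple[tuple[float, float], ...] | None = None,
                               ) -> pd.DataFrame:
    """Trajectories whose first frames fall in PAPA readout blocks.

    Green-reactivated and violet-reactivated molecules may carry
    different state mixtures (``green_states`` / ``violet_states``,
    defaulting to ``cfg.states``), emulating proximity-dependent
    reactivation of a bound-enriched subpopulation. Trajectory motion
    reuses the SMT simulator's physics; first frames are placed
    uniformly in the saved readout blocks of the given phase.
    """
    if phase_map is None:
        phase_map = build_phase_map()
    rng = np.random.default_rng(cfg.seed)
    frames_by_phase = {
        "papa_readout": np.flatnonzero(phase_map.labels == "papa_readout"),
        "violet_readout": np.flatnonzero(phase_map.labels == "violet_readout"),
    }
    rows = []
    next_id = 0
    for phase, n_mol, states in (("papa_readout", n_green, green_states or cfg.states),
                                 ("violet_readout", n_violet,
                                  violet_states or cfg.states)):
        d_values = np.array([d for d, _ in states])
        weights = np.array([w for _, w in states])
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ConfigurationError("phase state weights must sum to 1")
        half = cfg.focal_depth / 2.0
        p_bleach = 1.0 / cfg.bleach_mean_frames
        n_saved = len(phase_map.labels)
        for _ in range(n_mol):
            k = rng.choice(len(d_values), p=weights)
            start = int(rng.choice(frames_by_phase[phase]))
            life = int(rng.geometric(p_bleach))
            x = rng.uniform(0, cfg.fov_size)
            y = rng.uniform(0, cfg.fov_size)
            z = rng.uniform(-half, half)
            step_sd = np.sqrt(2.0 * d_values[k] * cfg.frame_interval)
            cur = -1
            for f in range(start, min(start + life, n_saved)):
                if f > start and step_sd > 0:
                    dx, dy, dz = rng.normal(0.0, step_sd, size=3)
                    x, y, z = x + dx, y + dy, z + dz
                if abs(z) < half:
                    if cur < 0:
                        cur = next_id
                        next_id += 1
                    rows.append((f, cur,
                                 x + rng.normal(0, cfg.sigma_loc),
                                 y + rng.normal(0, cfg.sigma_loc)))
                else:
                    break  # slab exit ends the reactivated molecule's track
    out = pd.DataFrame(rows, columns=["frame", "trajectory", "x", "y"])
    out["cell_id"] = 0
    out["day_id"] = 0
    return out


def frap_recovery_curve(cfg: FrapSimConfig, t: np.ndarray) -> np.ndarray:
    """Ground-truth fractional recovery at times ``t`` (s, from the
    first post-bleach frame)."""
    t = np.asarray(t, dtype=float)
    return (cfg.a1 * (1.0 - np.exp(-t / cfg.tau1_s))
            + cfg.a2 * (1.0 - np.exp(-t / cfg.tau2_s)))


def simulate_frap_movie(cfg: FrapSimConfig
                        ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render a FRAP movie with known recovery kinetics.

    Returns ``(stack, timestamps_s, geometry)`` where ``geometry`` holds
    the bleach frame index, spot center (px), spot radius (px and µm)
    and pixel size. Pre-bleach frames show the nucleus at plateau
    intensity; at the bleach frame the spot drops by ``bleach_depth``
    and recovers per the double-exponential ground truth (reaction
    mode) or by Gaussian profile relaxation (diffusion mode). The whole
    nuclear signal decays by ``obs_bleach_rate`` per frame; background
    and Gaussian noise are added to every pixel.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.image_size
    n_frames = cfg.n_pre + cfg.n_post
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r_nuc_px = cfg.nucleus_radius_um / cfg.pixel_size_um
    r_spot_px = cfg.spot_radius_um / cfg.pixel_size_um
    sx = c + cfg.spot_offset_um[0] / cfg.pixel_size_um
    sy = c + cfg.spot_offset_um[1] / cfg.pixel_size_um
    nucleus = ((xx - c) ** 2 + (yy - c) ** 2) <= r_nuc_px ** 2
    dist2 = (xx - sx) ** 2 + (yy - sy) ** 2
    spot = dist2 <= r_spot_px ** 2

    timestamps = np.arange(n_frames) * cfg.frame_interval_s
    t_post = timestamps[cfg.bleach_frame:] - timestamps[cfg.bleach_frame]

    stack = np.zeros((n_frames, n, n), dtype=float)
    base = np.where(nucleus, cfg.nucleus_intensity, 0.0)
    spot_area = int(np.sum(spot & nucleus))
    out_area = int(np.sum(nucleus & ~spot))
    for f in range(n_frames):
        frame = base.copy()
        if f >= cfg.bleach_frame:
            t = t_post[f - cfg.bleach_frame]
            if cfg.mode == "reaction":
                rec = float(frap_recovery_curve(cfg, np.array([t]))[0])
                deficit = cfg.bleach_depth * (1.0 - rec)
                frame = np.where(spot, frame - deficit * cfg.nucleus_intensity,
                                 frame)
                # fluorescence is conserved: the intensity recovering in
                # the spot is exchanged from the rest of the nucleus
                recovered = cfg.bleach_depth * rec * cfg.nucleus_intensity
                if out_area > 0:
                    frame = np.where(nucleus & ~spot,
                                     frame - recovered * spot_area / out_area,
                                     frame)
            else:  # diffusion: Gaussian hole with sigma0 = spot radius relaxes
                sig2 = r_spot_px ** 2 + 2.0 * cfg.diffusion_coef * t / cfg.pixel_size_um ** 2
                dilute = r_spot_px ** 2 / sig2
                hole = cfg.bleach_depth * dilute * np.exp(-dist2 / (2.0 * sig2))
                frame = frame - np.where(nucleus, hole * cfg.nucleus_intensity, 0.0)
        if cfg.obs_bleach_rate > 0:
            frame = frame * np.exp(-cfg.obs_bleach_rate * f)
        frame = frame + cfg.background
        if cfg.noise_sd > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sd, size=frame.shape)
        stack[f] = frame
    geometry = {
        "bleach_frame": cfg.bleach_frame,
        "spot_center_px": (float(sx), float(sy)),
        "spot_radius_px": float(r_spot_px),
        "spot_radius_um": cfg.spot_radius_um,
        "pixel_size_um": cfg.pixel_size_um,
    }
    return stack, timestamps, geometry
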