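"""File formats: trajectory CSVs, spectrum JSON, masks and FRAP TIFFs.

Coordinates are micron-valued throughout; pixel-valued trajectory
inputs must be converted at ingest with an explicit pixel size
(0.16 µm by default). Masks travel as labeled integer TIFFs, FRAP
movies as multi-frame grayscale TIFFs with a JSON metadata sidecar.
"""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .spectrum import DiffusionGrid, DiffusionSpectrum

logger = logging.getLogger(__name__)

SPECTRUM_FORMAT_VERSION = 1

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_spectrum",
    "read_spectrum",
    "read_mask_tiff",
    "write_mask_tiff",
    "write_frap_movie",
    "read_frap_movie",
    "write_papa_counts",
    "read_papa_counts",
]

MANDATORY_COLUMNS = ("frame", "trajectory", "x", "y")


def read_trajectory_csv(path, pixel_size_um: float | None = None
                        ) -> pd.DataFrame:
    """Read a quot-style localization/trajectory CSV.

    Mandatory columns: ``frame, trajectory, x, y``; optional
    ``cell_id, day_id``; any extra columns are preserved untouched.
    x and y are in µm unless ``pixel_size_um`` is given, in which case
    they are converted from pixels at ingest. Rows with non-numeric
    values in mandatory columns are dropped with a line-numbered report.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    if len(df) == 0:
        warnings.warn(f"{path}: header-only file, empty table")
        return df
    bad_rows = []
    for col in MANDATORY_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] \
            if df[col].dtype == object else df.index[coerced.isna()]
        bad_rows.extend((int(i) + 2, col) for i in bad)  # +2: header + 1-based
        df[col] = coerced
    if bad_rows:
        for line, col in bad_rows[:20]:
            logger.warning("%s line %d: malformed value in column %r",
                           path, line, col)
        df = df.dropna(subset=list(MANDATORY_COLUMNS)).reset_index(drop=True)
    df["frame"] = df["frame"].astype(int)
    df["trajectory"] = df["trajectory"].astype(int)
    if pixel_size_um is not None:
        df["x"] = df["x"] * pixel_size_um
        df["y"] = df["y"] * pixel_size_um
    return df


def write_trajectory_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_spectrum(spectrum: DiffusionSpectrum, path) -> None:
    """Serialize a spectrum to JSON, bit-stable for grid and occupations."""
    grid = spectrum.grid
    payload = {
        "format_version": SPECTRUM_FORMAT_VERSION,
        "grid": {"d_min": grid.d_min, "d_max": grid.d_max,
                 "n_points": grid.n_points, "sigma_loc": grid.sigma_loc,
                 "frame_interval": grid.frame_interval,
                 "focal_depth": grid.focal_depth},
        "occupations": [float(v) for v in spectrum.occupations],
        "metadata": {"n_jumps": spectrum.n_jumps, "n_cells": spectrum.n_cells,
                     "splitsize": spectrum.splitsize,
                     "log_likelihood": spectrum.log_likelihood,
                     "n_iter": spectrum.n_iter},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_spectrum(path) -> DiffusionSpectrum:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != SPECTRUM_FORMAT_VERSION:
        raise ValueError(f"unsupported spectrum format version {version!r}")
    grid = DiffusionGrid(**payload["grid"])
    occ = np.asarray(payload["occupations"], dtype=float)
    if abs(occ.sum() - 1.0) > 1e-9 or np.any(occ < 0):
        raise ValueError("invalid spectrum: occupations must be >= 0 "
                         "and sum to 1")
    meta = payload.get("metadata")
    if meta is None:
        warnings.warn("spectrum file has no metadata; applying defaults")
        meta = {}
    return DiffusionSpectrum(
        grid=grid, occupations=occ,
        n_jumps=int(meta.get("n_jumps", 0)),
        n_cells=int(meta.get("n_cells", 0)),
        splitsize=int(meta.get("splitsize", 3)),
        log_likelihood=float(meta.get("log_likelihood", float("nan"))),
        n_iter=int(meta.get("n_iter", 0)))


def read_mask_tiff(path) -> np.ndarray:
    masks = tifffile.imread(path)
    if masks.ndim != 2:
        raise ValueError("mask TIFF must be a single 2-D labeled image")
    return masks.astype(np.int32)


def write_mask_tiff(masks: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(masks).astype(np.uint16))


def write_frap_movie(stack: np.ndarray, timestamps: np.ndarray,
                     geometry: dict, path) -> None:
    """Multi-frame grayscale TIFF plus a .json metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    sidecar = {"timestamps_s": [float(t) for t in timestamps], **geometry}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_frap_movie(path) -> tuple[np.ndarray, np.ndarray, dict]:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    timestamps = np.asarray(meta.pop("timestamps_s"), dtype=float)
    return stack, timestamps, meta


def write_papa_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, index=False)


def read_papa_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ("cell_id", "day_id", "n_spont1", "n_violet", "n_spont2",
                "n_green")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    return df
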