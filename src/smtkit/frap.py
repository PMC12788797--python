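"""FRAP recovery analysis: masking, correction, binning, and fitting.

The pipeline follows the standard confocal FRAP workflow for
reaction-dominant recoveries:

1. nuclear mask from a z-normalized sum projection (Gaussian blur,
   isodata threshold, hole filling, largest component);
2. per-frame background subtraction (median of non-nuclear pixels);
3. two-anchor photobleach correction — pre-bleach frames scaled to the
   last pre-bleach frame, post-bleach frames to the first post-bleach
   frame — removing observational photobleaching without touching the
   recovery signal;
4. FRAP(t): mean bleach-spot intensity normalized to the pre-bleach
   mean;
5. log-spaced binning so the long recovery tail does not dominate the
   fit;
6. the gradient-smoothing test: if the normalized radial bleach
   profile changes shape across early post-bleach frames, recovery is
   diffusion-coupled and the reaction-model fits below do not apply;
7. constrained single- or double-exponential fits of the fractional
   recovery of the bleached amount,
   rec(t) = A·(1 − e^{−t/τ}) or A1·(1 − e^{−t/τ1}) + A2·(1 − e^{−t/τ2}),
   with amplitudes in [0, 1] and their sum at most 1 (full recovery).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from skimage.filters import gaussian, threshold_isodata
from skimage.measure import label as cc_label

__all__ = [
    "FrapCurve",
    "ExpFit",
    "nuclear_mask",
    "background_subtract",
    "photobleach_correct",
    "extract_frap_curve",
    "log_bin_resample",
    "gradient_smoothing_test",
    "diffusion_timescale",
    "fit_single_exp",
    "fit_double_exp",
    "analyze_frap_movie",
]


@dataclass
class FrapCurve:
    """Normalized FRAP recovery curve.

    ``times`` are seconds relative to the first post-bleach frame
    (pre-bleach samples are negative); ``values`` are spot intensities
    normalized so the pre-bleach mean is 1. ``recovery`` is the
    fractional recovery of the bleached amount,
    (value − F0)/(1 − F0) with F0 the first post-bleach value — the
    quantity the exponential models describe. ``binned`` marks curves
    that went through :func:`log_bin_resample` and are ready to fit.
    """

    times: np.ndarray
    values: np.ndarray
    f0: float
    binned: bool = False

    @property
    def post(self) -> np.ndarray:
        return self.times >= 0

    @property
    def recovery(self) -> np.ndarray:
        if self.f0 >= 1.0:
            raise ValueError("no bleached amount: F0 >= 1")
        return (self.values - self.f0) / (1.0 - self.f0)


@dataclass
class ExpFit:
    """Constrained exponential-recovery fit."""

    model: str  # "single" | "double"
    params: dict[str, float]
    rss: float
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.model == "single":
            return p["A"] * (1.0 - np.exp(-t / p["tau"]))
        return (p["A1"] * (1.0 - np.exp(-t / p["tau1"]))
                + p["A2"] * (1.0 - np.exp(-t / p["tau2"])))


def nuclear_mask(stack: np.ndarray, blur_sigma: float = 2.0) -> np.ndarray:
    """Segment the nucleus from a FRAP stack.

    Each frame is z-normalized (mean subtracted, divided by its s.d.),
    the stack is sum-projected, blurred, thresholded by the isodata
    (intermeans) criterion, hole-filled, and reduced to its largest
    connected component.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a T×H×W stack with at least 2 frames")
    sds = stack.std(axis=(1, 2), keepdims=True)
    if np.any(sds == 0):
        raise ValueError("constant frame: no foreground to segment")
    znorm = (stack - stack.mean(axis=(1, 2), keepdims=True)) / sds
    proj = znorm.sum(axis=0)
    blurred = gaussian(proj, sigma=blur_sigma, preserve_range=True)
    thr = threshold_isodata(blurred)
    mask = blurred > thr
    if not mask.any() or mask.all():
        raise ValueError("isodata threshold produced no usable foreground")
    mask = ndimage.binary_fill_holes(mask)
    labels = cc_label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest


def background_subtract(stack: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Subtract each frame's median non-nuclear intensity from that frame."""
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValueError("mask covers the full frame: no background pixels")
    out = np.asarray(stack, dtype=float).copy()
    bg = np.median(out[:, ~mask], axis=1)
    return out - bg[:, None, None]


def photobleach_correct(stack: np.ndarray, mask: np.ndarray,
                        bleach_frame: int) -> np.ndarray:
    """Two-anchor correction for observational photobleaching.

    Pre-bleach frames are scaled so their in-mask sums equal that of
    the last pre-bleach frame; post-bleach frames so theirs equal the
    first post-bleach frame's. Anchoring each phase to its own end of
    the bleach event preserves the intentional intensity drop while
    flattening the slow acquisition-photobleaching decay.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not 0 < bleach_frame < stack.shape[0]:
        raise ValueError("bleach_frame must lie strictly inside the stack")
    sums = stack[:, mask].sum(axis=1)
    pre_anchor = sums[bleach_frame - 1]
    post_anchor = sums[bleach_frame]
    if pre_anchor <= 0 or post_anchor <= 0:
        raise ValueError("zero in-mask intensity on an anchor frame")
    scale = np.empty(stack.shape[0])
    scale[:bleach_frame] = pre_anchor / sums[:bleach_frame]
    scale[bleach_frame:] = post_anchor / sums[bleach_frame:]
    return stack * scale[:, None, None]


def extract_frap_curve(stack: np.ndarray, timestamps: np.ndarray,
                       spot_center_px: tuple[float, float],
                       spot_radius_px: float, bleach_frame: int,
                       mask: np.ndarray | None = None) -> FrapCurve:
    """Mean spot intensity over time, normalized to the pre-bleach mean.

    Times are re-referenced so the first post-bleach frame is t = 0.
    """
    stack = np.asarray(stack, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    yy, xx = np.mgrid[0:stack.shape[1], 0:stack.shape[2]]
    sx, sy = spot_center_px
    disk = (xx - sx) ** 2 + (yy - sy) ** 2 <= spot_radius_px ** 2
    if not disk.any():
        raise ValueError("bleach-spot disk contains no pixels")
    if mask is not None and not (disk & np.asarray(mask, bool)).any():
        raise ValueError("bleach spot lies outside the nuclear mask")
    spot_mean = stack[:, disk].mean(axis=1)
    pre = spot_mean[:bleach_frame]
    if len(pre) == 0 or pre.mean() <= 0:
        raise ValueError("no usable pre-bleach frames")
    values = spot_mean / pre.mean()
    times = timestamps - timestamps[bleach_frame]
    return FrapCurve(times=times, values=values,
                     f0=float(values[bleach_frame]), binned=False)


def log_bin_resample(curve: FrapCurve, n_bins: int = 100,
                     t_min: float = 0.01,
                     t_max: float | None = None) -> FrapCurve:
    """Resample the post-bleach curve onto log-spaced time bins.

    Bin edges are log-spaced on [t_min, t_max]; each non-empty bin
    contributes the arithmetic means of its timestamps and values.
    Post-bleach samples earlier than ``t_min`` (the t = 0 anchor) are
    excluded; empty bins are dropped. Equalizing time-decade coverage
    keeps the dense early sampling from dominating the fit residual.
    """
    post = curve.post
    t = curve.times[post]
    v = curve.values[post]
    keep = t >= t_min
    if not keep.any():
        raise ValueError(f"no post-bleach samples at or after t_min={t_min}")
    t, v = t[keep], v[keep]
    if t_max is None:
        t_max = float(t.max())
    edges = np.logspace(math.log10(t_min), math.log10(t_max), n_bins + 1)
    edges[-1] *= 1.0 + 1e-12  # keep the last sample inside the last bin
    which = np.digitize(t, edges) - 1
    bt, bv = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            bt.append(t[sel].mean())
            bv.append(v[sel].mean())
    return FrapCurve(times=np.array(bt), values=np.array(bv),
                     f0=curve.f0, binned=True)


def gradient_smoothing_test(stack: np.ndarray, timestamps: np.ndarray,
                            spot_center_px: tuple[float, float],
                            bleach_frame: int, n_frames: int = 5,
                            max_radius_px: float | None = None,
                            tolerance: float = 0.1
                            ) -> tuple[np.ndarray, bool | None]:
    """Radial-profile test for diffusion-coupled recovery.

    For the first ``n_frames`` post-bleach frames, computes the mean
    intensity in 1-px annuli around the spot center, min-max normalizes
    each profile to [0, 1], and compares successive profiles. Purely
    reaction-limited recovery refills the bleached spot uniformly, so
    the normalized profile shape is static; diffusive recovery smooths
    the bleach gradient, widening the profile frame by frame. The flag
    is True when any successive pair differs by more than ``tolerance``
    anywhere, None when fewer than two profiles are available.
    """
    stack = np.asarray(stack, dtype=float)
    yy, xx = np.mgrid[0:stack.shape[1], 0:stack.shape[2]]
    sx, sy = spot_center_px
    r = np.sqrt((xx - sx) ** 2 + (yy - sy) ** 2)
    if max_radius_px is None:
        max_radius_px = min(stack.shape[1], stack.shape[2]) / 4.0
    n_annuli = int(max_radius_px)
    ring = np.floor(r).astype(int)
    profiles = []
    for f in range(bleach_frame, min(bleach_frame + n_frames, stack.shape[0])):
        frame = stack[f]
        prof = np.array([frame[ring == k].mean() for k in range(n_annuli)])
        lo, hi = prof.min(), prof.max()
        prof = (prof - lo) / (hi - lo) if hi > lo else np.zeros_like(prof)
        profiles.append(prof)
    profiles = np.array(profiles)
    if len(profiles) < 2:
        return profiles, None
    diffs = np.abs(np.diff(profiles, axis=0)).max(axis=1)
    return profiles, bool(np.any(diffs > tolerance))


def diffusion_timescale(radius_um: float, D: float) -> float:
    """Mean time for a diffusing molecule to cross the bleach spot.

    From the 2-D mean-squared displacement 4·D·t = r²: the time for a
    molecule at the spot edge to reach the center is r²/(4·D). If this
    is far shorter than the first post-bleach sampling time, diffusion
    is invisible in the recovery and a reaction model is appropriate.
    """
    if radius_um <= 0 or D <= 0:
        raise ValueError("radius and D must be > 0")
    return radius_um ** 2 / (4.0 * D)


def _fit_recovery(t: np.ndarray, y: np.ndarray, n_components: int) -> ExpFit:
    """Multi-start constrained least squares for exponential recovery.

    Double fits use the reparameterization A1 = p·q, A2 = p·(1 − q)
    with p, q in [0, 1], which enforces A1 + A2 = p ≤ 1 with simple box
    bounds. Time constants are fitted on a log scale. Starts cover
    τ ∈ {0.1, 1, 10, 100} s crossed with amplitude splits.
    """
    log_taus = [math.log10(x) for x in (0.1, 1.0, 10.0, 100.0)]

    if n_components == 1:
        def resid(params):
            a, lt = params
            return a * (1.0 - np.exp(-t / 10 ** lt)) - y

        best = None
        for lt0 in log_taus:
            sol = least_squares(resid, x0=[0.8, lt0],
                                bounds=([0.0, -4.0], [1.0, 5.0]))
            if best is None or sol.cost < best.cost:
                best = sol
        a, lt = best.x
        params = {"A": float(a), "tau": float(10 ** lt)}
        return ExpFit(model="single", params=params,
                      rss=float(2 * best.cost), converged=bool(best.success))

    def resid(params):
        p, q, lt1, lt2 = params
        a1, a2 = p * q, p * (1.0 - q)
        return (a1 * (1.0 - np.exp(-t / 10 ** lt1))
                + a2 * (1.0 - np.exp(-t / 10 ** lt2)) - y)

    best = None
    for i, lt1 in enumerate(log_taus):
        for lt2 in log_taus[i + 1:]:
            for q0 in (0.3, 0.5, 0.7):
                sol = least_squares(
                    resid, x0=[0.8, q0, lt1, lt2],
                    bounds=([0.0, 0.0, -4.0, -4.0], [1.0, 1.0, 5.0, 5.0]))
                if best is None or sol.cost < best.cost:
                    best = sol
    p, q, lt1, lt2 = best.x
    a1, a2 = p * q, p * (1.0 - q)
    tau1, tau2 = 10 ** lt1, 10 ** lt2
    if tau1 > tau2:  # canonical ordering: fast component first
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    params = {"A1": float(a1), "tau1": float(tau1),
              "A2": float(a2), "tau2": float(tau2)}
    return ExpFit(model="double", params=params,
                  rss=float(2 * best.cost), converged=bool(best.success))


def _fit_input(curve: FrapCurve, min_points: int, allow_unbinned: bool
               ) -> tuple[np.ndarray, np.ndarray]:
    if not curve.binned and not allow_unbinned:
        raise ValueError("fit expects a log-binned curve; pass "
                         "allow_unbinned=True to override")
    if len(curve.times) < min_points:
        raise ValueError(f"need >= {min_points} points, got {len(curve.times)}")
    return curve.times, curve.recovery


def fit_single_exp(curve: FrapCurve, allow_unbinned: bool = False) -> ExpFit:
    """Fit rec(t) = A·(1 − e^{−t/τ}), A ∈ [0, 1], to a binned curve."""
    t, y = _fit_input(curve, 5, allow_unbinned)
    fit = _fit_recovery(t, y, 1)
    if not fit.converged:
        raise RuntimeError("single-exponential fit failed to converge")
    return fit


def fit_double_exp(curve: FrapCurve, allow_unbinned: bool = False) -> ExpFit:
    """Fit the two-component recovery with A1, A2 ≥ 0 and A1 + A2 ≤ 1."""
    t, y = _fit_input(curve, 8, allow_unbinned)
    fit = _fit_recovery(t, y, 2)
    if not fit.converged:
        raise RuntimeError("double-exponential fit failed to converge")
    return fit


def analyze_frap_movie(stack: np.ndarray, timestamps: np.ndarray,
                       spot_center_px: tuple[float, float],
                       spot_radius_px: float, bleach_frame: int,
                       n_bins: int = 100, t_min: float = 0.01,
                       t_max: float | None = None) -> FrapCurve:
    """Run steps 1–5 on one movie and return the binned curve."""
    mask = nuclear_mask(stack)
    corrected = photobleach_correct(background_subtract(stack, mask),
                                    mask, bleach_frame)
    curve = extract_frap_curve(corrected, timestamps, spot_center_px,
                               spot_radius_px, bleach_frame, mask=mask)
    return log_bin_resample(curve, n_bins=n_bins, t_min=t_min, t_max=t_max)
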