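"""Configuration objects for the synthetic-data generators.

All lengths are in microns and all times in seconds unless a field name
says otherwise. Frame-rate and optics defaults follow the fast-SMT
acquisition regime this package targets: 7.48 ms frames and a 0.7 µm
axial detection slab.
"""
from __future__ import annotations

from dataclasses import dataclass


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis configuration is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and acquisition parameters for SMT trajectory simulation.

    Parameters
    ----------
    states
        Sequence of ``(D, weight)`` pairs: diffusion coefficient in µm²/s
        and occupation fraction. Weights must be non-negative and sum to 1.
    sigma_loc
        Localization error, 1 s.d. per coordinate, µm.
    frame_interval
        Camera frame interval, s.
    focal_depth
        Full thickness of the axial detection slab, µm. Molecules are
        detected only while ``|z| < focal_depth / 2``.
    bleach_mean_frames
        Expected fluorophore lifetime in frames (geometric distribution).
    n_frames
        Movie length in frames.
    switching_rate
        Optional per-frame probability of hopping to a different state
        (uniform over the others). Off (0.0) by default: the inference
        model assumes a fixed state per molecule; switching exists for
        stress tests only.
    activation
        ``"uniform"`` (default): each molecule's fluorophore activates
        at a uniformly random frame, emulating continuous
        photoactivation and keeping per-frame localization density
        sparse and roughly constant. ``"start"``: all molecules appear
        at frame 0 (a dense initial burst that the dense-frame
        truncation filter would remove almost entirely).
    cell_weight_concentration
        When set, each cell's state weights are drawn from a Dirichlet
        with this concentration times the population weights, creating
        genuine cell-to-cell variability in the bound fraction (small
        values → large spread). ``None`` (default): all cells share
        the population weights.
    """

    states: tuple[tuple[float, float], ...] = ((0.005, 0.3), (2.0, 0.7))
    sigma_loc: float = 0.03
    frame_interval: float = 0.00748
    focal_depth: float = 0.7
    bleach_mean_frames: float = 8.0
    n_frames: int = 1200
    n_days: int = 2
    cells_per_day: int = 10
    mean_mols_per_cell: float = 60.0
    fov_size: float = 20.0
    switching_rate: float = 0.0
    activation: str = "uniform"
    cell_weight_concentration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.states) == 0:
            raise ConfigurationError("at least one diffusive state is required")
        weights = [w for _, w in self.states]
        if any(w < 0 for w in weights):
            raise ConfigurationError("state weights must be non-negative")
        total = sum(weights)
        if total <= 0:
            raise ConfigurationError("state weights are all zero")
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"state weights must sum to 1, got {total}")
        if any(d < 0 for d, _ in self.states):
            raise ConfigurationError("diffusion coefficients must be >= 0")
        if self.sigma_loc < 0:
            raise ConfigurationError("sigma_loc must be >= 0")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be > 0")
        if self.focal_depth <= 0:
            raise ConfigurationError("focal_depth must be > 0")
        if self.bleach_mean_frames < 1:
            raise ConfigurationError("bleach_mean_frames must be >= 1")
        if not (0.0 <= self.switching_rate < 1.0):
            raise ConfigurationError("switching_rate must lie in [0, 1)")
        if self.activation not in ("uniform", "start"):
            raise ConfigurationError("activation must be 'uniform' or 'start'")
        if (self.cell_weight_concentration is not None
                and self.cell_weight_concentration <= 0):
            raise ConfigurationError("cell_weight_concentration must be > 0")

    @property
    def bound_weight(self) -> float:
        """Total ground-truth weight of states with D below 0.1 µm²/s."""
        return sum(w for d, w in self.states if d < 0.1)


@dataclass(frozen=True)
class PapaSimConfig:
    """Count model for phase-structured PAPA acquisitions.

    Per cell the four saved-phase tallies are Poisson with means

    * ``n_spont1, n_spont2 ~ Poisson(spont_rate)``
    * ``n_violet ~ Poisson(spont_rate + violet_rate)``
    * ``n_green  ~ Poisson(spont_rate + control_ratio·violet_rate
      + interaction·green_rate)``

    so the expected corrected G/V ratio is
    ``control_ratio + interaction · green_rate / violet_rate``:
    a non-interacting condition (interaction = 0) lands on the
    control baseline, and the interaction term adds linearly.
    """

    n_cells: int = 20
    n_days: int = 2
    spont_rate: float = 20.0
    violet_rate: float = 80.0
    green_rate: float = 80.0
    interaction: float = 0.0
    control_ratio: float = 0.26
    cell_rate_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spont_rate", "violet_rate", "green_rate", "interaction",
                     "control_ratio", "cell_rate_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_cells < 1 or self.n_days < 1:
            raise ConfigurationError("n_cells and n_days must be >= 1")

    @property
    def expected_corrected_gv(self) -> float:
        """Deterministic expectation of the corrected G/V ratio."""
        if self.violet_rate == 0:
            raise ConfigurationError("violet_rate must be > 0 for a defined G/V")
        return self.control_ratio + self.interaction * self.green_rate / self.violet_rate


@dataclass(frozen=True)
class FrapSimConfig:
    """Ground truth for a synthetic FRAP movie.

    The nucleus is a uniform disk of intensity ``nucleus_intensity``
    (photons-per-pixel floats; no camera gain/offset model). A spot of
    radius ``spot_radius_um`` is bleached by ``bleach_depth`` between
    frames ``bleach_frame - 1`` and ``bleach_frame``, then recovers as

        rec(t) = A1·(1 − exp(−t/τ1)) + A2·(1 − exp(−t/τ2))

    of the bleached amount, with t measured from the first post-bleach
    frame. ``mode='diffusion'`` instead relaxes a Gaussian bleach
    profile by free diffusion (for gradient-smoothing tests).
    """

    image_size: int = 64
    pixel_size_um: float = 0.16
    nucleus_radius_um: float = 4.0
    spot_radius_um: float = 0.75
    spot_offset_um: tuple[float, float] = (0.0, 0.0)
    bleach_frame: int = 16
    n_pre: int = 16
    n_post: int = 120
    frame_interval_s: float = 0.5
    a1: float = 0.5
    tau1_s: float = 2.0
    a2: float = 0.3
    tau2_s: float = 30.0
    bleach_depth: float = 0.8
    nucleus_intensity: float = 1.0
    background: float = 0.1
    obs_bleach_rate: float = 0.0
    noise_sd: float = 0.0
    mode: str = "reaction"
    diffusion_coef: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        if self.a1 + self.a2 > 1 + 1e-12:
            raise ConfigurationError("A1 + A2 must be <= 1")
        if self.tau1_s <= 0 or self.tau2_s <= 0:
            raise ConfigurationError("time constants must be > 0")
        if not (0.0 <= self.bleach_depth <= 1.0):
            raise ConfigurationError("bleach_depth must lie in [0, 1]")
        if self.mode not in ("reaction", "diffusion"):
            raise ConfigurationError("mode must be 'reaction' or 'diffusion'")
        if self.bleach_frame != self.n_pre:
            raise ConfigurationError("bleach_frame must equal n_pre (bleach "
                                     "occurs between the phases)")
        dx, dy = self.spot_offset_um
        if ((dx ** 2 + dy ** 2) ** 0.5 + self.spot_radius_um
                > self.nucleus_radius_um):
            raise ConfigurationError("bleach spot must lie inside the nucleus")
        half_fov = self.image_size * self.pixel_size_um / 2
        if self.nucleus_radius_um >= half_fov:
            raise ConfigurationError("nucleus does not fit in the field of view")
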