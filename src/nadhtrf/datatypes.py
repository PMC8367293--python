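"""Core domain types for TCSPC simulation and analysis.

All times are picoseconds unless noted. Histograms are photon counts per
time bin; the time axis is the sequence of bin centers, 0-based, uniform.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AcquisitionSettings",
    "IRFKernel",
    "MultiExpParams",
    "AnisotropyParams",
    "BindingCondition",
    "EnvironmentModel",
    "DecayHistogram",
    "FitSpec",
    "FitResult",
    "PolarizedMeasurement",
    "ConditionSeries",
    "ReplicateSummary",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class AcquisitionSettings:
    """TCSPC acquisition geometry and photon budget.

    Defaults model a 40 MHz pulsed laser (25 ns repetition period) with
    4096 bins of 6.1035 ps spanning one full period.
    """

    n_bins: int = 4096
    bin_width: float = 6.1035  # ps
    rep_period: float = 25_000.0  # ps
    photon_budget: float = 1e6  # expected detected photons
    integration_time: float = 2.0  # s

    def __post_init__(self) -> None:
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")
        if self.bin_width <= 0 or self.rep_period <= 0:
            raise ValueError("bin_width and rep_period must be positive")
        if self.photon_budget < 0:
            raise ValueError("photon_budget must be non-negative")

    @property
    def time_axis(self) -> np.ndarray:
        """Bin-center times in ps."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def span(self) -> float:
        return self.n_bins * self.bin_width


@dataclass(frozen=True)
class IRFKernel:
    """Instrument response function sampled on the acquisition time axis.

    ``values`` are non-negative per-bin weights summing to one, so that
    convolution with the IRF conserves total counts.
    """

    center: float  # ps
    fwhm: float  # ps
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if np.any(vals < 0):
            raise ValueError("IRF weights must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("IRF weights must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class MultiExpParams:
    """Multi-exponential decay: I(t) = I0 * sum_i alpha_i exp(-t/tau_i) + C.

    ``fractions`` are pre-exponential (amplitude) fractions summing to one;
    ``lifetimes`` are strictly increasing. One, two, or four components.
    """

    lifetimes: tuple  # ps
    fractions: tuple
    amplitude: float = 1.0  # I0, counts scale at t=0
    background: float = 0.0  # C, counts per bin

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in self.lifetimes)
        fracs = tuple(float(a) for a in self.fractions)
        object.__setattr__(self, "lifetimes", taus)
        object.__setattr__(self, "fractions", fracs)
        if len(taus) not in (1, 2, 4):
            raise ValueError("1, 2, or 4 decay components required")
        if len(fracs) != len(taus):
            raise ValueError("lifetimes and fractions must have equal length")
        if any(t <= 0 for t in taus):
            raise ValueError("lifetimes must be positive")
        if any(t2 <= t1 for t1, t2 in zip(taus, taus[1:])):
            raise ValueError("lifetimes must be strictly increasing")
        if any(a < 0 for a in fracs):
            raise ValueError("fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def n_components(self) -> int:
        return len(self.lifetimes)


@dataclass(frozen=True)
class AnisotropyParams:
    """Single-exponential anisotropy decay r(t) = r0 * exp(-t/theta)."""

    r0: float = 0.35
    theta: float = 15_900.0  # rotational correlation time, ps
    g_factor: float = 1.0

    def __post_init__(self) -> None:
        if not -0.2 <= self.r0 <= 0.4:
            raise ValueError("r0 must lie in [-0.2, 0.4]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.g_factor <= 0:
            raise ValueError("g_factor must be positive")


@dataclass(frozen=True)
class BindingCondition:
    """One point of an NADH / LDH binding titration.

    Binding sites are treated as independent and identical with total site
    concentration ``sites_per_protein * ldh_total``. ``brightness_ratio`` is
    the bound/free quantum-yield ratio (LDH-bound NADH is ~3.3x brighter).
    """

    nadh_total: float  # uM
    ldh_total: float  # uM
    kd: float  # per-site dissociation constant, uM
    sites_per_protein: int = 4
    brightness_ratio: float = 3.3

    def __post_init__(self) -> None:
        if self.nadh_total < 0 or self.ldh_total < 0:
            raise ValueError("concentrations must be non-negative")
        if self.sites_per_protein < 1:
            raise ValueError("sites_per_protein must be >= 1")
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.brightness_ratio <= 0:
            raise ValueError("brightness_ratio must be positive")

    @property
    def ratio(self) -> float:
        """[LDH]:[NADH] concentration ratio."""
        if self.nadh_total == 0:
            return float("inf")
        return self.ldh_total / self.nadh_total


@dataclass(frozen=True)
class EnvironmentModel:
    """Linear microenvironmental response of the NADH decay.

    Slopes describe how the intensity-weighted mean lifetime, normalized
    intensity, and steady-state anisotropy change per degree Celsius
    relative to ``reference_params`` at ``reference_temp``. An explicit
    ``per_condition_table`` (condition value -> MultiExpParams) overrides
    the slopes when present, e.g. for pH series where no parametric model
    is assumed.
    """

    reference_params: MultiExpParams
    reference_temp: float = 25.0  # degC
    taum_slope: float = -8.0  # ps per degC
    intensity_slope: float = -0.022  # fraction of reference per degC
    anisotropy_slope: float = -9.9e-4  # steady-state r per degC
    reference_anisotropy: Optional[AnisotropyParams] = None
    per_condition_table: Optional[dict] = None

    def __post_init__(self) -> None:
        for s in (self.taum_slope, self.intensity_slope, self.anisotropy_slope):
            if not np.isfinite(s):
                raise ValueError("slopes must be finite")


@dataclass(frozen=True)
class DecayHistogram:
    """Photon counts per time bin for one polarisation channel."""

    counts: np.ndarray
    settings: AcquisitionSettings
    channel: str = "magic"  # parallel | perpendicular | magic

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if counts.size != self.settings.n_bins:
            raise ValueError(
                f"counts length {counts.size} != n_bins {self.settings.n_bins}"
            )

    @property
    def time_axis(self) -> np.ndarray:
        return self.settings.time_axis


@dataclass(frozen=True)
class FitSpec:
    """Configuration of a reconvolution decay fit.

    ``window`` is (start, end) in ps; None picks the default policy: start
    10 bins before the histogram peak, span 12.5 ns. ``t0_policy`` is
    either the string ``"fit"`` or a fixed shift in ps.
    """

    n_components: int = 2
    window: Optional[tuple] = None
    t0_policy: object = "fit"  # "fit" | float (fixed value, ps)
    fit_background: bool = True
    fixed_lifetimes: Optional[tuple] = None  # hold lifetimes at these values
    fixed_fractions: Optional[tuple] = None  # hold fractions at these values
    initial_values: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.n_components not in (1, 2, 4):
            raise ValueError("n_components must be 1, 2, or 4")
        if self.window is not None:
            start, end = self.window
            if end <= start:
                raise ValueError("window end must exceed start")
        if not (self.t0_policy == "fit" or isinstance(self.t0_policy, (int, float))):
            raise ValueError("t0_policy must be 'fit' or a numeric fixed value")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear least-squares decay fit."""

    params: MultiExpParams
    t0: float
    chi2_reduced: float
    stderr: dict
    converged: bool
    n_iterations: int
    window: tuple = (0.0, 0.0)
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PolarizedMeasurement:
    """Parallel / perpendicular channel pair with optional magic angle."""

    parallel: DecayHistogram
    perpendicular: DecayHistogram
    magic: Optional[DecayHistogram] = None
    g_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.g_factor <= 0:
            raise ValueError("g_factor must be positive")
        s = self.parallel.settings
        for h in (self.perpendicular, self.magic):
            if h is not None and (
                h.settings.n_bins != s.n_bins or h.settings.bin_width != s.bin_width
            ):
                raise ValueError("channel time axes must match")


@dataclass(frozen=True)
class ConditionSeries:
    """Per-condition fit results and intensities along one environmental axis."""

    condition_name: str  # "temperature" | "pH" | "ldh_ratio"
    x: tuple
    fits: tuple  # FitResult per condition
    intensities: tuple  # total_signal per condition
    anisotropy: Optional[tuple] = None

    def __post_init__(self) -> None:
        n = len(self.x)
        if len(self.fits) != n or len(self.intensities) != n:
            raise ValueError("x, fits, intensities must have equal length")
        if self.anisotropy is not None and len(self.anisotropy) != n:
            raise ValueError("anisotropy length must match x")
        if any(b < a for a, b in zip(self.x, self.x[1:])):
            raise ValueError("condition values must be sorted ascending")


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-parameter mean and sample standard deviation over replicates."""

    mean: dict
    std: dict
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if any(v < 0 for v in self.std.values()):
            raise ValueError("std must be non-negative")
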