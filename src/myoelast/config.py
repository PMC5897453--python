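"""Acquisition and fitting configuration containers.

All interface units are the AFM bench units: nm for lengths along the piezo
axis, µm for scan-plane lengths, pN for forces, pN/nm for cantilever spring
constants, Pa for Young's moduli.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class AcquisitionConfig:
    """Force-volume acquisition geometry and instrument parameters.

    Defaults describe a soft-cantilever force-map acquisition on living
    myotubes: a 25 x 100 grid over a 10 x 80 µm area, 30 pN/nm lever,
    500 pN trigger force and a 3 µm total ramp.

    Parameters
    ----------
    grid_rows, grid_cols
        Force-map resolution (rows scan across ``scan_height_um``).
    scan_width_um, scan_height_um
        Scan-area extent; columns sample the width, rows the height.
    spring_constant_pN_per_nm
        Cantilever spring constant k.
    trigger_force_pN
        Maximum load; each approach ramp stops once the deflection force
        exceeds this value.
    ramp_length_nm
        Total piezo travel of one approach ramp.
    samples_per_curve
        Number of equidistant piezo samples along one (untruncated) ramp.
    loading_speed_um_per_s
        Constant approach speed (metadata only; no rate dependence is
        modelled).
    noise_sd_nm
        Standard deviation of additive Gaussian deflection noise.
    baseline_tilt_nm_per_um
        Optional linear baseline drift of the deflection signal along the
        ramp, standing in for slow thermal/optical drift.
    temperature_K
        Bath temperature (used by the thermal spring-constant calibration).
    seed
        Default seed for stochastic simulation.
    """

    grid_rows: int = 25
    grid_cols: int = 100
    scan_width_um: float = 80.0
    scan_height_um: float = 10.0
    spring_constant_pN_per_nm: float = 30.0
    trigger_force_pN: float = 500.0
    ramp_length_nm: float = 3000.0
    samples_per_curve: int = 1024
    loading_speed_um_per_s: float = 7.0
    noise_sd_nm: float = 0.3
    baseline_tilt_nm_per_um: float = 0.0
    temperature_K: float = 305.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigError("grid_rows and grid_cols must be >= 1")
        if self.spring_constant_pN_per_nm <= 0:
            raise ConfigError("spring constant must be > 0")
        if self.trigger_force_pN <= 0:
            raise ConfigError("trigger force must be > 0")
        if self.ramp_length_nm <= 0:
            raise ConfigError("ramp length must be > 0")
        if self.samples_per_curve < 32:
            raise ConfigError("samples_per_curve must be >= 32")
        if self.noise_sd_nm < 0:
            raise ConfigError("noise sd must be >= 0")
        if self.scan_width_um <= 0 or self.scan_height_um <= 0:
            raise ConfigError("scan extents must be > 0")
        if self.temperature_K <= 0:
            raise ConfigError("temperature must be > 0")

    @property
    def pixel_size_um(self) -> Tuple[float, float]:
        """(dy, dx) pixel pitch in µm; pixel centers sit at (i + 0.5) * pitch."""
        return (self.scan_height_um / self.grid_rows,
                self.scan_width_um / self.grid_cols)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class FitConfig:
    """Per-curve processing parameters: contact detection, Sneddon fit, QC.

    ``nu`` is the Poisson ratio (0.5 for incompressible soft matter) and
    ``half_angle_deg`` the cone half-opening angle of the tip. The QC rule
    flags a fit poor when its force RMSE exceeds
    ``max(rmse_cap_pN, rmse_cap_noise_factor * k * baseline_sd)`` so the cap
    tracks the actual detector noise of the curve.
    """

    nu: float = 0.5
    half_angle_deg: float = 45.0
    baseline_fraction: float = 0.3
    adaptive_baseline: bool = True
    contact_method: str = "threshold"
    n_sigma: float = 3.0
    min_run: int = 5
    refine_contact: bool = True
    refine_back_nm: float = 800.0
    refine_forward_nm: float = 100.0
    force_window: Tuple[float, float] = (0.1, 0.9)
    min_points: int = 8
    rmse_cap_pN: float = 5.0
    rmse_cap_noise_factor: float = 2.0
    min_indentation_nm: float = 20.0
    e_max_Pa: float = 1.0e5
    substrate_percentile: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 < self.nu <= 0.5):
            raise ConfigError("Poisson ratio must be in (0, 0.5]")
        if not (0.0 < self.half_angle_deg < 90.0):
            raise ConfigError("half-opening angle must be in (0, 90) degrees")
        if not (0.0 < self.baseline_fraction <= 0.8):
            raise ConfigError("baseline_fraction must be in (0, 0.8]")
        if self.contact_method not in ("threshold", "ratio_of_variances"):
            raise ConfigError(f"unknown contact method {self.contact_method!r}")
        lo, hi = self.force_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError("force_window must satisfy 0 <= lo < hi <= 1")
        if self.min_points < 3:
            raise ConfigError("min_points must be >= 3")
        if self.e_max_Pa <= 0:
            raise ConfigError("e_max_Pa must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        known = {f for f in cls.__dataclass_fields__}
        d = dict(d)
        if "force_window" in d and isinstance(d["force_window"], list):
            d["force_window"] = tuple(d["force_window"])
        return cls(**{k: v for k, v in d.items() if k in known})
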