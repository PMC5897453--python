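"""In-memory containers for force curves and force volumes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

import numpy as np

from .config import AcquisitionConfig


class CurveError(ValueError):
    """Raised when a force curve violates its invariants."""


@dataclass
class ForceCurve:
    """One approach ramp: piezo extension vs cantilever deflection.

    ``z_nm`` increases toward the sample and must be strictly monotone;
    positive deflection means repulsive contact. The contact point is
    expressed on the same ``z_nm`` axis, so a larger contact z means a
    taller pixel.
    """

    z_nm: np.ndarray
    deflection_nm: np.ndarray
    spring_constant_pN_per_nm: float
    loading_speed_um_per_s: float = 7.0
    pixel_coords: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.deflection_nm = np.asarray(self.deflection_nm, dtype=float)
        if self.z_nm.ndim != 1 or self.deflection_nm.ndim != 1:
            raise CurveError("z and deflection must be 1-D arrays")
        if self.z_nm.shape != self.deflection_nm.shape:
            raise CurveError("z and deflection must have the same length")
        if self.z_nm.size < 16:
            raise CurveError("a force curve needs at least 16 samples")
        dz = np.diff(self.z_nm)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise CurveError("z must be strictly monotone on the approach")
        if self.spring_constant_pN_per_nm <= 0:
            raise CurveError("spring constant must be > 0")

    def __len__(self) -> int:
        return self.z_nm.size

    def force_pN(self, d0_nm: float = 0.0) -> np.ndarray:
        """Deflection converted to force, F = k * (d - d0)."""
        return self.spring_constant_pN_per_nm * (self.deflection_nm - d0_nm)

    def replace_deflection(self, deflection_nm: np.ndarray) -> "ForceCurve":
        return ForceCurve(self.z_nm.copy(), np.asarray(deflection_nm, float),
                          self.spring_constant_pN_per_nm,
                          self.loading_speed_um_per_s, self.pixel_coords)


@dataclass
class ForceVolume:
    """A rectangular, row-major grid of force curves (one force map)."""

    curves: List[List[ForceCurve]]
    config: AcquisitionConfig
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rows = len(self.curves)
        if rows == 0:
            raise CurveError("empty force volume")
        cols = len(self.curves[0])
        if any(len(r) != cols for r in self.curves):
            raise CurveError("force-volume grid must be fully populated")
        ks = {c.spring_constant_pN_per_nm for row in self.curves for c in row}
        if len(ks) != 1:
            raise CurveError("all curves in a volume must share the spring constant")

    @property
    def shape(self) -> Tuple[int, int]:
        return (len(self.curves), len(self.curves[0]))

    def __getitem__(self, rc: Tuple[int, int]) -> ForceCurve:
        r, c = rc
        return self.curves[r][c]

    def iter_pixels(self) -> Iterator[Tuple[int, int, ForceCurve]]:
        for i, row in enumerate(self.curves):
            for j, curve in enumerate(row):
                yield i, j, curve
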