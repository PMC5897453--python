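"""Ground-truth-known phantoms and simulated force-volume acquisition.

The generator emulates a soft-cantilever force-map experiment on cultured
myotubes: a half-cylinder "tube" of soft material (moduli drawn from a
two-component Gaussian mixture, hundreds of Pa to a few kPa) lying on a
stiff flat substrate (default 100 kPa, the collagen film), scanned with a
30 pN/nm lever, 500 pN trigger force and a 3 µm ramp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .curves import ForceCurve, ForceVolume
from .sneddon import (cone_prefactor_pN_per_nm2,
                      indentation_from_separation_nm)


class SimulationError(RuntimeError):
    """Raised when an acquisition cannot be simulated as configured."""


#: (w1, mu1_Pa, sigma1_Pa, mu2_Pa, sigma2_Pa)
MixtureParams = Tuple[float, float, float, float, float]

#: Default cell mixture: soft (myosin-rich) and stiff (actin-rich) component
#: scales typical of thin wildtype myotubes.
DEFAULT_MIXTURE: MixtureParams = (0.5, 557.0, 80.0, 1200.0, 150.0)


@dataclass
class CellPhantom:
    """Ground-truth cell geometry and elasticity field over a scan grid."""

    height_field_nm: np.ndarray
    modulus_field_Pa: np.ndarray
    cell_mask: np.ndarray
    mixture_params: MixtureParams
    substrate_modulus_Pa: float
    tube_radius_um: float

    def __post_init__(self) -> None:
        if self.height_field_nm.shape != self.modulus_field_Pa.shape \
                or self.height_field_nm.shape != self.cell_mask.shape:
            raise ValueError("phantom rasters must share one shape")
        if np.any(self.modulus_field_Pa <= 0):
            raise ValueError("modulus field must be positive everywhere")
        if np.any(self.height_field_nm < 0):
            raise ValueError("height field must be non-negative")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.height_field_nm.shape


@dataclass
class GroundTruthManifest:
    """Everything needed to score a recovery against a simulated map."""

    true_modulus_Pa: np.ndarray
    true_contact_z_nm: np.ndarray
    cell_mask: np.ndarray
    mixture_params: MixtureParams
    substrate_modulus_Pa: float
    seed: Optional[int]


def _validate_mixture(mixture: MixtureParams) -> MixtureParams:
    w1, mu1, s1, mu2, s2 = (float(v) for v in mixture)
    if not (0.0 < w1 < 1.0):
        raise ValueError("mixture weight w1 must be in (0, 1)")
    if not (mu1 < mu2):
        raise ValueError("mixture means must satisfy mu1 < mu2")
    if s1 < 0 or s2 < 0:
        raise ValueError("mixture sigmas must be >= 0")
    return (w1, mu1, s1, mu2, s2)


def sample_mixture(mixture: MixtureParams, n: int, rng: np.random.Generator,
                   floor_Pa: float = 50.0) -> np.ndarray:
    """Draw n i.i.d. moduli from a two-component Gaussian mixture.

    Draws below ``floor_Pa`` are redrawn (left truncation) so every modulus
    stays physical.
    """
    w1, mu1, s1, mu2, s2 = _validate_mixture(mixture)
    if floor_Pa <= 0:
        raise ValueError("truncation floor must be positive")
    comp = rng.random(n) < w1
    vals = np.where(comp, rng.normal(mu1, s1, n), rng.normal(mu2, s2, n))
    for _ in range(1000):
        bad = vals < floor_Pa
        if not bad.any():
            break
        nbad = int(bad.sum())
        comp_b = rng.random(nbad) < w1
        vals[bad] = np.where(comp_b, rng.normal(mu1, s1, nbad),
                             rng.normal(mu2, s2, nbad))
    else:  # pragma: no cover - pathological mixture entirely below floor
        raise ValueError("mixture mass lies almost entirely below the floor")
    return vals


def make_phantom(config: AcquisitionConfig,
                 tube_radius_um: float = 2.0,
                 tube_center_um: Optional[float] = None,
                 mixture: MixtureParams = DEFAULT_MIXTURE,
                 substrate_modulus_Pa: float = 1.0e5,
                 floor_Pa: float = 50.0,
                 seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None) -> CellPhantom:
    """Build a half-cylinder myotube phantom over the scan grid.

    The tube axis runs along the scan width (columns); its cross-section in
    the row direction is h(y) = sqrt(r^2 - (y - y0)^2) where defined, else 0.
    Cell pixels (h > 0) draw their moduli i.i.d. from ``mixture``; substrate
    pixels take the constant ``substrate_modulus_Pa``.
    """
    if tube_radius_um <= 0:
        raise ValueError("tube radius must be positive")
    mixture = _validate_mixture(mixture)
    if substrate_modulus_Pa <= 0:
        raise ValueError("substrate modulus must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)

    dy, _ = config.pixel_size_um
    y = (np.arange(config.grid_rows) + 0.5) * dy
    y0 = 0.5 * config.scan_height_um if tube_center_um is None else tube_center_um
    r = tube_radius_um
    inside = np.abs(y - y0) < r
    profile_um = np.where(inside, np.sqrt(np.clip(r ** 2 - (y - y0) ** 2, 0, None)), 0.0)
    height = np.tile((profile_um * 1000.0)[:, None], (1, config.grid_cols))

    cell_mask = height > 0
    modulus = np.full(height.shape, float(substrate_modulus_Pa))
    n_cell = int(cell_mask.sum())
    if n_cell:
        modulus[cell_mask] = sample_mixture(mixture, n_cell, rng, floor_Pa)
    return CellPhantom(height, modulus, cell_mask, mixture,
                       float(substrate_modulus_Pa), float(tube_radius_um))


def simulate_curve(true_modulus_Pa: float, contact_height_nm: float,
                   config: AcquisitionConfig, nu: float = 0.5,
                   half_angle_deg: float = 45.0,
                   rng: Optional[np.random.Generator] = None,
                   seed: Optional[int] = None,
                   approach_clearance_nm: float = 500.0,
                   pixel_coords: Optional[Tuple[int, int]] = None) -> ForceCurve:
    """Simulate one approach ramp over a pixel of known modulus and height.

    The ramp window starts ``approach_clearance_nm`` before the contact
    point ``contact_height_nm`` (expressed on the absolute piezo axis;
    larger = taller) and spans ``ramp_length_nm``. Past contact the
    indentation solves z - z0 = delta + F(delta)/k in closed form; the curve
    is truncated one sample after the force first exceeds the trigger.
    """
    if true_modulus_Pa <= 0:
        raise ValueError("true modulus must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    k = config.spring_constant_pN_per_nm
    z0 = float(contact_height_nm)
    z = z0 - approach_clearance_nm + np.linspace(
        0.0, config.ramp_length_nm, config.samples_per_curve)
    delta = indentation_from_separation_nm(z - z0, true_modulus_Pa, k,
                                           nu, half_angle_deg)
    c = cone_prefactor_pN_per_nm2(true_modulus_Pa, nu, half_angle_deg)
    force = c * delta ** 2
    if force[-1] < config.trigger_force_pN:
        raise SimulationError(
            f"trigger force {config.trigger_force_pN} pN unreachable within "
            f"the ramp (max simulated force {force[-1]:.1f} pN) at pixel "
            f"{pixel_coords}")
    over = np.nonzero(force > config.trigger_force_pN)[0]
    stop = (over[0] + 1) if over.size else force.size
    stop = max(stop, 16)
    z, force = z[:stop], force[:stop]

    deflection = force / k
    deflection = deflection + config.baseline_tilt_nm_per_um * (z - z[0]) / 1000.0
    if config.noise_sd_nm > 0:
        deflection = deflection + rng.normal(0.0, config.noise_sd_nm, z.size)
    return ForceCurve(z, deflection, k, config.loading_speed_um_per_s,
                      pixel_coords)


def simulate_map(phantom: CellPhantom, config: AcquisitionConfig,
                 nu: float = 0.5, half_angle_deg: float = 45.0,
                 seed: Optional[int] = None,
                 approach_clearance_nm: float = 500.0
                 ) -> Tuple[ForceVolume, GroundTruthManifest]:
    """Simulate the full force-volume acquisition of a phantom.

    One curve per pixel, each with its own independent noise stream spawned
    from the seed, so identical (phantom, config, seed) are reproducible.
    The substrate sits at piezo height 0; each pixel's contact point is its
    phantom height.
    """
    if phantom.shape != (config.grid_rows, config.grid_cols):
        raise ValueError("phantom and config grids disagree")
    the_seed = config.seed if seed is None else seed
    children = np.random.SeedSequence(the_seed).spawn(
        config.grid_rows * config.grid_cols)
    rows: List[List[ForceCurve]] = []
    idx = 0
    for i in range(config.grid_rows):
        row: List[ForceCurve] = []
        for j in range(config.grid_cols):
            rng = np.random.default_rng(children[idx])
            idx += 1
            try:
                row.append(simulate_curve(
                    float(phantom.modulus_field_Pa[i, j]),
                    float(phantom.height_field_nm[i, j]),
                    config, nu, half_angle_deg, rng=rng,
                    approach_clearance_nm=approach_clearance_nm,
                    pixel_coords=(i, j)))
            except SimulationError as exc:
                raise SimulationError(f"pixel ({i}, {j}): {exc}") from exc
        rows.append(row)
    volume = ForceVolume(rows, config, provenance={"source": "synthetic",
                                                   "seed": the_seed})
    manifest = GroundTruthManifest(
        phantom.modulus_field_Pa.copy(), phantom.height_field_nm.copy(),
        phantom.cell_mask.copy(), phantom.mixture_params,
        phantom.substrate_modulus_Pa, the_seed)
    return volume, manifest


@dataclass
class GroupSpec:
    """Generative description of one experimental group in a cohort."""

    label: str
    n_maps: int
    mixture: MixtureParams = DEFAULT_MIXTURE
    diameter_mean_um: float = 5.19
    diameter_sd_um: float = 1.0
    diameter_floor_um: float = 1.7
    substrate_modulus_Pa: float = 1.0e5

    def __post_init__(self) -> None:
        if self.n_maps < 1:
            raise ValueError("each group needs n_maps >= 1")
        _validate_mixture(self.mixture)
        if self.diameter_mean_um <= 0 or self.diameter_sd_um <= 0:
            raise ValueError("diameter distribution must be positive")


def sample_diameters_um(spec: GroupSpec, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal myotube diameters (left-truncated at the floor)."""
    vals = rng.normal(spec.diameter_mean_um, spec.diameter_sd_um, n)
    for _ in range(1000):
        bad = vals < spec.diameter_floor_um
        if not bad.any():
            return vals
        vals[bad] = rng.normal(spec.diameter_mean_um, spec.diameter_sd_um,
                               int(bad.sum()))
    raise ValueError("diameter distribution lies below the floor")


def generate_cohort(group_specs: Sequence[GroupSpec],
                    config: AcquisitionConfig, out_dir, seed: int,
                    nu: float = 0.5, half_angle_deg: float = 45.0,
                    force: bool = False) -> dict:
    """Simulate a cohort of force maps and write it to ``out_dir``.

    Writes one HDF5 force-volume file per map, a ``diameters.csv`` with
    columns (group, map_id, diameter_um) and a ``manifest.json`` recording
    every generative parameter. Each map's tube radius is half its sampled
    diameter, tying the thin/thick classification to the simulated geometry.
    """
    from .io import write_volume  # local import to avoid a cycle

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"cohort directory {out} exists; use force=True")
    out.mkdir(parents=True, exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)

    ss = np.random.SeedSequence(seed)
    manifest: dict = {"seed": int(seed), "config": config.to_dict(),
                      "nu": nu, "half_angle_deg": half_angle_deg,
                      "groups": []}
    rows = []
    for spec, group_ss in zip(group_specs, ss.spawn(len(group_specs))):
        dia_rng = np.random.default_rng(group_ss.spawn(1)[0])
        diameters = sample_diameters_um(spec, spec.n_maps, dia_rng)
        map_entries = []
        for m, (dia, map_ss) in enumerate(
                zip(diameters, group_ss.spawn(spec.n_maps))):
            map_id = f"{spec.label}_{m:03d}"
            child = map_ss.generate_state(1)[0] % (2 ** 31)
            phantom = make_phantom(
                config, tube_radius_um=float(dia) / 2.0,
                mixture=spec.mixture,
                substrate_modulus_Pa=spec.substrate_modulus_Pa,
                rng=np.random.default_rng(map_ss.spawn(1)[0]))
            volume, truth = simulate_map(phantom, config, nu, half_angle_deg,
                                         seed=int(child))
            path = out / "maps" / f"{map_id}.h5"
            write_volume(path, volume, ground_truth=truth)
            rows.append({"group": spec.label, "map_id": map_id,
                         "diameter_um": float(dia)})
            map_entries.append({"map_id": map_id, "file": str(path.name),
                                "diameter_um": float(dia),
                                "seed": int(child)})
        manifest["groups"].append({
            "label": spec.label, "n_maps": spec.n_maps,
            "mixture": list(spec.mixture),
            "diameter_mean_um": spec.diameter_mean_um,
            "diameter_sd_um": spec.diameter_sd_um,
            "diameter_floor_um": spec.diameter_floor_um,
            "substrate_modulus_Pa": spec.substrate_modulus_Pa,
            "maps": map_entries})
    pd.DataFrame(rows).to_csv(out / "diameters.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
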