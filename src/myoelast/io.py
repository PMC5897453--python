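"""Force-volume container IO.

Two documented on-disk forms:

* HDF5: ``/metadata`` (acquisition config as attributes),
  ``/curves/<row>_<col>/{z_nm, deflection_nm}``, optional ``/ground_truth``.
* Plain-text dialect: one two-column TSV per curve plus a JSON sidecar with
  the calibration metadata.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional, Tuple

import h5py
import numpy as np

from .config import AcquisitionConfig
from .curves import ForceCurve, ForceVolume
from .synthetic import GroundTruthManifest


class FormatError(ValueError):
    """Raised when a container file does not match the documented layout."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_volume(path, volume: ForceVolume,
                 ground_truth: Optional[GroundTruthManifest] = None) -> Path:
    """Write a force volume (and optional ground truth) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        meta = f.create_group("metadata")
        for key, val in volume.config.to_dict().items():
            meta.attrs[key] = val
        curves = f.create_group("curves")
        for i, j, curve in volume.iter_pixels():
            g = curves.create_group(f"{i}_{j}")
            # track_times=False keeps repeated writes reproducible
            g.create_dataset("z_nm", data=curve.z_nm, track_times=False)
            g.create_dataset("deflection_nm", data=curve.deflection_nm,
                             track_times=False)
        if ground_truth is not None:
            gt = f.create_group("ground_truth")
            gt.create_dataset("true_modulus_Pa",
                              data=ground_truth.true_modulus_Pa,
                              track_times=False)
            gt.create_dataset("true_contact_z_nm",
                              data=ground_truth.true_contact_z_nm,
                              track_times=False)
            gt.create_dataset("cell_mask",
                              data=ground_truth.cell_mask.astype(np.uint8),
                              track_times=False)
            gt.attrs["mixture_params"] = list(ground_truth.mixture_params)
            gt.attrs["substrate_modulus_Pa"] = ground_truth.substrate_modulus_Pa
            if ground_truth.seed is not None:
                gt.attrs["seed"] = ground_truth.seed
    return path


def read_volume(path, spring_constant_override_pN_per_nm: Optional[float] = None
                ) -> Tuple[ForceVolume, Optional[GroundTruthManifest]]:
    """Read a force volume from HDF5; returns (volume, ground_truth | None).

    ``spring_constant_override_pN_per_nm`` replaces the stored calibration
    (e.g. with a freshly measured value); the original stays in the file.
    """
    path = Path(path)
    checksum = _sha256(path)
    with h5py.File(path, "r") as f:
        if "metadata" not in f or "curves" not in f:
            raise FormatError(f"{path}: missing /metadata or /curves group")
        attrs = dict(f["metadata"].attrs)
        if "spring_constant_pN_per_nm" not in attrs \
                and spring_constant_override_pN_per_nm is None:
            raise FormatError(f"{path}: no spring constant stored and no "
                              "override given")
        if spring_constant_override_pN_per_nm is not None:
            attrs["spring_constant_pN_per_nm"] = \
                float(spring_constant_override_pN_per_nm)
        attrs = {k: (v.item() if hasattr(v, "item") else v)
                 for k, v in attrs.items()}
        config = AcquisitionConfig.from_dict(attrs)
        rows, cols = config.grid_rows, config.grid_cols
        grid: List[List[ForceCurve]] = []
        for i in range(rows):
            row = []
            for j in range(cols):
                name = f"{i}_{j}"
                if name not in f["curves"]:
                    raise FormatError(f"{path}: missing curve dataset "
                                      f"/curves/{name}")
                g = f["curves"][name]
                for ds in ("z_nm", "deflection_nm"):
                    if ds not in g:
                        raise FormatError(
                            f"{path}: /curves/{name} lacks dataset {ds!r}")
                row.append(ForceCurve(g["z_nm"][()], g["deflection_nm"][()],
                                      config.spring_constant_pN_per_nm,
                                      config.loading_speed_um_per_s, (i, j)))
            grid.append(row)
        truth = None
        if "ground_truth" in f:
            gt = f["ground_truth"]
            truth = GroundTruthManifest(
                gt["true_modulus_Pa"][()], gt["true_contact_z_nm"][()],
                gt["cell_mask"][()].astype(bool),
                tuple(gt.attrs["mixture_params"]),
                float(gt.attrs["substrate_modulus_Pa"]),
                int(gt.attrs["seed"]) if "seed" in gt.attrs else None)
    volume = ForceVolume(grid, config,
                         provenance={"source": str(path), "sha256": checksum})
    return volume, truth


# -- plain-text single-curve dialect ----------------------------------------

def write_curve_tsv(path, curve: ForceCurve) -> Path:
    """Write one curve as a two-column TSV plus a JSON metadata sidecar."""
    path = Path(path)
    data = np.column_stack([curve.z_nm, curve.deflection_nm])
    np.savetxt(path, data, delimiter="\t", fmt="%.17g",
               header="z_nm\tdeflection_nm", comments="")
    sidecar = {
        "spring_constant_pN_per_nm": curve.spring_constant_pN_per_nm,
        "loading_speed_um_per_s": curve.loading_speed_um_per_s,
        "pixel_coords": list(curve.pixel_coords) if curve.pixel_coords else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))
    return path


def read_curve_tsv(path) -> ForceCurve:
    """Read one curve from the TSV + JSON sidecar dialect."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    if "spring_constant_pN_per_nm" not in meta:
        raise FormatError(f"{sidecar_path}: missing spring constant")
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2:
        raise FormatError(f"{path}: expected two tab-separated columns")
    coords = meta.get("pixel_coords")
    return ForceCurve(data[:, 0], data[:, 1],
                      float(meta["spring_constant_pN_per_nm"]),
                      float(meta.get("loading_speed_um_per_s", 7.0)),
                      tuple(coords) if coords else None)
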