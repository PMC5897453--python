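"""Assemble per-pixel fits into co-registered topography and elasticity maps.

Topography is the detected contact height of each pixel re-zeroed to a low
percentile of the contact heights (the substrate level); elasticity is the
fitted Young's modulus. Every pixel carries a QC status; failures are
flagged, never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import FitConfig
from .curves import ForceVolume
from .curve_ops import (STATUS_EXCLUDED, STATUS_NO_CONTACT, STATUS_OK,
                        analyze_curve)

logger = logging.getLogger(__name__)

QC_STATUSES = ("ok", "low_indentation", "poor_fit", "no_contact", "excluded")


class MapError(RuntimeError):
    """Raised when a force map cannot be processed or queried."""


@dataclass
class RasterMap:
    """A per-pixel raster co-registered with a QC mask."""

    values: np.ndarray
    qc_mask: np.ndarray  # array of QC status strings
    pixel_size_um: Tuple[float, float]
    units: str

    def __post_init__(self) -> None:
        if self.values.shape != self.qc_mask.shape:
            raise MapError("raster and QC mask must share one shape")

    @property
    def ok_mask(self) -> np.ndarray:
        return self.qc_mask == STATUS_OK

    @property
    def ok_values(self) -> np.ndarray:
        return self.values[self.ok_mask]


class TopographyMap(RasterMap):
    """Contact-height raster (nm), re-zeroed to the substrate level."""


class ElasticityMap(RasterMap):
    """Young's modulus raster (Pa)."""


@dataclass
class RegionOfInterest:
    """An explicit pixel set, e.g. the cell body or a projection."""

    label: str
    pixels: np.ndarray  # (n, 2) array of (row, col)

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        if self.pixels.size == 0:
            raise MapError("ROI must contain at least one pixel")
        if self.pixels.shape[1] != 2:
            raise MapError("ROI pixels must be (row, col) pairs")

    @classmethod
    def from_rect(cls, label: str, row0: int, col0: int,
                  row1: int, col1: int) -> "RegionOfInterest":
        """Inclusive-exclusive rectangle [row0, row1) x [col0, col1)."""
        rr, cc = np.meshgrid(np.arange(row0, row1), np.arange(col0, col1),
                             indexing="ij")
        return cls(label, np.column_stack([rr.ravel(), cc.ravel()]))

    def clip_to(self, shape: Tuple[int, int]) -> "RegionOfInterest":
        m = (self.pixels[:, 0] >= 0) & (self.pixels[:, 0] < shape[0]) \
            & (self.pixels[:, 1] >= 0) & (self.pixels[:, 1] < shape[1])
        return RegionOfInterest(self.label, self.pixels[m])


def process_volume(volume: ForceVolume,
                   fit_config: Optional[FitConfig] = None
                   ) -> Tuple[TopographyMap, ElasticityMap, pd.DataFrame]:
    """Fit every curve of a force volume and assemble the map products.

    Returns the topography map (contact heights re-zeroed so the
    ``substrate_percentile`` of detected heights is 0), the elasticity map,
    and a tidy per-pixel fit table. Pixels whose fitted modulus exceeds
    ``e_max_Pa`` are flagged ``excluded`` (substrate/collagen); all other
    failure modes keep their per-curve status.
    """
    cfg = fit_config or FitConfig()
    rows, cols = volume.shape
    elasticity = np.full((rows, cols), np.nan)
    topography = np.full((rows, cols), np.nan)
    qc = np.full((rows, cols), STATUS_NO_CONTACT, dtype=object)
    records = []
    for i, j, curve in volume.iter_pixels():
        fit = analyze_curve(curve, cfg)
        status = fit.status
        if status == STATUS_OK and fit.youngs_modulus_Pa > cfg.e_max_Pa:
            status = STATUS_EXCLUDED
        qc[i, j] = status
        topography[i, j] = fit.contact_z_nm
        if status == STATUS_OK:
            elasticity[i, j] = fit.youngs_modulus_Pa
        records.append({
            "row": i, "col": j, "status": status,
            "youngs_modulus_Pa": fit.youngs_modulus_Pa,
            "contact_z_nm": fit.contact_z_nm,
            "baseline_sd_nm": fit.baseline_sd_nm,
            "fit_rmse_pN": fit.fit_rmse_pN,
            "n_points_fit": fit.n_points_fit,
            "max_indentation_nm": fit.max_indentation_nm,
        })
    table = pd.DataFrame.from_records(records)

    n_ok = int((qc == STATUS_OK).sum())
    if not np.isfinite(topography).any():
        raise MapError("no processable pixels in the volume")
    datum = np.nanpercentile(topography, cfg.substrate_percentile)
    topography = topography - datum
    table["height_nm"] = table["contact_z_nm"] - datum
    logger.info("processed %dx%d map: %d/%d pixels ok (%.1f%%)",
                rows, cols, n_ok, rows * cols, 100.0 * n_ok / (rows * cols))

    pix = volume.config.pixel_size_um
    qc_str = qc.astype(str)
    return (TopographyMap(topography, qc_str, pix, "nm"),
            ElasticityMap(elasticity, qc_str, pix, "Pa"),
            table)


def roi_statistics(emap: ElasticityMap, roi: RegionOfInterest
                   ) -> Tuple[float, float, int]:
    """Mean, SEM and n of the ok-pixel moduli inside an ROI."""
    roi = roi.clip_to(emap.values.shape)
    r, c = roi.pixels[:, 0], roi.pixels[:, 1]
    ok = emap.qc_mask[r, c] == STATUS_OK
    vals = emap.values[r[ok], c[ok]]
    if vals.size == 0:
        raise MapError(f"ROI {roi.label!r} has no ok pixels")
    n = int(vals.size)
    sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(vals.mean()), sem, n


def exclude_maps(map_ids: Sequence[str],
                 exclusions: Sequence[Tuple[str, str]]
                 ) -> Tuple[List[str], pd.DataFrame]:
    """Apply a reasoned exclusion list to a set of map ids.

    Mirrors the experimental practice of dropping maps whose optical images
    show morphological change during acquisition: excluded ids are removed
    from downstream aggregation but retained in the returned audit log.
    Duplicate exclusions collapse to one with a warning; unknown ids raise.
    """
    known = list(map_ids)
    seen: Dict[str, str] = {}
    for map_id, reason in exclusions:
        if not isinstance(reason, str) or not reason.strip():
            raise ValueError(f"exclusion of {map_id!r} needs a non-empty reason")
        if map_id not in known:
            raise KeyError(f"unknown map id {map_id!r}")
        if map_id in seen:
            logger.warning("map %s excluded more than once", map_id)
            continue
        seen[map_id] = reason
    kept = [m for m in known if m not in seen]
    audit = pd.DataFrame(
        [{"map_id": m, "excluded": m in seen, "reason": seen.get(m, "")}
         for m in known])
    return kept, audit


def export_maps(topography: TopographyMap, elasticity: ElasticityMap,
                out_dir, basename: str = "map",
                color_range_kPa: Tuple[float, float] = (0.0, 5.0),
                colormap: str = "viridis_r") -> Dict[str, Path]:
    """Write the map products: 32-bit float TIFFs, CSV rasters, and a PNG.

    The PNG renders the topography surface colored by elasticity with the
    default 0-5 kPa color scale (values above the scale are clamped in the
    rendering only; TIFF and CSV keep the unclamped data).
    """
    import tifffile
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    for name, rmap in (("topography", topography), ("elasticity", elasticity)):
        tif = out / f"{basename}_{name}.tif"
        tifffile.imwrite(tif, rmap.values.astype(np.float32))
        csv = out / f"{basename}_{name}.csv"
        np.savetxt(csv, rmap.values, delimiter=",", fmt="%.17g")
        paths[f"{name}_tiff"] = tif
        paths[f"{name}_csv"] = csv
    qc_csv = out / f"{basename}_qc.csv"
    np.savetxt(qc_csv, topography.qc_mask, delimiter=",", fmt="%s")
    paths["qc_csv"] = qc_csv

    dy, dx = topography.pixel_size_um
    rows, cols = topography.values.shape
    y = (np.arange(rows) + 0.5) * dy
    x = (np.arange(cols) + 0.5) * dx
    X, Y = np.meshgrid(x, y)
    Z = np.where(np.isfinite(topography.values), topography.values, 0.0) / 1000.0
    e_kPa = elasticity.values / 1000.0
    norm = colors.Normalize(*color_range_kPa, clip=True)
    shading = cm.get_cmap(colormap)(norm(np.where(np.isfinite(e_kPa), e_kPa,
                                                  color_range_kPa[1])))
    fig = plt.figure(figsize=(10, 4))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(X, Y, Z, facecolors=shading, rstride=1, cstride=1,
                    linewidth=0, antialiased=False, shade=False)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_zlabel("height (µm)")
    mappable = cm.ScalarMappable(norm=norm, cmap=colormap)
    fig.colorbar(mappable, ax=ax, shrink=0.6, label="E (kPa)")
    png = out / f"{basename}_surface.png"
    fig.savefig(png, dpi=120)
    plt.close(fig)
    paths["surface_png"] = png
    return paths
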