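"""Config-driven orchestration: simulate -> process -> stats -> report.

A pipeline run is a pure function of (config, seed): it writes a resolved
config snapshot, a structured log, per-map fit tables, group summaries, the
comparison grid and a human-readable report into one run directory, and is
byte-reproducible for fixed inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .config import AcquisitionConfig, ConfigError, FitConfig
from .curves import ForceVolume
from .forcemap import exclude_maps, export_maps, process_volume
from .io import read_volume
from .mixture import (DoubleGaussianFit, ElasticitySample, MixtureError,
                      aggregate_peaks, fit_double_gaussian, summary_table)
from .stats import compare_cohort, thickness_analysis
from .synthetic import GroupSpec, generate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage and offending map id."""

    def __init__(self, stage: str, map_id: str, message: str):
        self.stage = stage
        self.map_id = map_id
        super().__init__(f"stage {stage!r} failed on {map_id!r}: {message}")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``load_config``)."""

    acquisition: AcquisitionConfig
    fit: FitConfig
    groups: List[GroupSpec]
    stats: dict
    seed: int
    export_maps: bool = False

    @property
    def comparison_plan(self) -> List[Tuple[str, str]]:
        plan = self.stats.get("comparison_plan")
        if plan:
            return [tuple(p) for p in plan]
        labels = [g.label for g in self.groups]
        return [(labels[i], labels[j]) for i in range(len(labels))
                for j in range(i + 1, len(labels))]


def load_config(source: Union[str, Path, dict]) -> PipelineConfig:
    """Load and validate a pipeline config from YAML (path) or a dict."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("pipeline config must be a mapping")
    try:
        acquisition = AcquisitionConfig.from_dict(raw.get("acquisition", {}))
        fit = FitConfig.from_dict(raw.get("fit", {}))
        cohort = raw.get("cohort", {})
        groups = [GroupSpec(
            label=str(g["label"]), n_maps=int(g["n_maps"]),
            mixture=tuple(g.get("mixture", GroupSpec.__dataclass_fields__["mixture"].default)),
            diameter_mean_um=float(g.get("diameter_mean_um", 5.19)),
            diameter_sd_um=float(g.get("diameter_sd_um", 1.0)),
            diameter_floor_um=float(g.get("diameter_floor_um", 1.7)),
            substrate_modulus_Pa=float(g.get("substrate_modulus_Pa", 1.0e5)),
        ) for g in cohort.get("groups", [])]
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc
    if not groups:
        raise ConfigError("cohort.groups must define at least one group")
    stats = raw.get("stats", {})
    seed = int(raw.get("seed", acquisition.seed))
    return PipelineConfig(acquisition, fit, groups, stats, seed,
                          export_maps=bool(raw.get("export_maps", False)))


def _resolved_config_dict(cfg: PipelineConfig) -> dict:
    return {
        "seed": cfg.seed,
        "acquisition": cfg.acquisition.to_dict(),
        "fit": cfg.fit.to_dict(),
        "cohort": {"groups": [{
            "label": g.label, "n_maps": g.n_maps, "mixture": list(g.mixture),
            "diameter_mean_um": g.diameter_mean_um,
            "diameter_sd_um": g.diameter_sd_um,
            "diameter_floor_um": g.diameter_floor_um,
            "substrate_modulus_Pa": g.substrate_modulus_Pa,
        } for g in cfg.groups]},
        "stats": cfg.stats,
        "export_maps": cfg.export_maps,
    }


def process_map_file(path, fit_config: FitConfig,
                     stats_cfg: Optional[dict] = None):
    """Read, fit and summarize one stored force map.

    Returns (fit table, double-Gaussian fit, topography, elasticity).
    """
    stats_cfg = stats_cfg or {}
    volume, _ = read_volume(path)
    topo, emap, table = process_volume(volume, fit_config)
    sample = ElasticitySample(emap.ok_values, map_id=Path(path).stem)
    dg = fit_double_gaussian(
        sample,
        method=stats_cfg.get("method", "histogram_ls"),
        binning=stats_cfg.get("binning", "freedman_diaconis"),
        range_Pa=tuple(stats_cfg.get("range_Pa", (0.0, 10_000.0))),
        bin_width_Pa=stats_cfg.get("bin_width_Pa"))
    return table, dg, topo, emap


def ingest_external(paths: Sequence, metadata_overrides: Optional[dict] = None
                    ) -> List[ForceVolume]:
    """Validate and load externally produced HDF5 force volumes.

    ``metadata_overrides`` may carry ``spring_constant_pN_per_nm`` (e.g. a
    bench-measured calibration); the stored and overriding values are both
    logged. Malformed files raise naming the first offending dataset.
    """
    overrides = metadata_overrides or {}
    k_override = overrides.get("spring_constant_pN_per_nm")
    volumes = []
    for p in paths:
        volume, _ = read_volume(p, spring_constant_override_pN_per_nm=k_override)
        if k_override is not None:
            logger.info("ingest %s: spring constant overridden to %.3f pN/nm",
                        p, k_override)
        volumes.append(volume)
    return volumes


def run_pipeline(config: Union[str, Path, dict, PipelineConfig], out_dir,
                 seed: Optional[int] = None) -> Path:
    """Run the full desk-scale replication: simulate, process, stats, report.

    Returns the run directory containing ``cohort/`` (simulated maps),
    ``tables/`` (per-map fits, group summary, comparisons, thickness),
    ``report.md``, ``resolved_config.json`` and ``pipeline.log``.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    if seed is not None:
        cfg.seed = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)

    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("myoelast")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        (out / "resolved_config.json").write_text(
            json.dumps(_resolved_config_dict(cfg), indent=2, sort_keys=True))

        logger.info("stage simulate: %d groups, seed %d", len(cfg.groups),
                    cfg.seed)
        manifest = generate_cohort(cfg.groups, cfg.acquisition, out / "cohort",
                                   cfg.seed, cfg.fit.nu, cfg.fit.half_angle_deg,
                                   force=True)

        per_map_rows = []
        fits_by_group: Dict[str, List[DoubleGaussianFit]] = {}
        for group in manifest["groups"]:
            for entry in group["maps"]:
                map_id = entry["map_id"]
                path = out / "cohort" / "maps" / entry["file"]
                try:
                    table, dg, topo, emap = process_map_file(
                        path, cfg.fit, cfg.stats)
                except (MixtureError, OSError, ValueError) as exc:
                    raise PipelineError("process", map_id, str(exc)) from exc
                n_ok = int((table["status"] == "ok").sum())
                logger.info("stage process: map %s ok %d/%d, peaks "
                            "(%.0f, %.0f) Pa", map_id, n_ok, len(table),
                            dg.mu1_Pa, dg.mu2_Pa)
                table.insert(0, "map_id", map_id)
                per_map_rows.append((map_id, group["label"], table, dg))
                fits_by_group.setdefault(group["label"], []).append(dg)
                if cfg.export_maps:
                    export_maps(topo, emap, out / "maps", basename=map_id)

        fit_table = pd.concat([t for _, _, t, _ in per_map_rows],
                              ignore_index=True)
        fit_table.to_csv(out / "tables" / "per_pixel_fits.csv", index=False)
        pd.DataFrame([{
            "map_id": mid, "group": grp, "mu1_Pa": dg.mu1_Pa,
            "mu2_Pa": dg.mu2_Pa, "sigma1_Pa": dg.sigma1_Pa,
            "sigma2_Pa": dg.sigma2_Pa, "A1": dg.A1, "A2": dg.A2,
            "converged": dg.converged, "degenerate": dg.degenerate,
            "n_pixels": dg.n,
        } for mid, grp, _, dg in per_map_rows]).to_csv(
            out / "tables" / "per_map_peaks.csv", index=False)

        try:
            summaries = {label: aggregate_peaks(fits, label)
                         for label, fits in fits_by_group.items()}
        except MixtureError as exc:
            raise PipelineError("stats", "aggregate", str(exc)) from exc
        summary_table(summaries.values()).to_csv(
            out / "tables" / "group_summary.csv", index=False)

        plan = [p for p in cfg.comparison_plan
                if p[0] in summaries and p[1] in summaries]
        comparisons = compare_cohort(summaries, plan,
                                     alpha=float(cfg.stats.get("alpha", 0.05)))
        comparisons.to_csv(out / "tables" / "comparisons.csv", index=False)

        diameters = pd.read_csv(out / "cohort" / "diameters.csv")
        thick = thickness_analysis(
            {g: df["diameter_um"].to_numpy()
             for g, df in diameters.groupby("group")}
        ) if all(n >= 10 for n in diameters.groupby("group").size()) else None
        if thick is not None:
            thick.counts.to_csv(out / "tables" / "thickness.csv", index=False)

        _write_report(out, summaries, comparisons, thick)
        logger.info("pipeline complete: %s", out)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _write_report(out: Path, summaries, comparisons: pd.DataFrame,
                  thick) -> None:
    lines = ["# Force-volume cohort report", ""]
    lines.append("## Group peaks (mean ± SEM over maps)")
    for s in summaries.values():
        lines.append(
            f"- {s.group}: Peak 1 = {s.peak1_mean_Pa:.2f} ± "
            f"{s.peak1_sem_Pa:.2f} Pa, Peak 2 = {s.peak2_mean_Pa:.2f} ± "
            f"{s.peak2_sem_Pa:.2f} Pa (n = {s.n_maps})")
    lines.append("")
    lines.append("## Comparisons (Mann-Whitney, two-sided)")
    for _, row in comparisons.iterrows():
        lines.append(
            f"- {row['group_a']} vs {row['group_b']}: Peak 1 p = "
            f"{row['peak1_p']:.4f} ({row['peak1_stars']}), Peak 2 p = "
            f"{row['peak2_p']:.4f} ({row['peak2_stars']})")
    lines.append(f"\n{len(comparisons)} comparisons, no multiplicity "
                 "correction applied.")
    if thick is not None:
        lines.append("\n## Myotube widths")
        lines.append(f"Pooled median cut-off: {thick.median_um:.2f} µm")
        for _, row in thick.counts.iterrows():
            lines.append(
                f"- {row['group']}: Gaussian µ = {row['gaussian_mu_um']:.2f} "
                f"µm, σ = {row['gaussian_sigma_um']:.2f} µm; thin/wide = "
                f"{row['n_thin']}/{row['n_wide']}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
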