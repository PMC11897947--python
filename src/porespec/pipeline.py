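"""End-to-end orchestration: volume → masks → porosity → thickness →
pore network → permeability (voxel Stokes and PNM) → JSON report.

One :class:`PipelineConfig` drives the whole chain deterministically: the
same config and seed always produce the same report body (timings go to the
log, never into the report).  Flow is solved on a central interior cuboid
of the percolating pore space — specimens have closed outer surfaces, so
permeability is a property of the core pore network — for each requested
axis and with both methods, mirroring the paired FE/PNM reporting of μCT
permeability studies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_volume import (
    AXIS_INDEX,
    BinaryMask,
    VoxelVolume,
    read_volume,
    write_mask,
    write_report,
    write_volume,
)
from .pore_network import (
    component_stats,
    extract_network,
    pnm_solve,
    watershed_separate,
)
from .segmentation import (
    SegmentationParams,
    percolating_pore_space,
    porosity_percent,
    segment_volume,
)
from .stokes_flow import darcy_permeability, solve_stokes
from .synthetic_volume import SyntheticSpec, generate_sintered_packing
from .thickness import local_thickness, summarize_thickness

logger = logging.getLogger("porespec")

REPORT_VERSION = 1


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one of ``input_path`` / ``synthetic`` must be given.  ``axes``
    lists the flow directions to solve (z = build/longitudinal axis).
    ``flow_margin`` voxels are cropped from every face before the flow
    stages (default: the synthetic skin thickness + 2, or 4 for scanned
    input).
    """

    input_path: str | Path | None = None
    synthetic: SyntheticSpec | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    thickness_bin_width: float | None = None  # mm; default 1 voxel diameter
    marker_separation: int = 2  # voxels, watershed peak suppression
    axes: tuple[str, ...] = ("z", "x")
    delta_p: float = 1000.0  # Pa
    viscosity: float = 0.001  # Pa·s
    tol: float = 1e-5
    max_iter: int = 5000
    flow_margin: int | None = None
    output_dir: str | Path = "porespec_out"
    seed: int | None = None  # overrides synthetic.seed when given

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path / synthetic must be set")
        if not self.axes:
            raise ValueError("axes must be non-empty")
        for a in self.axes:
            if a not in AXIS_INDEX:
                raise ValueError(f"unknown axis {a!r}")
        if self.synthetic is not None and self.seed is not None:
            self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)


def _interior(mask: BinaryMask, margin: int) -> BinaryMask:
    if margin <= 0:
        return mask
    if 2 * margin >= min(mask.shape):
        raise ValueError(f"flow margin {margin} leaves no interior volume")
    sl = (slice(margin, -margin),) * 3
    return BinaryMask(mask.data[sl].copy(), mask.voxel_size, mask.role)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the report dictionary."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    volume = _stage("load")(_load)(cfg, out)
    material, envelope, pore = _stage("segment")(_segment)(cfg, volume, out)
    porosity = porosity_percent(pore, envelope)
    logger.info("porosity %.2f%%", porosity)

    thickness = _stage("thickness")(_thickness)(cfg, material, pore)
    clusters = _stage("pore_clusters")(_clusters)(cfg, pore, out)
    permeability = _stage("flow")(_flow)(cfg, pore)

    report = {
        "report_version": REPORT_VERSION,
        "axis_order": "zyx",
        "input": str(cfg.input_path) if cfg.input_path else "synthetic",
        "porosity_pct": float(porosity),
        "thickness": thickness,
        "pore_clusters": clusters,
        "permeability": permeability,
        "parameters": _parameters(cfg),
    }
    write_report(report, out / "report.json")
    return report


def _parameters(cfg: PipelineConfig) -> dict:
    par = {
        "threshold": cfg.segmentation.threshold,
        "closing_radius": cfg.segmentation.closing_radius,
        "marker_separation": cfg.marker_separation,
        "axes": list(cfg.axes),
        "delta_p_Pa": cfg.delta_p,
        "viscosity_Pa_s": cfg.viscosity,
        "tol": cfg.tol,
    }
    if cfg.synthetic is not None:
        par["synthetic"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg.synthetic).items()
        }
    return par


def _load(cfg: PipelineConfig, out: Path) -> VoxelVolume:
    if cfg.input_path is not None:
        return read_volume(cfg.input_path)
    vol = generate_sintered_packing(cfg.synthetic)
    write_volume(vol, out / "volume.tif")
    return vol


def _segment(cfg: PipelineConfig, vol: VoxelVolume, out: Path):
    material, envelope, pore = segment_volume(vol, cfg.segmentation)
    for mask, stem in ((material, "material"), (envelope, "closed_filled"), (pore, "pore")):
        write_mask(mask, out / f"mask_{stem}.tif")
    return material, envelope, pore


def _thickness(cfg: PipelineConfig, material: BinaryMask, pore: BinaryMask) -> dict:
    result = {}
    for phase, mask in (("material", material), ("pore", pore)):
        summary = summarize_thickness(local_thickness(mask), cfg.thickness_bin_width)
        result[phase] = {
            "peak_mm": float(summary.peak_center),
            "fwhm_mm": float(summary.fwhm),
        }
    return result


def _clusters(cfg: PipelineConfig, pore: BinaryMask, out: Path) -> dict:
    labeled = watershed_separate(pore, cfg.marker_separation)
    table = component_stats(labeled)
    table.to_csv(out / "pore_table.csv", index=False)
    return {
        "count": int(len(table)),
        "mean_volume_mm3": float(table["volume_mm3"].mean()),
        "median_volume_mm3": float(table["volume_mm3"].median()),
        "mean_aspect_ratio": float(table["aspect_ratio"].mean()),
        "table": "pore_table.csv",
    }


def _default_margin(cfg: PipelineConfig) -> int:
    if cfg.flow_margin is not None:
        return cfg.flow_margin
    if cfg.synthetic is not None:
        return cfg.synthetic.skin_voxels + 2
    return 4


def _flow(cfg: PipelineConfig, pore: BinaryMask) -> dict:
    core = _interior(pore, _default_margin(cfg))
    h = core.voxel_size * 1e-6
    results: dict[str, dict] = {}
    for axis in cfg.axes:
        perc = percolating_pore_space(core, axis)
        field_ = solve_stokes(
            perc, axis=axis, delta_p=cfg.delta_p, viscosity=cfg.viscosity,
            tol=cfg.tol, max_iter=cfg.max_iter,
        )
        fe = darcy_permeability(field_)

        labeled = watershed_separate(perc, cfg.marker_separation)
        net = extract_network(labeled, perc, axis)
        ax = AXIS_INDEX[axis]
        length = perc.shape[ax] * h
        area = (perc.data.size / perc.shape[ax]) * h * h
        pnm, _ = pnm_solve(
            net, domain_cross_section=area, domain_length=length, axis=axis,
            delta_p=cfg.delta_p, viscosity=cfg.viscosity,
        )
        results[axis] = {"FE": fe.as_dict(), "PNM": pnm.as_dict()}
        logger.info(
            "axis %s: FE k=%.3f d (tau %.3f), PNM k=%.3f d (tau %.3f)",
            axis, fe.k_darcy, fe.tortuosity, pnm.k_darcy, pnm.tortuosity,
        )
    return results


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a JSON file (schema: see docs)."""
    with open(path) as fh:
        raw = json.load(fh)
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = dict(raw["synthetic"])
        if "domain_shape" in syn:
            syn["domain_shape"] = tuple(syn["domain_shape"])
        raw["synthetic"] = SyntheticSpec(**syn)
    if "segmentation" in raw and raw["segmentation"] is not None:
        raw["segmentation"] = SegmentationParams(**raw["segmentation"])
    if "axes" in raw:
        raw["axes"] = tuple(raw["axes"])
    return PipelineConfig(**raw)
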