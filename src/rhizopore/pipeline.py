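"""Pipeline orchestration: simulate -> segment -> shells -> pores -> report.

Each stage writes its outputs under the run directory and records them (with
SHA-256 checksums, parameters, wall time and any warnings) in
``manifest.json``.  A re-run with the same configuration skips stages whose
outputs already exist unless forced, and a fixed configuration plus seed
reproduces every table byte for byte.
"""
from __future__ import annotations

import dataclasses
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io, metrics_report, pore_morphology, shell_partition
from .phases import REFERENCE
from .segmentation import CalibrationRegions, SegmentationError, segment_volume
from .synthetic_ct import SimulationResult, SyntheticSpec, simulate

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``synthetic`` (a SyntheticSpec; calibration regions and root
    seeds then come from the generator's ground truth) or ``input_volume``
    plus explicit ``calibration`` and ``seeds`` must be provided.
    """

    outdir: str | Path = "run"
    seed: int = 0
    sample: str = "S1"
    day: int = 0
    synthetic: SyntheticSpec | None = None
    input_volume: str | None = None
    input_sidecar: str | None = None
    calibration: CalibrationRegions | None = None
    seeds: np.ndarray | None = None
    voxel_size: float = 12.0
    median_radius: int = 3
    tolerance: float = 2.5
    margin_voxels: float = 1.0
    crop_mm: float = 0.24
    geometry: str = "box"
    class_bounds_um: tuple[float, float] = (24.0, 72.0)
    thickness_radius_step: float | None = 0.5
    schedule: shell_partition.ShellSchedule | None = None
    write_volumes: bool = True

    def validate(self) -> None:
        lo, hi = self.class_bounds_um
        if not 0 < lo < hi:
            raise ValueError("class bounds must be positive and ordered")
        if self.synthetic is None and self.input_volume is None:
            raise ValueError("either a synthetic spec or an input volume is required")

    def resolved_schedule(self) -> shell_partition.ShellSchedule:
        if self.schedule is not None:
            return self.schedule
        return shell_partition.ShellSchedule.default(self.voxel_size)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        kw = dict(raw)
        if "synthetic" in kw and kw["synthetic"] is not None:
            syn = dict(kw["synthetic"])
            if "shape" in syn:
                syn["shape"] = tuple(syn["shape"])
            kw["synthetic"] = SyntheticSpec(**syn)
        if kw.get("calibration"):
            kw["calibration"] = CalibrationRegions.from_dict(kw["calibration"])
        if kw.get("seeds") is not None:
            kw["seeds"] = np.asarray(kw["seeds"], dtype=int)
        if kw.get("class_bounds_um"):
            kw["class_bounds_um"] = tuple(kw["class_bounds_um"])
        return cls(**kw)


def _record(manifest, stage, outdir, files, t0, warns):
    manifest["stages"][stage] = {
        "files": {f: io.sha256_file(outdir / f) for f in files},
        "seconds": round(time.perf_counter() - t0, 3),
        "warnings": warns,
    }


def _catch(stage):
    class _Ctx:
        def __enter__(self):
            self._w = warnings.catch_warnings(record=True)
            self.records = self._w.__enter__()
            warnings.simplefilter("always")
            return self

        def __exit__(self, exc_type, exc, tb):
            self._w.__exit__(exc_type, exc, tb)
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(stage, str(exc)) from exc
            return False

        def messages(self):
            return [str(r.message) for r in self.records]

    return _Ctx()


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute every stage, returning the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = {"config": _config_dict(config), "stages": {}}
    prior = io.read_json(manifest_path) if manifest_path.exists() else None

    def done(stage, files):
        if force or prior is None or stage not in prior.get("stages", {}):
            return False
        entry = prior["stages"][stage]
        if set(entry["files"]) != set(files):
            return False
        ok = all((outdir / f).exists() for f in files)
        if ok:
            manifest["stages"][stage] = entry
        return ok

    # ---- simulate ---------------------------------------------------------
    stage_files = ["gray.tif", "truth_labels.tif", "sidecar.json"]
    sim: SimulationResult | None = None
    gray = None
    meta: dict = {}
    if config.synthetic is not None:
        spec = config.synthetic.replace(rng_seed=config.seed)
        with _catch("simulate") as ctx:
            t0 = time.perf_counter()
            if not done("simulate", stage_files):
                sim = simulate(spec)
                if config.write_volumes:
                    io.write_gray_tiff(outdir / "gray.tif", sim.gray)
                    io.write_label_tiff(outdir / "truth_labels.tif",
                                        sim.truth.phase_labels)
                else:
                    (outdir / "gray.tif").touch()
                    (outdir / "truth_labels.tif").touch()
                io.write_json(outdir / "sidecar.json", {
                    "voxel_size_um": spec.voxel_size,
                    "seed": config.seed,
                    "spec": dataclasses.asdict(spec),
                    "calibration": sim.calibration.to_dict(),
                    "seeds": sim.truth.axis_seeds,
                    "phase_codes": {"pore": 0, "solid": 1, "root": 2,
                                    "excluded": 3, "reference": 4},
                })
            else:
                sim = simulate(spec)  # cheap to regenerate; keeps memory path simple
            _record(manifest, "simulate", outdir, stage_files, t0, ctx.messages())
        gray = sim.gray
        calib = sim.calibration
        seeds = sim.truth.axis_seeds
        reference_mask = sim.truth.phase_labels == REFERENCE
        voxel_size = spec.voxel_size
    else:
        gray, meta = io.read_volume(config.input_volume, config.input_sidecar)
        gray = gray.astype(np.float32)
        calib = config.calibration
        seeds = config.seeds
        reference_mask = None
        voxel_size = config.voxel_size

    # ---- segment ----------------------------------------------------------
    with _catch("segment") as ctx:
        t0 = time.perf_counter()
        if calib is None:
            raise SegmentationError("no calibration regions in config")
        if seeds is None:
            raise SegmentationError("no root seed points in config")
        masks = segment_volume(
            gray, voxel_size, calib, seeds,
            median_radius=config.median_radius,
            tolerance=config.tolerance,
            margin_voxels=config.margin_voxels,
            crop_mm=config.crop_mm,
            geometry=config.geometry,
            reference_mask=reference_mask,
        )
        if config.write_volumes:
            io.write_label_tiff(outdir / "masks.tif", masks.to_labels())
        else:
            (outdir / "masks.tif").touch()
        _record(manifest, "segment", outdir, ["masks.tif"], t0, ctx.messages())

    # ---- shells -----------------------------------------------------------
    schedule = config.resolved_schedule()
    with _catch("shells") as ctx:
        t0 = time.perf_counter()
        shells = shell_partition.build_shells(masks.root, schedule,
                                              masks.analysis_region)
        discrete = shell_partition.shell_porosity(
            shells, masks, schedule, "discrete", config.sample, config.day)
        cumulative = shell_partition.shell_porosity(
            shells, masks, schedule, "cumulative", config.sample, config.day)
        named = shell_partition.named_region_porosity(
            shells, masks, schedule, config.sample, config.day)
        profile, objects = shell_partition.depth_profile(
            shells, masks, schedule, sample=config.sample, day=config.day,
            with_objects=False)
        if config.write_volumes:
            io.write_label_tiff(outdir / "shells.tif", shells)
        else:
            (outdir / "shells.tif").touch()
        files = ["shells.tif", "porosity_discrete.csv", "porosity_cumulative.csv",
                 "porosity_named.csv", "depth_profile.csv"]
        discrete.to_csv(outdir / "porosity_discrete.csv", index=False)
        cumulative.to_csv(outdir / "porosity_cumulative.csv", index=False)
        named.to_csv(outdir / "porosity_named.csv", index=False)
        profile.to_csv(outdir / "depth_profile.csv", index=False)
        _record(manifest, "shells", outdir, files, t0, ctx.messages())

    # ---- pores ------------------------------------------------------------
    with _catch("pores") as ctx:
        t0 = time.perf_counter()
        thickness = pore_morphology.local_thickness(
            masks.pore, voxel_size, radius_step=config.thickness_radius_step)
        named_masks = shell_partition.named_region_masks(shells, schedule)
        classes = pore_morphology.classify_pores(
            masks.pore, thickness, named_masks, voxel_size,
            config.sample, config.day, bounds_um=config.class_bounds_um)
        hist = pore_morphology.thickness_distribution(
            thickness, named_masks, voxel_size, sample=config.sample,
            day=config.day)
        rm = pore_morphology.root_metrics(masks.root, voxel_size,
                                          radius_step=config.thickness_radius_step)
        classes.to_csv(outdir / "pore_classes.csv", index=False)
        hist.to_csv(outdir / "thickness_hist.csv", index=False)
        io.write_json(outdir / "root_metrics.json", dataclasses.asdict(rm))
        files = ["pore_classes.csv", "thickness_hist.csv", "root_metrics.json"]
        if config.write_volumes:
            io.write_float_tiff(outdir / "thickness.tif", thickness)
            files.append("thickness.tif")
        _record(manifest, "pores", outdir, files, t0, ctx.messages())

    # ---- report -----------------------------------------------------------
    with _catch("report") as ctx:
        t0 = time.perf_counter()
        contrasts = metrics_report.surface_bulk_contrast(named)
        study = metrics_report.build_study_table(
            [discrete, named], [{"texture": "synthetic"}] * 2)
        contrasts.to_csv(outdir / "contrasts.csv", index=False)
        study.to_csv(outdir / "study_summary.csv", index=False)
        _record(manifest, "report", outdir,
                ["contrasts.csv", "study_summary.csv"], t0, ctx.messages())

    io.write_json(manifest_path, manifest)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["outdir"] = str(config.outdir)
    if config.calibration is not None:
        d["calibration"] = config.calibration.to_dict()
    if config.seeds is not None:
        d["seeds"] = np.asarray(config.seeds).tolist()
    if config.schedule is not None:
        d["schedule"] = {"boundaries": list(config.schedule.boundaries),
                         "inner_exclusion": config.schedule.inner_exclusion,
                         "voxel_size": config.schedule.voxel_size}
    return d
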