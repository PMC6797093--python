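"""Declarative end-to-end pipeline: enhance -> tile -> detect -> fuse -> evaluate.

A single config (YAML or a plain nested dict) describes every flight
altitude (mosaic path, ground resolution, tiling and merge parameters,
optional ground truth and the transform into the reference altitude's
frame), the enhancement variants to run, and the detector backend.
:func:`run_pipeline` executes all stages in order, writes every
intermediate artifact under the output directory, and returns a run report
with per-stage counts; a ``manifest.json`` (config echo, package version,
seed, counts) makes the run reproducible and auditable.

Detector backends:

* ``reference`` — the classical TGI-threshold detector. Three-band variant
  tiles are first reduced to an 8-bit TGI band (mosaic-level min-max), so
  the detector can run on any variant.
* ``csv`` — externally produced per-tile detections (e.g. from a trained
  CNN), one CSV per (altitude, variant).
* ``simulated`` — the stochastic detector model of
  :mod:`bananacount.synthetic` (requires ground truth).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .detection import DetectionSet, DetectorConfig, detect_reference, load_detections, save_detections
from .enhancement import (
    SCTSpec,
    StretchSpec,
    linear_contrast_stretch,
    synthetic_color_transform,
    tgi_broadband,
    to_eight_bit,
)
from .evaluation import MatchSpec, compute_metrics, load_ground_truth, match_points
from .fusion import (
    AltitudeTransform,
    MergeSpec,
    fuse_altitudes,
    fuse_variants,
    save_plant_points,
)
from .raster import RasterImage, read_raster, write_raster
from .synthetic import SimDetectorSpec, simulate_detections
from .tiling import Tile, extract_tiles, plan_grid

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AltitudeEntry", "run_pipeline"]

DEFAULT_MERGE_THRESHOLDS = {"40m": 30.0, "50m": 25.0, "60m": 20.0}


@dataclasses.dataclass
class AltitudeEntry:
    """One flight altitude's inputs and parameters."""

    mosaic: str
    resolution_cm_per_px: float | None = None
    tile_size: int = 600
    overlap: int = 50
    merge_threshold_px: float = 30.0
    ground_truth: str | None = None
    transform: AltitudeTransform = dataclasses.field(default_factory=AltitudeTransform)


@dataclasses.dataclass
class PipelineConfig:
    """Full pipeline description; see the module docstring."""

    altitudes: dict[str, AltitudeEntry]
    reference_altitude: str
    variants: tuple[str, ...] = ("LCS", "SCT", "TGI")
    detector_backend: str = "reference"
    detector: DetectorConfig = dataclasses.field(default_factory=DetectorConfig)
    detector_csv_paths: dict = dataclasses.field(default_factory=dict)
    sim_detector: SimDetectorSpec | None = None
    stretch: StretchSpec = dataclasses.field(default_factory=StretchSpec)
    sct: SCTSpec = dataclasses.field(default_factory=SCTSpec)
    tgi_8bit_mode: str = "per_image_minmax"
    cross_altitude_threshold_px: float = 30.0
    evaluation_radius_px: float = 30.0
    output_dir: str = "bananacount_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_altitude not in self.altitudes:
            raise ValueError(
                f"reference altitude {self.reference_altitude!r} has no altitude entry"
            )
        if self.cross_altitude_threshold_px <= 0 or self.evaluation_radius_px <= 0:
            raise ValueError("thresholds must be positive")
        if self.detector_backend not in ("reference", "csv", "simulated"):
            raise ValueError("detector_backend must be reference, csv or simulated")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        alts = {}
        for tag, entry in raw.pop("altitudes").items():
            entry = dict(entry)
            t = entry.pop("transform", None)
            transform = AltitudeTransform(**t) if t else AltitudeTransform()
            alts[tag] = AltitudeEntry(transform=transform, **entry)
        det = raw.pop("detector", None)
        sim = raw.pop("sim_detector", None)
        kwargs: dict[str, Any] = dict(raw)
        kwargs["altitudes"] = alts
        if det:
            kwargs["detector"] = DetectorConfig(**det)
        if sim:
            kwargs["sim_detector"] = SimDetectorSpec(**sim)
        if "variants" in kwargs:
            kwargs["variants"] = tuple(kwargs["variants"])
        stretch = raw.pop("stretch", None)
        if stretch:
            kwargs["stretch"] = StretchSpec(**stretch)
        sct = raw.pop("sct", None)
        if sct:
            kwargs["sct"] = SCTSpec(**sct)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _green_band(img: RasterImage) -> RasterImage:
    return RasterImage(
        img.band(1).copy(),
        resolution_cm_per_px=img.resolution_cm_per_px,
        altitude_m=img.altitude_m,
    )


def make_variant(img: RasterImage, variant: str, cfg: PipelineConfig) -> RasterImage:
    """Produce one enhancement variant of the mosaic."""
    if variant == "RGB":
        return img
    if variant == "LCS":
        return linear_contrast_stretch(img, cfg.stretch)
    if variant == "SCT":
        return synthetic_color_transform(_green_band(img), cfg.sct)
    if variant == "TGI":
        return to_eight_bit(tgi_broadband(img), mode=cfg.tgi_8bit_mode)
    raise ValueError(f"unknown variant {variant!r}")


def _detect_tiles_reference(
    variant_img: RasterImage, tiles: list[Tile], variant: str, altitude: str, cfg: PipelineConfig
) -> DetectionSet:
    records = []
    for tile in tiles:
        boxes = detect_reference(tile, cfg.detector)
        records.extend((tile.name, b) for b in boxes)
    return DetectionSet(records, variant_tag=variant, altitude_tag=altitude)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run report (also on disk).

    Stage outputs are pure functions of (inputs, config, seed): re-running
    the same config reproduces identical CSVs. Any stage failure aborts
    with the stage and offending input in the raised error.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "altitudes": {},
    }
    points_per_altitude: dict[str, list] = {}
    transforms: dict[str, AltitudeTransform] = {}
    gt_by_altitude: dict[str, Any] = {}

    for alt, entry in config.altitudes.items():
        alt_report: dict[str, Any] = {}
        try:
            mosaic = read_raster(
                entry.mosaic, resolution_cm_per_px=entry.resolution_cm_per_px
            )
        except Exception as exc:
            raise RuntimeError(f"stage=read altitude={alt} input={entry.mosaic}: {exc}") from exc
        grid = plan_grid(mosaic.width, mosaic.height, entry.tile_size, entry.overlap)
        alt_report["mosaic"] = [mosaic.width, mosaic.height]
        alt_report["tiles"] = grid.n_tiles

        gt = load_ground_truth(entry.ground_truth) if entry.ground_truth else None
        gt_by_altitude[alt] = gt

        det_sets: list[DetectionSet] = []
        alt_dir = out / alt
        alt_dir.mkdir(exist_ok=True)
        for variant in config.variants:
            try:
                if config.detector_backend == "csv":
                    path = config.detector_csv_paths[alt][variant]
                    dset = load_detections(path, variant, alt, tile_size=entry.tile_size)
                elif config.detector_backend == "simulated":
                    if gt is None:
                        raise ValueError("simulated backend needs ground_truth")
                    sim = config.sim_detector or SimDetectorSpec(seed=config.seed)
                    dset = simulate_detections(gt, grid, sim, variant, altitude_tag=alt)
                else:
                    vimg = make_variant(mosaic, variant, config)
                    write_raster(vimg, alt_dir / f"variant_{variant}.png")
                    det_img = (
                        vimg
                        if vimg.n_bands == 1
                        else to_eight_bit(tgi_broadband(vimg), mode=config.tgi_8bit_mode)
                    )
                    tiles = extract_tiles(det_img, grid)
                    dset = _detect_tiles_reference(det_img, tiles, variant, alt, config)
            except Exception as exc:
                raise RuntimeError(
                    f"stage=detect altitude={alt} variant={variant}: {exc}"
                ) from exc
            save_detections(dset, alt_dir / f"detections_{variant}.csv")
            alt_report.setdefault("boxes", {})[variant] = len(dset)
            det_sets.append(dset)

        merged = fuse_variants(det_sets, grid, MergeSpec(entry.merge_threshold_px))
        save_plant_points(merged, alt_dir / "plant_points.csv")
        alt_report["plants"] = len(merged)

        if gt is not None:
            res = match_points(merged, gt, MatchSpec(config.evaluation_radius_px))
            metrics = compute_metrics(res.tp, len(merged), gt.count)
            r, p, o = metrics.rounded()
            alt_report["metrics"] = dict(
                correct=res.tp,
                all_detected=len(merged),
                gt=gt.count,
                recall=r,
                precision=p,
                overall_accuracy=o,
            )
        points_per_altitude[alt] = merged
        transforms[alt] = entry.transform
        report["altitudes"][alt] = alt_report

    if len(points_per_altitude) > 1:
        fused = fuse_altitudes(
            points_per_altitude,
            transforms,
            config.reference_altitude,
            MergeSpec(config.cross_altitude_threshold_px),
        )
        save_plant_points(fused, out / "plant_points_cross_altitude.csv")
        report["cross_altitude"] = {"plants": len(fused)}
        ref_gt = gt_by_altitude.get(config.reference_altitude)
        if ref_gt is not None:
            res = match_points(fused, ref_gt, MatchSpec(config.evaluation_radius_px))
            metrics = compute_metrics(res.tp, len(fused), ref_gt.count)
            r, p, o = metrics.rounded()
            report["cross_altitude"]["metrics"] = dict(
                correct=res.tp,
                all_detected=len(fused),
                gt=ref_gt.count,
                recall=r,
                precision=p,
                overall_accuracy=o,
            )

    manifest = dict(report)
    manifest["config"] = _config_echo(config)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report


def _config_echo(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, frozenset):
            return sorted(obj)
        return obj

    return enc(config)
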