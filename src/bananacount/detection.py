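"""Per-tile detector contract, detection I/O, and a classical reference detector.

The pipeline is detector-agnostic: anything that emits per-tile bounding
boxes fits. A trained CNN detector (e.g. Faster-RCNN) runs externally and
its per-tile outputs are ingested from CSV or VOC-style XML. For running the
full pipeline without any trained model, :func:`detect_reference` provides a
classical detector that thresholds an 8-bit TGI tile and extracts connected
components — TGI isolates high-chlorophyll pixels, so on imagery with clear
canopy/grass contrast the bright components are the plants.

:class:`DetectorConfig` also carries the settings a wrapped CNN detector is
expected to run with (IoU threshold 0.5, at most 300 proposals after its own
non-maximum suppression); those are pass-through configuration for external
backends, not used by the reference detector's component analysis.
"""

from __future__ import annotations

import dataclasses
import logging
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .tiling import Tile, tile_origin_from_name

logger = logging.getLogger(__name__)

__all__ = [
    "BoundingBox",
    "DetectionSet",
    "DetectorConfig",
    "detect_reference",
    "load_detections",
    "load_voc_xml",
    "save_detections",
]


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in tile pixel coordinates with a confidence score."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    score: float = 1.0
    label: str = "banana"

    def __post_init__(self) -> None:
        if not (0 <= self.xmin < self.xmax):
            raise ValueError(f"need 0 <= xmin < xmax, got [{self.xmin}, {self.xmax})")
        if not (0 <= self.ymin < self.ymax):
            raise ValueError(f"need 0 <= ymin < ymax, got [{self.ymin}, {self.ymax})")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclasses.dataclass
class DetectionSet:
    """Per-tile boxes from one detector run on one variant at one altitude."""

    records: list[tuple[str, BoundingBox]]
    variant_tag: str = "RGB"
    altitude_tag: str = ""

    def __post_init__(self) -> None:
        for name, _ in self.records:
            tile_origin_from_name(name)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DetectionSet):
            return NotImplemented
        return (
            sorted(self.records, key=lambda r: (r[0], r[1].xmin, r[1].ymin))
            == sorted(other.records, key=lambda r: (r[0], r[1].xmin, r[1].ymin))
            and self.variant_tag == other.variant_tag
            and self.altitude_tag == other.altitude_tag
        )


@dataclasses.dataclass(frozen=True)
class DetectorConfig:
    """Detector settings.

    ``iou_threshold`` and ``max_detections`` mirror the configuration an
    external CNN detector runs with (duplicate suppression at IoU 0.5, at
    most 300 proposals); ``tgi_threshold``, ``min_area_px`` and
    ``max_area_px`` drive the classical reference detector. ``n_anchors``
    is metadata for users wiring in an anchor-based model.
    """

    score_threshold: float = 0.0
    iou_threshold: float = 0.5
    max_detections: int = 300
    min_area_px: int = 100
    max_area_px: int = 4000
    tgi_threshold: int = 200
    n_anchors: int = 12

    def __post_init__(self) -> None:
        if not 0 <= self.min_area_px < self.max_area_px:
            raise ValueError("need 0 <= min_area_px < max_area_px")
        if not 0.0 <= self.iou_threshold <= 1.0:
            raise ValueError("iou_threshold must lie in [0, 1]")
        if not 0 <= self.tgi_threshold <= 255:
            raise ValueError("tgi_threshold must lie in [0, 255]")


# 4-connectivity: components touch only through edges, not corners.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def detect_reference(tile: Tile, cfg: DetectorConfig = DetectorConfig()) -> list[BoundingBox]:
    """Threshold-and-label detector on a single-band 8-bit TGI tile.

    Pixels at or above ``cfg.tgi_threshold`` are foreground; 4-connected
    components with area in ``[min_area_px, max_area_px]`` become boxes
    (tight extents), scored by mean component intensity / 255, capped at
    ``max_detections`` by descending score. Deterministic: ties in score are
    broken by box position.
    """
    px = tile.pixels
    if px.ndim != 2:
        raise ValueError("detect_reference expects a single-band (TGI) tile")
    mask = px >= cfg.tgi_threshold
    labels, n = ndimage.label(mask, structure=_CROSS)
    if n == 0:
        return []
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    boxes = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        area = areas[lab - 1]
        if area < cfg.min_area_px or area > cfg.max_area_px:
            continue
        ys, xs = sl
        comp = labels[sl] == lab
        score = float(px[sl][comp].mean() / 255.0)
        if score < cfg.score_threshold:
            continue
        boxes.append(
            BoundingBox(
                xmin=float(xs.start),
                ymin=float(ys.start),
                xmax=float(xs.stop),
                ymax=float(ys.stop),
                score=score,
            )
        )
    boxes.sort(key=lambda b: (-b.score, b.xmin, b.ymin))
    return boxes[: cfg.max_detections]


_CSV_COLUMNS = ["tile_name", "xmin", "ymin", "xmax", "ymax", "score"]


def save_detections(dset: DetectionSet, path: str | Path) -> None:
    """Write a detection set as CSV: tile_name,xmin,ymin,xmax,ymax,score."""
    rows = [
        dict(tile_name=name, xmin=b.xmin, ymin=b.ymin, xmax=b.xmax, ymax=b.ymax, score=b.score)
        for name, b in dset.records
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def load_detections(
    path: str | Path,
    variant_tag: str = "RGB",
    altitude_tag: str = "",
    tile_size: int = 600,
) -> DetectionSet:
    """Load per-tile detections from CSV, rejecting invalid records.

    A record whose box violates ``0 <= min < max <= tile_size`` (or whose
    tile name does not parse) is dropped with a logged line number rather
    than aborting the load.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"detections CSV missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        try:
            tile_origin_from_name(row.tile_name)
            box = BoundingBox(
                xmin=float(row.xmin),
                ymin=float(row.ymin),
                xmax=float(row.xmax),
                ymax=float(row.ymax),
                score=float(getattr(row, "score", 1.0)),
            )
            if box.xmax > tile_size or box.ymax > tile_size:
                raise ValueError(f"box exceeds tile size {tile_size}")
        except ValueError as exc:
            logger.warning("%s line %d: rejected record (%s)", path, lineno, exc)
            continue
        records.append((row.tile_name, box))
    return DetectionSet(records, variant_tag=variant_tag, altitude_tag=altitude_tag)


def load_voc_xml(
    paths: list[str | Path] | str | Path,
    variant_tag: str = "RGB",
    altitude_tag: str = "",
) -> DetectionSet:
    """Ingest VOC-style per-tile annotation XML files.

    The tile name is taken from the XML ``filename`` element (stem) or,
    failing that, the file's own stem. Boxes come from
    ``object/bndbox/{xmin,ymin,xmax,ymax}``; missing scores default to 1.
    """
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        paths = sorted(p.glob("*.xml")) if p.is_dir() else [p]
    records = []
    for path in paths:
        path = Path(path)
        root = ET.parse(path).getroot()
        fname = root.findtext("filename") or path.name
        name = Path(fname).stem
        tile_origin_from_name(name)
        for obj in root.iter("object"):
            bb = obj.find("bndbox")
            if bb is None:
                continue
            records.append(
                (
                    name,
                    BoundingBox(
                        xmin=float(bb.findtext("xmin")),
                        ymin=float(bb.findtext("ymin")),
                        xmax=float(bb.findtext("xmax")),
                        ymax=float(bb.findtext("ymax")),
                        score=float(obj.findtext("score") or 1.0),
                        label=obj.findtext("name") or "banana",
                    ),
                )
            )
    return DetectionSet(records, variant_tag=variant_tag, altitude_tag=altitude_tag)
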