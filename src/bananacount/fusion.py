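"""Centroid fusion of detections across variants, tiles and altitudes.

Running several detectors (one per enhancement variant) over overlapping
tiles finds more plants than any single run, but also detects the same
plant many times — in several variants, and in both tiles of an overlap
band. Both problems are solved the same way: every bounding box is reduced
to its centroid, centroids are restored to mosaic coordinates using the
tile-name offsets, and centroids closer than a per-altitude Euclidean
threshold (30/25/20 px at 40/50/60 m — just under the closest plant
spacing) are merged into one plant point.

Merging is single-linkage: clusters are connected components of the graph
joining any two centroids within the threshold, and each cluster is
replaced by the arithmetic mean of its members. The same merge, after a
per-axis linear transform ``x' = x * scale + shift`` into the reference
altitude's pixel frame, combines the plant points of several flight
altitudes (threshold 30 px in the reference frame).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .detection import BoundingBox, DetectionSet
from .tiling import TileGrid, tile_origin_from_name

__all__ = [
    "PlantPoint",
    "AltitudeTransform",
    "MergeSpec",
    "box_centroid",
    "to_mosaic_coords",
    "merge_within",
    "fuse_variants",
    "transform_points",
    "fuse_altitudes",
    "estimate_transform",
]

#: Default merge thresholds (px) per flight altitude, and across altitudes.
DEFAULT_THRESHOLDS = {"40m": 30.0, "50m": 25.0, "60m": 20.0, "cross": 30.0}


@dataclasses.dataclass(frozen=True)
class PlantPoint:
    """A (possibly merged) plant centroid in mosaic pixel coordinates.

    ``sources`` records the contributing (variant_tag, altitude_tag) pairs;
    ``members`` counts every original centroid merged into this point.
    """

    x: float
    y: float
    sources: frozenset = frozenset()
    members: int = 1

    def __post_init__(self) -> None:
        if self.members < 1:
            raise ValueError("members must be >= 1")


@dataclasses.dataclass(frozen=True)
class AltitudeTransform:
    """Per-axis linear map into the reference altitude's pixel frame.

    ``x' = x * x_scale + x_shift``; ``y' = y * y_scale + y_shift``. Scale
    factors are ratios of region-of-interest dimensions (e.g. 10032/7877
    for 50 m -> 40 m); shifts absorb the lateral offset between mosaics.
    """

    x_scale: float = 1.0
    y_scale: float = 1.0
    x_shift: float = 0.0
    y_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.x_scale <= 0 or self.y_scale <= 0:
            raise ValueError("scale factors must be positive")

    @classmethod
    def identity(cls) -> "AltitudeTransform":
        return cls()


@dataclasses.dataclass(frozen=True)
class MergeSpec:
    """Euclidean distance threshold (px) for centroid merging."""

    threshold_px: float = 30.0

    def __post_init__(self) -> None:
        if self.threshold_px <= 0:
            raise ValueError("threshold_px must be positive")


def box_centroid(box: BoundingBox) -> tuple[float, float]:
    """Centre of a bounding box: ((xmin+xmax)/2, (ymin+ymax)/2)."""
    return ((box.xmin + box.xmax) / 2.0, (box.ymin + box.ymax) / 2.0)


def to_mosaic_coords(
    point: tuple[float, float], tile_origin: tuple[int, int]
) -> tuple[float, float]:
    """Restore a tile-frame point to mosaic coordinates by adding the origin."""
    return (point[0] + tile_origin[0], point[1] + tile_origin[1])


def _as_points(points: Iterable) -> list[PlantPoint]:
    out = []
    for p in points:
        if isinstance(p, PlantPoint):
            out.append(p)
        else:
            out.append(PlantPoint(float(p[0]), float(p[1])))
    return out


def merge_within(points: Iterable, spec: MergeSpec) -> list[PlantPoint]:
    """Single-linkage merge of centroids within a Euclidean threshold.

    Clusters are the connected components of the graph with an edge between
    any two points at distance <= ``spec.threshold_px``; each output point
    is the arithmetic mean of its cluster, ``sources`` the union of member
    sources and ``members`` the total merged centroid count. The result is
    independent of input order (cluster means are accumulated in a fixed
    coordinate-sorted order) and is returned sorted by (y, x).

    Accepts :class:`PlantPoint` instances or plain ``(x, y)`` pairs.
    """
    pts = _as_points(points)
    n = len(pts)
    if n == 0:
        return []
    coords = np.array([(p.x, p.y) for p in pts], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("point coordinates must be finite")

    # union-find over KD-tree neighbour pairs
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(r=spec.threshold_px):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    merged = []
    for idxs in clusters.values():
        idxs = sorted(idxs, key=lambda i: (coords[i, 0], coords[i, 1]))
        xy = coords[idxs]
        sources = frozenset().union(*(pts[i].sources for i in idxs))
        merged.append(
            PlantPoint(
                x=float(xy[:, 0].mean()),
                y=float(xy[:, 1].mean()),
                sources=sources,
                members=sum(pts[i].members for i in idxs),
            )
        )
    merged.sort(key=lambda p: (p.y, p.x))
    return merged


def restore_centroids(dset: DetectionSet) -> list[PlantPoint]:
    """Per-tile box centroids restored to mosaic coordinates, tagged by source."""
    src = frozenset({(dset.variant_tag, dset.altitude_tag)})
    pts = []
    for name, box in dset.records:
        x, y = to_mosaic_coords(box_centroid(box), tile_origin_from_name(name))
        pts.append(PlantPoint(x, y, sources=src))
    return pts


def fuse_variants(
    sets: Sequence[DetectionSet], grid: TileGrid, spec: MergeSpec
) -> list[PlantPoint]:
    """Merge the detections of several enhancement variants at one altitude.

    Pools the restored centroids of all variants (and all tiles, including
    duplicate detections in overlap bands) and applies :func:`merge_within`;
    the output length is the altitude's final plant count.
    """
    if not sets:
        return []
    altitudes = {s.altitude_tag for s in sets}
    if len(altitudes) > 1:
        raise ValueError(f"fuse_variants got mixed altitudes: {sorted(altitudes)}")
    pooled: list[PlantPoint] = []
    for dset in sets:
        for name, box in dset.records:
            origin = tile_origin_from_name(name)
            if origin[0] >= grid.width or origin[1] >= grid.height:
                raise ValueError(f"tile {name} lies outside the {grid.width}x{grid.height} grid")
        pooled.extend(restore_centroids(dset))
    return merge_within(pooled, spec)


def transform_points(points: Iterable, t: AltitudeTransform) -> list[PlantPoint]:
    """Apply the per-axis linear altitude transform to plant points."""
    out = []
    for p in _as_points(points):
        out.append(
            dataclasses.replace(
                p, x=p.x * t.x_scale + t.x_shift, y=p.y * t.y_scale + t.y_shift
            )
        )
    return out


def fuse_altitudes(
    points_per_altitude: Mapping[str, Sequence],
    transforms: Mapping[str, AltitudeTransform],
    reference: str,
    spec: MergeSpec = MergeSpec(30.0),
) -> list[PlantPoint]:
    """Merge plant points from several altitudes in the reference frame.

    Every non-reference point set is mapped through its transform into the
    reference altitude's pixel frame, pooled with the reference set, and
    merged with :func:`merge_within`. A missing transform is an error; the
    reference's own transform defaults to identity.
    """
    if reference not in points_per_altitude:
        raise ValueError(f"reference altitude {reference!r} not among inputs")
    pooled: list[PlantPoint] = []
    for alt, pts in points_per_altitude.items():
        if alt == reference:
            t = transforms.get(alt, AltitudeTransform.identity())
        else:
            if alt not in transforms:
                raise ValueError(f"no transform to reference for altitude {alt!r}")
            t = transforms[alt]
        pooled.extend(transform_points(pts, t))
    return merge_within(pooled, spec)


def save_plant_points(points: Sequence[PlantPoint], path) -> None:
    """Write plant points as CSV: x,y,members,sources.

    Sources are serialized ``variant@altitude`` joined by ``;``.
    """
    import pandas as pd

    rows = [
        dict(
            x=p.x,
            y=p.y,
            members=p.members,
            sources=";".join(sorted(f"{v}@{a}" for v, a in p.sources)),
        )
        for p in points
    ]
    pd.DataFrame(rows, columns=["x", "y", "members", "sources"]).to_csv(path, index=False)


def load_plant_points(path) -> list[PlantPoint]:
    """Read plant points from the CSV written by :func:`save_plant_points`."""
    import pandas as pd

    df = pd.read_csv(path)
    points = []
    for row in df.itertuples(index=False):
        raw = getattr(row, "sources", "")
        sources = frozenset(
            tuple(item.split("@", 1)) for item in str(raw).split(";") if item and item != "nan"
        )
        points.append(
            PlantPoint(
                float(row.x), float(row.y), sources=sources, members=int(getattr(row, "members", 1))
            )
        )
    return points


def estimate_transform(
    src: Sequence[tuple[float, float]], dst: Sequence[tuple[float, float]]
) -> AltitudeTransform:
    """Least-squares scale+shift fit from >= 2 corresponding point pairs.

    Fits ``x' = a x + b`` and ``y' = c y + d`` independently. A convenience
    for users registering mosaics from control points instead of supplying
    the transform directly.
    """
    src_a = np.asarray(src, dtype=float)
    dst_a = np.asarray(dst, dtype=float)
    if src_a.shape != dst_a.shape or src_a.ndim != 2 or src_a.shape[0] < 2:
        raise ValueError("need >= 2 corresponding (x, y) pairs of equal count")
    ax, bx = np.polyfit(src_a[:, 0], dst_a[:, 0], 1)
    ay, by = np.polyfit(src_a[:, 1], dst_a[:, 1], 1)
    return AltitudeTransform(x_scale=ax, y_scale=ay, x_shift=bx, y_shift=by)
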