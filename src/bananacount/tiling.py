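"""Deterministic overlap tiling of a mosaic into fixed-size tiles.

A detector sees 600x600 px windows, cut in a grid with stride
``tile_size - overlap`` (default 550 when tiling a region of interest with
the 50 px overlap, so plants on tile edges appear whole in the neighbouring
tile). Tile names encode the pixel offset of the tile's top-left corner —
``tile_{x}_{y}`` — which is what lets per-tile detections be restored to
mosaic coordinates later. Edge tiles are zero-padded to full size so a
detector always receives fixed-size input.

Coordinates are 0-based, x = column, y = row, origin at top-left; a tile
covers the half-open window ``[x, x + tile_size) x [y, y + tile_size)``.
"""

from __future__ import annotations

import dataclasses
import math
import re
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image

from .raster import RasterImage

__all__ = [
    "TileGrid",
    "Tile",
    "plan_grid",
    "extract_tiles",
    "tile_name",
    "tile_origin_from_name",
    "write_tiles",
    "read_manifest",
]

_NAME_RE = re.compile(r"^tile_(\d+)_(\d+)$")


@dataclasses.dataclass(frozen=True)
class TileGrid:
    """Tiling plan for a mosaic of ``width x height`` pixels."""

    width: int
    height: int
    tile_size: int = 600
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("mosaic dimensions must be positive")
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if not 0 <= self.overlap < self.tile_size:
            raise ValueError("need 0 <= overlap < tile_size")

    @property
    def stride(self) -> int:
        return self.tile_size - self.overlap

    @property
    def nx(self) -> int:
        return math.ceil(self.width / self.stride)

    @property
    def ny(self) -> int:
        return math.ceil(self.height / self.stride)

    @property
    def n_tiles(self) -> int:
        return self.nx * self.ny

    def origins(self) -> Iterator[tuple[int, int]]:
        """Tile origins in row-major order (y outer, x inner)."""
        for iy in range(self.ny):
            for ix in range(self.nx):
                yield ix * self.stride, iy * self.stride


@dataclasses.dataclass
class Tile:
    """One fixed-size window of the mosaic, zero-padded beyond the edge."""

    name: str
    origin: tuple[int, int]
    pixels: np.ndarray
    padded: bool = False


def plan_grid(width: int, height: int, tile_size: int = 600, overlap: int = 0) -> TileGrid:
    """Plan the tile grid covering the full ``width x height`` extent.

    Origins along each axis are ``{k * stride : k = 0 .. n-1}`` with
    ``n = ceil(dim / stride)``, so every mosaic pixel is covered by at least
    one tile; the total tile count is ``nx * ny`` (e.g. 247 tiles for a
    10032 x 7048 mosaic with 600 px tiles and 50 px overlap).
    """
    return TileGrid(width, height, tile_size, overlap)


def tile_name(x: int, y: int) -> str:
    return f"tile_{x}_{y}"


def tile_origin_from_name(name: str) -> tuple[int, int]:
    """Recover the (x, y) pixel origin encoded in a tile name."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"malformed tile name: {name!r} (expected 'tile_<x>_<y>')")
    return int(m.group(1)), int(m.group(2))


def extract_tiles(img: RasterImage, grid: TileGrid) -> list[Tile]:
    """Cut the mosaic into tiles per the grid plan, row-major order."""
    if (img.width, img.height) != (grid.width, grid.height):
        raise ValueError(
            f"image is {img.width}x{img.height} but grid expects "
            f"{grid.width}x{grid.height}"
        )
    px = img.pixels
    ts = grid.tile_size
    tiles = []
    for x, y in grid.origins():
        w = min(ts, grid.width - x)
        h = min(ts, grid.height - y)
        window = px[y : y + h, x : x + w]
        padded = (w < ts) or (h < ts)
        if padded:
            shape = (ts, ts) if px.ndim == 2 else (ts, ts, px.shape[2])
            block = np.zeros(shape, dtype=px.dtype)
            block[:h, :w] = window
        else:
            block = window.copy()
        tiles.append(Tile(name=tile_name(x, y), origin=(x, y), pixels=block, padded=padded))
    return tiles


def write_tiles(tiles: list[Tile], outdir: str | Path, fmt: str = "jpg") -> Path:
    """Write tiles as ``tile_{x}_{y}.<fmt>`` plus a CSV grid manifest.

    Returns the manifest path. Single-band tiles are written as grayscale.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in tiles:
        Image.fromarray(t.pixels).save(outdir / f"{t.name}.{fmt}")
        rows.append(
            dict(
                name=t.name,
                x=t.origin[0],
                y=t.origin[1],
                width=t.pixels.shape[1],
                height=t.pixels.shape[0],
                padded=int(t.padded),
            )
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for name in df["name"]:
        tile_origin_from_name(name)  # validates
    return df
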