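"""8-bit raster container and file I/O.

The mosaic and every enhancement variant are plain 8-bit grids: a single
band or three bands stored in R, G, B order. TIFF (including GeoTIFF, whose
georeferencing tags are carried through untouched) is handled by tifffile;
PNG and JPEG by Pillow.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

#: Tag codes carrying GeoTIFF georeferencing; copied verbatim on write.
_GEO_TAG_CODES = (33550, 33922, 34264, 34735, 34736, 34737, 42112, 42113)

VARIANT_TAGS = ("RGB", "LCS", "SCT", "TGI")


@dataclasses.dataclass
class RasterImage:
    """An 8-bit single- or 3-band image with optional flight metadata.

    Parameters
    ----------
    pixels
        ``(H, W)`` or ``(H, W, 3)`` array of digital numbers (DN) in
        [0, 255]; 3-band images store bands in R, G, B order.
    resolution_cm_per_px
        Ground sampling distance, centimetres per pixel (e.g. 1.78 at 40 m).
    altitude_m
        Flight altitude above ground in metres.
    variant_tag
        Which enhancement produced this image: RGB, LCS, SCT or TGI.
    geo_tags
        Raw GeoTIFF extratags read from a source TIFF, passed through
        untouched on write. ``None`` for non-georeferenced images.
    """

    pixels: np.ndarray
    resolution_cm_per_px: float | None = None
    altitude_m: float | None = None
    variant_tag: str = "RGB"
    geo_tags: tuple | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(
                f"pixels must be (H, W) or (H, W, 3), got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have positive height and width")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("digital numbers must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.variant_tag not in VARIANT_TAGS:
            raise ValueError(
                f"variant_tag must be one of {VARIANT_TAGS}, got {self.variant_tag!r}"
            )
        if self.resolution_cm_per_px is not None and self.resolution_cm_per_px <= 0:
            raise ValueError("resolution_cm_per_px must be positive")
        if self.altitude_m is not None and self.altitude_m <= 0:
            raise ValueError("altitude_m must be positive")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_bands(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def band(self, index: int) -> np.ndarray:
        """Return one band as a 2-D uint8 view (0=R, 1=G, 2=B)."""
        if self.pixels.ndim == 2:
            if index != 0:
                raise IndexError("single-band image has only band 0")
            return self.pixels
        return self.pixels[:, :, index]


def read_raster(path: str | Path, **meta) -> RasterImage:
    """Read a TIFF/PNG/JPEG raster into a :class:`RasterImage`.

    Extra keyword arguments (``resolution_cm_per_px``, ``altitude_m``,
    ``variant_tag``) are attached as metadata.
    """
    path = Path(path)
    geo = None
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            px = page.asarray()
            tags = []
            for code in _GEO_TAG_CODES:
                tag = page.tags.get(code)
                if tag is not None:
                    tags.append((tag.code, tag.dtype, tag.count, tag.value, True))
            geo = tuple(tags) if tags else None
    else:
        px = np.asarray(Image.open(path))
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[:, :, :3]
    return RasterImage(px, geo_tags=geo, **meta)


def write_raster(img: RasterImage, path: str | Path) -> None:
    """Write to TIFF/PNG/JPEG by extension; GeoTIFF tags pass through."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels, extratags=img.geo_tags or ())
    else:
        Image.fromarray(img.pixels).save(path)
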