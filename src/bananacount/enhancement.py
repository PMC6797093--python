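"""Vegetation-enhancing image transforms for RGB orthomosaics.

Young banana canopies are hard to separate from the surrounding grass in a
plain RGB mosaic: both are green and the chlorophyll contrast is small.
Three enhancements make the canopies stand out, each producing a variant of
the mosaic that a per-tile detector can run on:

* **Linear Contrast Stretch (LCS)** — per-band linear mapping of digital
  numbers (DN) to gray levels (GL) so the occupied DN range fills the full
  [0, 255] display range, clipping ("saturating") a small fraction of
  extreme pixels at each end (default 1%).
* **Synthetic Color Transform (SCT)** — false-colouring of the green band:
  its low spatial-frequency content (surface scattering from vegetation)
  drives hue, its high-frequency residual drives value, saturation is held
  constant (default 0.5), and the HSV image is converted to RGB.
* **Triangular Greenness Index (TGI)** — an RGB-band vegetation index
  proportional to leaf chlorophyll content; broadband form
  ``TGI = G - 0.39 R - 0.61 B``, kept signed and quantized to 8 bits for
  detection.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb

from ._util import minmax_unit, round_half_away
from .raster import RasterImage

logger = logging.getLogger(__name__)

__all__ = [
    "StretchSpec",
    "SCTSpec",
    "SignedBand",
    "linear_contrast_stretch",
    "synthetic_color_transform",
    "tgi_broadband",
    "tgi_narrowband",
    "to_eight_bit",
]


@dataclasses.dataclass(frozen=True)
class StretchSpec:
    """Parameters of the linear contrast stretch.

    saturation_fraction: fraction of pixels clipped at *each* end of the
    histogram before the linear DN->GL mapping (0.01 = the 1% saturation
    stretch). per_band: stretch each band against its own quantiles rather
    than joint quantiles over all bands.
    """

    saturation_fraction: float = 0.01
    per_band: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturation_fraction < 0.5:
            raise ValueError("saturation_fraction must lie in [0, 0.5)")


@dataclasses.dataclass(frozen=True)
class SCTSpec:
    """Parameters of the synthetic color transform.

    lowpass_sigma_px: Gaussian sigma of the low-pass filter separating low
    and high spatial frequencies (default 25 px, about one canopy diameter
    at the 40 m ground resolution). saturation_constant: fixed HSV
    saturation (default 0.5).
    """

    lowpass_sigma_px: float = 25.0
    saturation_constant: float = 0.5

    def __post_init__(self) -> None:
        if self.lowpass_sigma_px <= 0:
            raise ValueError("lowpass_sigma_px must be positive")
        if not 0.0 <= self.saturation_constant <= 1.0:
            raise ValueError("saturation_constant must lie in [0, 1]")


@dataclasses.dataclass
class SignedBand:
    """A single-band signed-real image, e.g. raw TGI values.

    For 8-bit RGB input the broadband TGI lies in [-255, 255].
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("SignedBand expects a 2-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("SignedBand values must be finite")
        self.values = v


def _stretch_band(band: np.ndarray, lo: float, hi: float) -> np.ndarray:
    gl = 255.0 * (band.astype(float) - lo) / (hi - lo)
    return np.clip(round_half_away(gl), 0, 255).astype(np.uint8)


def linear_contrast_stretch(
    img: RasterImage, spec: StretchSpec = StretchSpec()
) -> RasterImage:
    """Stretch DN to fill the full [0, 255] gray-level range.

    Per band (when ``spec.per_band``): ``lo``/``hi`` are the DN quantiles at
    ``saturation_fraction`` and ``1 - saturation_fraction`` (linear
    interpolation between order statistics); each output gray level is
    ``clip(round(255 (DN - lo) / (hi - lo)), 0, 255)`` with rounding half
    away from zero. A degenerate band (``hi == lo``) is returned unchanged
    with a logged warning.
    """
    s = spec.saturation_fraction
    px = img.pixels
    if px.ndim == 2:
        bands = [px]
    else:
        bands = [px[:, :, i] for i in range(3)]

    if not spec.per_band:
        lo_all, hi_all = np.quantile(px.astype(float), [s, 1.0 - s])

    out = []
    for i, band in enumerate(bands):
        if spec.per_band:
            lo, hi = np.quantile(band.astype(float), [s, 1.0 - s])
        else:
            lo, hi = lo_all, hi_all
        if hi == lo:
            logger.warning(
                "linear_contrast_stretch: band %d has degenerate DN range "
                "(lo == hi == %g); returned unchanged",
                i,
                lo,
            )
            out.append(band.copy())
        else:
            out.append(_stretch_band(band, lo, hi))

    stretched = out[0] if px.ndim == 2 else np.stack(out, axis=-1)
    return RasterImage(
        stretched,
        resolution_cm_per_px=img.resolution_cm_per_px,
        altitude_m=img.altitude_m,
        variant_tag="LCS",
        geo_tags=img.geo_tags,
    )


def synthetic_color_transform(
    green_band: RasterImage, spec: SCTSpec = SCTSpec()
) -> RasterImage:
    """False-colour a single band from its spatial-frequency split.

    The band is separated into ``low`` (Gaussian low-pass, sigma
    ``spec.lowpass_sigma_px``) and ``high = band - low``. Hue is the min-max
    normalization of ``low`` rescaled to [0, 2/3] (red through blue, so the
    extremes are distinct colours), value is the min-max normalization of
    ``high`` to [0, 1], and saturation is fixed at
    ``spec.saturation_constant``. The HSV image is converted to RGB and
    quantized to 8 bits. A constant low or high component zeroes the
    corresponding channel with a warning.
    """
    if green_band.n_bands != 1:
        raise ValueError("synthetic_color_transform expects a single-band image")
    band = green_band.pixels.astype(float)
    low = ndimage.gaussian_filter(band, sigma=spec.lowpass_sigma_px)
    high = band - low

    hue = minmax_unit(low)
    if hue is None:
        logger.warning("synthetic_color_transform: constant low-pass component; hue set to 0")
        hue = np.zeros_like(band)
    else:
        hue = hue * (2.0 / 3.0)

    value = minmax_unit(high)
    if value is None:
        logger.warning("synthetic_color_transform: constant high-pass component; value set to 0")
        value = np.zeros_like(band)

    hsv = np.stack(
        [hue, np.full_like(band, spec.saturation_constant), value], axis=-1
    )
    rgb = np.clip(round_half_away(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    return RasterImage(
        rgb,
        resolution_cm_per_px=green_band.resolution_cm_per_px,
        altitude_m=green_band.altitude_m,
        variant_tag="SCT",
        geo_tags=green_band.geo_tags,
    )


def tgi_broadband(img: RasterImage) -> SignedBand:
    """Broadband triangular greenness index, ``G - 0.39 R - 0.61 B``.

    The coefficients sum to 1, so gray pixels map to exactly 0; values are
    kept as signed reals (range [-255, 255] for 8-bit input).
    """
    if img.n_bands != 3:
        raise ValueError(f"tgi_broadband needs a 3-band image, got {img.n_bands} band(s)")
    # integer arithmetic then one division: gray pixels give exactly 0
    px = img.pixels.astype(np.int64)
    return SignedBand((100 * px[:, :, 1] - 39 * px[:, :, 0] - 61 * px[:, :, 2]) / 100.0)


def tgi_narrowband(r670: float, r550: float, r480: float) -> float:
    """Narrow-band TGI from spectral reflectances at 670/550/480 nm.

    Proportional to the area of the triangle spanned by the three
    (wavelength, reflectance) points:
    ``-0.5 [190 (R670 - R550) - 120 (R670 - R480)]``. Provided as a utility
    for calibrated sensors; the pipeline itself works on broadband RGB.
    """
    if r670 < 0 or r550 < 0 or r480 < 0:
        raise ValueError("reflectances must be non-negative")
    return -0.5 * (190.0 * (r670 - r550) - 120.0 * (r670 - r480))


def to_eight_bit(band: SignedBand, mode: str = "per_image_minmax") -> RasterImage:
    """Quantize a signed band to an 8-bit single-band image.

    ``per_image_minmax`` maps [min, max] -> [0, 255] (maximal contrast,
    the default for detection); ``fixed_range`` maps [-255, 255] -> [0, 255]
    for cross-image comparability. Rounding is half away from zero. A
    constant band in ``per_image_minmax`` mode yields an all-128 image with
    a warning.
    """
    v = band.values
    if mode == "per_image_minmax":
        unit = minmax_unit(v)
        if unit is None:
            logger.warning("to_eight_bit: constant band; returning mid-gray (128)")
            out = np.full(v.shape, 128, dtype=np.uint8)
        else:
            out = np.clip(round_half_away(unit * 255.0), 0, 255).astype(np.uint8)
    elif mode == "fixed_range":
        out = np.clip(round_half_away((v + 255.0) / 510.0 * 255.0), 0, 255).astype(
            np.uint8
        )
    else:
        raise ValueError("mode must be 'per_image_minmax' or 'fixed_range'")
    return RasterImage(out, variant_tag="TGI")
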