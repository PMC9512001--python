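"""Deterministic preprocessing of a cropped fluorescein photograph.

The measurement pipeline reduces an RGB slit-lamp photograph of the
fluorescein pattern under an ortho-k lens to a one-dimensional intensity
profile along the horizontal meridian, takes the absolute first derivative,
and picks local maxima of the derivative as candidate zone-boundary edges:

1. proportional resize to a standard width (1,000 px),
2. green-channel extraction (fluorescein emission under blue light with a
   yellow barrier filter lives almost entirely in the green channel),
3. linear min-max contrast stretch,
4. extraction of a vertically centered horizontal band (60 px tall),
5. column-wise averaging of the band into an intensity profile,
6. absolute first difference of the (optionally pre-smoothed) profile and
   prominence/separation-filtered peak picking.

All operations are deterministic: identical input bytes and parameters
yield bit-identical profiles, derivatives and peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageOps, UnidentifiedImageError
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from skimage.transform import resize as _sk_resize

__all__ = [
    "RasterImage",
    "MeridianBand",
    "IntensityProfile",
    "DerivativeProfile",
    "PeakSet",
    "ImageDecodeError",
    "ImageFormatError",
    "DegenerateContrastError",
    "ImageTooSmallError",
    "load_image",
    "resize_to_standard_width",
    "extract_green",
    "maximize_contrast",
    "extract_meridian_band",
    "compute_profile",
    "abs_first_derivative",
    "detect_peaks",
]


class ImageDecodeError(ValueError):
    """The file could not be decoded as a raster image."""


class ImageFormatError(ValueError):
    """The decoded image has an unsupported layout (e.g. channel count)."""


class DegenerateContrastError(ValueError):
    """The image is constant and carries no pattern to stretch."""


class ImageTooSmallError(ValueError):
    """The image is smaller than the requested meridian band."""


@dataclass(frozen=True)
class RasterImage:
    """A decoded raster with intensities normalized to [0, 1].

    ``pixels`` is ``(rows, cols)`` for single-channel images or
    ``(rows, cols, 3)`` in RGB order.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim not in (2, 3):
            raise ImageFormatError(f"expected a 2-D or 3-D array, got ndim={px.ndim}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise ImageFormatError(f"expected 1 or 3 channels, got {px.shape[2]}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError(f"degenerate image shape {px.shape}")
        if px.size and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
            raise ImageFormatError("intensities must lie within [0, 1]")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass(frozen=True)
class MeridianBand:
    """A horizontal band of single-channel rows centered on the meridian."""

    pixels: np.ndarray
    row_start: int
    row_end: int

    @property
    def band_height(self) -> int:
        return self.row_end - self.row_start

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class IntensityProfile:
    """Band-averaged intensity per column of the resized image."""

    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DerivativeProfile:
    """|dI/dx| magnitudes; index i is the transition between columns i and i+1."""

    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PeakSet:
    """Local maxima of the derivative profile surviving the thresholds."""

    positions: np.ndarray
    magnitudes: np.ndarray
    min_prominence_frac: float
    min_separation_px: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        mag = np.asarray(self.magnitudes, dtype=np.float64)
        if pos.shape != mag.shape:
            raise ValueError("positions and magnitudes must have equal length")
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("peak positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "magnitudes", mag)

    def __len__(self) -> int:
        return len(self.positions)


def load_image(path: str | Path) -> RasterImage:
    """Decode a JPEG or PNG file, honoring EXIF orientation.

    Intensities are scaled to [0, 1] by the source bit depth.  RGBA input
    is reduced to RGB (the alpha plane is dropped); palette images are
    expanded.  Raises :class:`ImageDecodeError` for unreadable files and
    :class:`ImageFormatError` for unsupported channel layouts.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = ImageOps.exif_transpose(im)
            if im.mode == "P":
                im = im.convert("RGB")
            elif im.mode == "RGBA":
                im = im.convert("RGB")
            elif im.mode == "LA":
                im = im.convert("L")
            elif im.mode == "I;16":
                arr = np.asarray(im, dtype=np.float64) / 65535.0
                return RasterImage(arr)
            elif im.mode not in ("RGB", "L", "I", "F"):
                raise ImageFormatError(f"unsupported image mode {im.mode!r} in {path}")
            arr = np.asarray(im, dtype=np.float64)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise ImageDecodeError(f"cannot decode image file {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] not in (1, 3):
        raise ImageFormatError(f"unsupported channel count {arr.shape[2]} in {path}")
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.max(initial=0.0) > 1.0:
        arr = arr / 255.0
    return RasterImage(arr)


def resize_to_standard_width(img: RasterImage, target_width: int = 1000) -> RasterImage:
    """Proportionally resize so the output is ``target_width`` columns wide.

    Output height is ``round(height * target_width / width)``.  Bilinear
    interpolation with anti-aliasing; a no-op when the width already matches.
    """
    if target_width < 2:
        raise ValueError(f"target_width must be >= 2, got {target_width}")
    if img.width_px == target_width:
        return img
    # round-half-up so e.g. 1333x1000 -> 1000x750, matching manual computation
    target_height = int(np.floor(img.height_px * target_width / img.width_px + 0.5))
    target_height = max(target_height, 1)
    out_shape = (
        (target_height, target_width)
        if img.channels == 1
        else (target_height, target_width, 3)
    )
    resized = _sk_resize(
        img.pixels,
        out_shape,
        order=1,
        anti_aliasing=img.width_px > target_width,
        preserve_range=True,
        mode="reflect",
    )
    return RasterImage(np.clip(resized, 0.0, 1.0))


def extract_green(img: RasterImage) -> RasterImage:
    """Keep only the green channel; single-channel input passes through."""
    if img.channels == 1:
        return img
    return RasterImage(img.pixels[:, :, 1])


def maximize_contrast(img: RasterImage) -> RasterImage:
    """Linear min-max stretch of a single-channel image onto [0, 1].

    Monotone and order-preserving, so edge positions are unaffected.
    Raises :class:`DegenerateContrastError` on a constant image.
    """
    if img.channels != 1:
        raise ImageFormatError("contrast stretch expects a single-channel image")
    lo = float(img.pixels.min())
    hi = float(img.pixels.max())
    if hi - lo <= 0.0:
        raise DegenerateContrastError(
            "image is constant; no fluorescein pattern to stretch"
        )
    return RasterImage((img.pixels - lo) / (hi - lo))


def extract_meridian_band(img: RasterImage, band_height: int = 60) -> MeridianBand:
    """Extract a vertically centered band of ``band_height`` rows.

    The fluorescein pattern is assumed centered in the cropped photograph,
    so the central horizontal meridian crosses all four zone boundaries.
    """
    if img.channels != 1:
        raise ImageFormatError("meridian band expects a single-channel image")
    if band_height < 1:
        raise ValueError(f"band_height must be >= 1, got {band_height}")
    if img.height_px < band_height:
        raise ImageTooSmallError(
            f"image height {img.height_px} px is smaller than band height {band_height} px"
        )
    row_start = (img.height_px - band_height) // 2
    row_end = row_start + band_height
    return MeridianBand(img.pixels[row_start:row_end, :], row_start, row_end)


def compute_profile(band: MeridianBand, reducer: str = "mean") -> IntensityProfile:
    """Collapse the band to one value per column.

    The mean (default) maximizes suppression of uncorrelated sensor noise;
    the median is offered for robustness against specular highlights.
    """
    if reducer == "mean":
        values = band.pixels.mean(axis=0)
    elif reducer == "median":
        values = np.median(band.pixels, axis=0)
    else:
        raise ValueError(f"unknown reducer {reducer!r}; use 'mean' or 'median'")
    return IntensityProfile(np.asarray(values, dtype=np.float64))


def abs_first_derivative(
    profile: IntensityProfile, smoothing_sigma: float = 2.0
) -> DerivativeProfile:
    """Absolute forward first difference of the (pre-smoothed) profile.

    A 1-D Gaussian pre-smoothing (``smoothing_sigma`` px, 0 disables)
    suppresses JPEG blocking noise that would otherwise litter the
    derivative with spurious local maxima.  Smoothing a skewed transition
    also shifts the derivative's mode, so :func:`detect_peaks` re-localizes
    each detected peak on the unsmoothed derivative.  Output length is one
    less than the profile length; the value at index i is attributed to
    column i, a uniform half-pixel convention that cancels in all diameter
    differences.
    """
    values = np.asarray(profile.values, dtype=np.float64)
    if len(values) < 2:
        raise ValueError("profile must have at least 2 samples")
    if smoothing_sigma < 0:
        raise ValueError(f"smoothing_sigma must be >= 0, got {smoothing_sigma}")
    if smoothing_sigma > 0:
        values = gaussian_filter1d(values, smoothing_sigma, mode="nearest")
    return DerivativeProfile(np.abs(np.diff(values)))


def detect_peaks(
    deriv: DerivativeProfile,
    min_prominence_frac: float = 0.1,
    min_separation_px: int = 10,
    refine_on: DerivativeProfile | None = None,
    refine_radius: int = 0,
) -> PeakSet:
    """Pick local maxima of the derivative as candidate zone edges.

    A peak must have prominence at least ``min_prominence_frac`` of the
    global derivative maximum, and surviving peaks are pairwise at least
    ``min_separation_px`` apart; when two candidates are closer, the larger
    magnitude wins (ties broken toward smaller x).  An all-zero derivative
    yields an empty set — downstream edge assignment then fails informatively.

    When ``refine_on`` is given (normally the unsmoothed derivative) each
    accepted peak is re-localized to the argmax of that signal within
    ``refine_radius`` px: pre-smoothing makes detection robust, but it
    also drags the derivative mode of a skewed transition sideways, so the
    final position is read off the raw signal (coarse-to-fine).  The
    radius is clamped below half the separation, so refined peaks keep
    their ordering.
    """
    if not 0 < min_prominence_frac <= 1:
        raise ValueError(
            f"min_prominence_frac must be in (0, 1], got {min_prominence_frac}"
        )
    if min_separation_px < 1:
        raise ValueError(f"min_separation_px must be >= 1, got {min_separation_px}")
    values = np.asarray(deriv.values, dtype=np.float64)
    peak_max = values.max(initial=0.0)
    if peak_max <= 0.0:
        return PeakSet(
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.float64),
            min_prominence_frac,
            min_separation_px,
        )
    candidates, _ = find_peaks(values, prominence=min_prominence_frac * peak_max)
    # enforce separation ourselves for an explicit, documented tie-break:
    # process by descending magnitude (ascending x among ties), keep a
    # candidate only if it is >= min_separation_px from every kept peak.
    order = sorted(range(len(candidates)), key=lambda i: (-values[candidates[i]], candidates[i]))
    kept: list[int] = []
    for i in order:
        x = candidates[i]
        if all(abs(int(x) - k) >= min_separation_px for k in kept):
            kept.append(int(x))
    kept.sort()
    kept_arr = np.asarray(kept, dtype=np.int64)
    report_values = values
    if refine_on is not None and refine_radius > 0 and len(kept_arr):
        raw = np.asarray(refine_on.values, dtype=np.float64)
        if len(raw) != len(values):
            raise ValueError("refine_on must have the same length as the derivative")
        radius = min(int(refine_radius), (min_separation_px - 1) // 2)
        refined = []
        for p in kept_arr:
            lo = max(0, int(p) - radius)
            hi = min(len(raw), int(p) + radius + 1)
            refined.append(lo + int(np.argmax(raw[lo:hi])))
        kept_arr = np.asarray(refined, dtype=np.int64)
        report_values = raw
    return PeakSet(
        kept_arr, report_values[kept_arr], min_prominence_frac, min_separation_px
    )


def preprocess(
    img: RasterImage,
    target_width: int = 1000,
    band_height: int = 60,
    reducer: str = "mean",
    smoothing_sigma: float = 2.0,
    min_prominence_frac: float = 0.1,
    min_separation_px: int = 10,
) -> tuple[RasterImage, IntensityProfile, DerivativeProfile, PeakSet]:
    """Run steps 1–6 end to end; returns (resized image, profile, derivative, peaks)."""
    resized = resize_to_standard_width(img, target_width)
    mono = maximize_contrast(extract_green(resized))
    band = extract_meridian_band(mono, band_height)
    profile = compute_profile(band, reducer)
    deriv = abs_first_derivative(profile, smoothing_sigma)
    if smoothing_sigma > 0:
        raw = abs_first_derivative(profile, 0.0)
        radius = int(np.ceil(2 * smoothing_sigma))
        peaks = detect_peaks(
            deriv, min_prominence_frac, min_separation_px,
            refine_on=raw, refine_radius=radius,
        )
    else:
        peaks = detect_peaks(deriv, min_prominence_frac, min_separation_px)
    return resized, profile, deriv, peaks
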