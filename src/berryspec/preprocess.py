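"""Cube preprocessing: calibration, band cropping, Savitzky-Golay smoothing,
pixel-wise area normalization, fruit segmentation, mean-spectrum extraction,
first-derivative spectra and spatial resizing.

The canonical order used by the pipeline is
calibrate -> crop (441-947 nm) -> SG smooth -> area normalize ->
(segment + mean spectrum for 1D models | resize for 3D models);
every operation is deterministic so re-running reproduces outputs
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.transform import resize as _sk_resize

from .cube import HyperCube

__all__ = [
    "Spectrum",
    "SegmentationError",
    "calibrate_reflectance",
    "crop_bands",
    "sg_smooth",
    "area_normalize",
    "segment_fruit",
    "mean_spectrum",
    "first_derivative",
    "resize_cube",
    "preprocess_cube",
]

#: Retained spectral window (nm), closed on both ends.
CROP_LOW = 441.0
CROP_HIGH = 947.0

#: Savitzky-Golay defaults (window must be odd, polyorder < window).
SG_WINDOW = 11
SG_POLYORDER = 3


class SegmentationError(RuntimeError):
    """Raised when no fruit region can be found in a cube."""


@dataclass
class Spectrum:
    """A single reflectance profile over the retained bands."""

    values: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.shape != self.wavelengths.shape or self.values.ndim != 1:
            raise ValueError("spectrum values and wavelengths must be 1-D and equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")


def calibrate_reflectance(
    raw: HyperCube, white: HyperCube, dark: HyperCube, denom_floor: float = 1e-6
) -> HyperCube:
    """Convert raw counts to reflectance: (raw - dark) / (white - dark).

    The denominator is clamped at ``denom_floor`` so dead pixels (where the
    white and dark references coincide) do not blow up; clamped voxels end up
    with large but finite values that the downstream mask excludes.
    """
    for other in (white, dark):
        if other.shape != raw.shape or not np.allclose(other.wavelengths, raw.wavelengths):
            raise ValueError("raw, white and dark cubes must share shape and wavelength grid")
    denom = np.maximum(white.values - dark.values, denom_floor)
    return HyperCube((raw.values - dark.values) / denom, raw.wavelengths.copy())


def crop_bands(cube: HyperCube, low: float = CROP_LOW, high: float = CROP_HIGH) -> HyperCube:
    """Retain exactly the bands with ``low <= wavelength <= high`` (closed)."""
    if low > high:
        raise ValueError(f"need low <= high, got [{low}, {high}]")
    keep = (cube.wavelengths >= low - 1e-9) & (cube.wavelengths <= high + 1e-9)
    if not keep.any():
        raise ValueError(f"no bands inside [{low}, {high}] nm")
    return HyperCube(cube.values[:, :, keep], cube.wavelengths[keep])


def _spectral_axis_values(obj: HyperCube | Spectrum) -> tuple[np.ndarray, int]:
    if isinstance(obj, HyperCube):
        return obj.values, 2
    return obj.values, 0


def _rewrap(obj: HyperCube | Spectrum, values: np.ndarray) -> HyperCube | Spectrum:
    if isinstance(obj, HyperCube):
        return HyperCube(values, obj.wavelengths.copy())
    return Spectrum(values, obj.wavelengths.copy())


def sg_smooth(
    obj: HyperCube | Spectrum, window: int = SG_WINDOW, polyorder: int = SG_POLYORDER
) -> HyperCube | Spectrum:
    """Savitzky-Golay smoothing along the spectral axis only.

    Edges are handled by evaluating the end-window least-squares polynomial
    (scipy's ``interp`` mode), so polynomials of degree <= polyorder are
    reproduced exactly everywhere, including the edges.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder ({polyorder}) must be < window ({window})")
    values, axis = _spectral_axis_values(obj)
    if values.shape[axis] < window:
        raise ValueError(f"need >= {window} bands for window {window}")
    return _rewrap(obj, savgol_filter(values, window, polyorder, axis=axis, mode="interp"))


def area_normalize(obj: HyperCube | Spectrum) -> HyperCube | Spectrum:
    """Divide each pixel spectrum by its band sum so every spectrum sums to 1.

    Removes brightness/shape effects; requires strictly positive band sums.
    """
    values, axis = _spectral_axis_values(obj)
    sums = values.sum(axis=axis, keepdims=True)
    if np.any(sums <= 0):
        n_bad = int((sums <= 0).sum())
        raise ValueError(f"{n_bad} pixel spectra have non-positive sum; cannot area-normalize")
    return _rewrap(obj, values / sums)


def segment_fruit(cube: HyperCube, nir_nm: float = 900.0) -> np.ndarray:
    """Segment the fruit as the largest bright connected component in a
    high-NIR band (fruit tissue reflects strongly there, background does not).

    Returns a boolean (rows, cols) mask.  Raises :class:`SegmentationError`
    when the image has no separable foreground.
    """
    band = int(np.argmin(np.abs(cube.wavelengths - nir_nm)))
    img = cube.values[:, :, band]
    if np.ptp(img) < 1e-12:
        raise SegmentationError("image is constant; no fruit/background contrast")
    thr = threshold_otsu(img)
    fg = img > thr
    if not fg.any() or fg.all():
        raise SegmentationError("thresholding produced an empty or full mask")
    labels = cc_label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    # guard against picking up sparse noise speckle as 'fruit'
    if mask.sum() < 9:
        raise SegmentationError("largest component too small to be a fruit")
    return mask


def mean_spectrum(cube: HyperCube, mask: np.ndarray) -> Spectrum:
    """Arithmetic per-band mean over the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape must match the cube's spatial dims")
    if not mask.any():
        raise ValueError("mask is empty")
    return Spectrum(cube.values[mask].mean(axis=0), cube.wavelengths.copy())


def first_derivative(
    spectrum: Spectrum, window: int = SG_WINDOW, polyorder: int = SG_POLYORDER
) -> Spectrum:
    """First derivative with respect to wavelength (reflectance per nm).

    Uses the Savitzky-Golay derivative with the smoothing window, assuming a
    uniform wavelength step; output has the same length as the input.
    """
    if spectrum.values.size < 2:
        raise ValueError("need >= 2 bands for a derivative")
    steps = np.diff(spectrum.wavelengths)
    delta = float(steps.mean())
    if spectrum.values.size < window:
        # fall back to plain finite differences on short spectra
        deriv = np.gradient(spectrum.values, spectrum.wavelengths)
        return Spectrum(deriv, spectrum.wavelengths.copy())
    deriv = savgol_filter(spectrum.values, window, polyorder, deriv=1, delta=delta, mode="interp")
    return Spectrum(deriv, spectrum.wavelengths.copy())


def resize_cube(cube: HyperCube, out_rows: int = 85, out_cols: int = 85) -> HyperCube:
    """Spatial-only bilinear resize; the spectral axis is untouched."""
    if out_rows < 1 or out_cols < 1:
        raise ValueError("target dims must be positive")
    rows, cols, _ = cube.shape
    if (out_rows, out_cols) == (rows, cols):
        return cube.copy()
    values = _sk_resize(
        cube.values,
        (out_rows, out_cols, cube.n_bands),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return HyperCube(values, cube.wavelengths.copy())


def preprocess_cube(
    cube: HyperCube,
    low: float = CROP_LOW,
    high: float = CROP_HIGH,
    window: int = SG_WINDOW,
    polyorder: int = SG_POLYORDER,
    normalize_first: bool = False,
) -> HyperCube:
    """Crop + SG smooth + area normalize, in the canonical order.

    ``normalize_first=True`` swaps smoothing and normalization for
    sensitivity checks; the default order smooths first.
    """
    out = crop_bands(cube, low, high)
    if normalize_first:
        out = area_normalize(out)
        out = sg_smooth(out, window, polyorder)
    else:
        out = sg_smooth(out, window, polyorder)
        out = area_normalize(out)
    return out
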