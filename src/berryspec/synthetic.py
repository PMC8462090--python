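"""Synthetic hyperspectral strawberry phantoms.

Real strawberry cubes for this problem are not publicly deposited, so the
pipeline is exercised on phantoms that reproduce the statistical structure the
analysis relies on:

* four ordinal maturity classes D1..D4 defined by the fraction of the fruit
  surface that is red (<=25%, 26-50%, 51-75%, 76-100%), encoded 0..3;
* pixel spectra that are mixtures of a green-tissue endmember (chlorophyll
  absorption trough near 670 nm) and a red-tissue endmember (anthocyanin
  reflectance rise above ~600 nm), so that class differences concentrate in
  the visible 441-700 nm window and vanish above ~750 nm;
* class-conditional soluble-solids content (SSC, degrees Brix) drawn from
  normals with means 8.23, 8.57, 9.58, 10.37 and SDs 1.15, 0.8, 1.32, 1.71
  for D1..D4;
* an optional SSC-proportional reflectance bump confined to 700-940 nm so
  that SSC is spectrally recoverable (sugar-related NIR signal surrogate).

The red region grows from the fruit apex as a contiguous cap, matching how
strawberries colour from the tip, which also gives spatially coherent
saliency maps downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cube import HyperCube, write_envi

__all__ = [
    "SSC_MEANS",
    "SSC_SDS",
    "PhantomConfig",
    "EndmemberLibrary",
    "StrawberryPhantom",
    "make_wavelength_grid",
    "maturity_label_from_fraction",
    "simulate_phantom",
    "simulate_ssc",
    "simulate_samples",
    "simulate_dataset",
]

#: Class-conditional SSC (degrees Brix) mean and SD for D1..D4.
SSC_MEANS = np.array([8.23, 8.57, 9.58, 10.37])
SSC_SDS = np.array([1.15, 0.8, 1.32, 1.71])

#: Upper edges of the red-fraction intervals for D1..D4 (half-open intervals
#: (0, .25], (.25, .50], (.50, .75], (.75, 1]).
CLASS_EDGES = np.array([0.25, 0.50, 0.75, 1.0])


def make_wavelength_grid(start: float, end: float, n_bands: int) -> np.ndarray:
    """Evenly spaced, strictly increasing wavelength grid in nm.

    The generator default (380-1030 nm, 515 bands) is chosen so that the
    441-947 nm crop used downstream retains exactly 400 bands.
    """
    if n_bands < 2:
        raise ValueError(f"n_bands must be >= 2, got {n_bands}")
    if not end > start:
        raise ValueError(f"need end > start, got [{start}, {end}]")
    return np.linspace(float(start), float(end), int(n_bands))


def maturity_label_from_fraction(red_fraction: float) -> int:
    """Map a red-area fraction in [0, 1] to the maturity class 0..3.

    Thresholds: <=0.25 -> 0 (D1), <=0.50 -> 1 (D2), <=0.75 -> 2 (D3),
    else 3 (D4).
    """
    f = float(red_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"red fraction must be in [0, 1], got {f}")
    return int(np.searchsorted(CLASS_EDGES[:-1], f, side="left"))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class EndmemberLibrary:
    """Named endmember reflectance spectra over a common wavelength grid.

    Green and red tissue share an identical NIR plateau (blended in above the
    ~692 nm red edge), so their difference is large inside 441-700 nm and
    negligible above 750 nm.
    """

    wavelengths: np.ndarray
    green: np.ndarray
    red: np.ndarray
    background: np.ndarray
    name: str = "strawberry_v1"

    def __post_init__(self) -> None:
        for em in (self.green, self.red, self.background):
            if em.shape != self.wavelengths.shape:
                raise ValueError("endmember length must match wavelength grid")
            if np.any(em < 0):
                raise ValueError("endmembers must be nonnegative")

    @classmethod
    def default(cls, wavelengths: np.ndarray) -> "EndmemberLibrary":
        wl = np.asarray(wavelengths, dtype=float)
        # smooth VIS->NIR switch at the red edge
        s = _sigmoid((wl - 692.0) / 7.0)
        nir = 0.80 - 0.05 * np.exp(-0.5 * ((wl - 970.0) / 45.0) ** 2)
        green_vis = (
            0.32
            + 0.18 * np.exp(-0.5 * ((wl - 550.0) / 35.0) ** 2)
            - 0.22 * np.exp(-0.5 * ((wl - 668.0) / 22.0) ** 2)
        )
        red_vis = (
            0.10
            + 0.45 * _sigmoid((wl - 610.0) / 18.0)
            + 0.05 * np.exp(-0.5 * ((wl - 470.0) / 40.0) ** 2)
        )
        green = green_vis * (1.0 - s) + nir * s
        # equalize integrated reflectance over the 441-947 nm analysis window
        # by rescaling only the red VISIBLE part: pixel-wise area
        # normalization divides by the spectrum sum, so unequal endmember
        # sums would rescale the NIR plateau by a class-dependent factor and
        # delocalize the class signal out of the visible window; scaling the
        # whole spectrum would instead break the shared NIR plateau
        window = (wl >= 441.0) & (wl <= 947.0)
        vis_part = red_vis * (1.0 - s)
        nir_part = nir * s
        denom = vis_part[window].sum()
        if window.any() and denom > 0:
            beta = (green[window].sum() - nir_part[window].sum()) / denom
            red = vis_part * beta + nir_part
        else:
            red = vis_part + nir_part
        background = np.full_like(wl, 0.02)
        return cls(wl, green, red, background)


def ssc_bump_shape(wavelengths: np.ndarray, low: float = 700.0, high: float = 940.0) -> np.ndarray:
    """Compact-support spectral shape carrying the SSC signal (amplitude 1).

    A full sine period over [low, high]: a zero-integral *reshaping* of the
    NIR plateau rather than a brightness change.  Pixel-wise area
    normalization removes overall brightness, so only a sum-preserving
    signature survives preprocessing localized to where it was injected.
    """
    wl = np.asarray(wavelengths, dtype=float)
    inside = (wl >= low) & (wl <= high)
    shape = np.zeros_like(wl)
    shape[inside] = np.sin(2.0 * np.pi * (wl[inside] - low) / (high - low))
    return shape


@dataclass
class PhantomConfig:
    """Generation parameters for one phantom.

    ``ssc_bump_amplitude`` is the reflectance added per degree Brix at the
    peak of the 700-940 nm bump (default 0.004, i.e. ~4-5% of the NIR plateau
    at typical SSC); set to 0 to remove any SSC-related spectral signal.
    ``noise_sd`` is i.i.d. additive Gaussian noise per voxel in reflectance
    units (default 0.01, 1% of full scale).
    """

    image_height: int = 24
    image_width: int = 24
    wavelength_start: float = 380.0
    wavelength_end: float = 1030.0
    n_bands: int = 515
    red_fraction: float = 0.5
    noise_sd: float = 0.01
    seed: int = 0
    endmembers: str = "strawberry_v1"
    ssc_bump_amplitude: float = 0.004
    fruit_semi_axes: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.red_fraction <= 1.0:
            raise ValueError(f"red_fraction must be in [0, 1], got {self.red_fraction}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_bands < 2 or self.wavelength_end <= self.wavelength_start:
            raise ValueError("invalid wavelength grid")

    @property
    def wavelengths(self) -> np.ndarray:
        return make_wavelength_grid(self.wavelength_start, self.wavelength_end, self.n_bands)


@dataclass
class StrawberryPhantom:
    """One synthetic berry: cube, masks, ground truth and SSC."""

    cube: HyperCube
    fruit_mask: np.ndarray
    red_mask: np.ndarray
    true_red_fraction: float
    maturity_label: int
    ssc: float


def _fruit_ellipse(config: PhantomConfig) -> np.ndarray:
    h, w = config.image_height, config.image_width
    if config.fruit_semi_axes is not None:
        a_r, a_c = config.fruit_semi_axes
    else:
        a_r, a_c = 0.40 * h, 0.34 * w
    if 2 * a_r > h or 2 * a_c > w:
        raise ValueError(f"fruit ellipse (semi-axes {a_r:.1f}, {a_c:.1f}) exceeds image {h}x{w}")
    rr, cc = np.mgrid[0:h, 0:w]
    return ((rr - (h - 1) / 2) / a_r) ** 2 + ((cc - (w - 1) / 2) / a_c) ** 2 <= 1.0


def simulate_phantom(
    config: PhantomConfig,
    ssc: float | None = None,
    rng: np.random.Generator | None = None,
) -> StrawberryPhantom:
    """Render one phantom from *config*.

    The red cap covers (as closely as pixelation allows, with at least one
    pixel) ``red_fraction`` of the fruit mask, growing contiguously from the
    apex (bottom of the image).  The maturity label is assigned from the
    achieved red fraction via :func:`maturity_label_from_fraction`.  If *ssc*
    is not given it is drawn from the class-conditional SSC normal.
    Deterministic given ``config.seed`` (when *rng* is not supplied).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    wl = config.wavelengths
    lib = EndmemberLibrary.default(wl)
    mask = _fruit_ellipse(config)
    n_fruit = int(mask.sum())
    if n_fruit == 0:
        raise ValueError("fruit mask is empty; enlarge the image or the ellipse")

    n_red = int(np.clip(round(config.red_fraction * n_fruit), 0, n_fruit))
    if config.red_fraction > 0 and n_red == 0:
        n_red = 1
    true_red_fraction = n_red / n_fruit
    label = maturity_label_from_fraction(true_red_fraction)
    if ssc is None:
        ssc = float(simulate_ssc(label, rng=rng))

    # contiguous cap from the apex: fill fruit pixels from the bottom row up
    rows, cols = np.nonzero(mask)
    order = np.lexsort((cols, -rows))  # bottom rows first, left-to-right
    red_mask = np.zeros_like(mask)
    red_mask[rows[order[:n_red]], cols[order[:n_red]]] = True

    values = np.empty((config.image_height, config.image_width, config.n_bands))
    values[:] = lib.background
    values[mask & ~red_mask] = lib.green
    values[red_mask] = lib.red
    if config.ssc_bump_amplitude != 0.0:
        values[mask] += config.ssc_bump_amplitude * ssc * ssc_bump_shape(wl)
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)
        # fruit spectra must stay strictly positive for area normalization
        values[mask] = np.maximum(values[mask], 1e-4)

    return StrawberryPhantom(
        cube=HyperCube(values, wl),
        fruit_mask=mask,
        red_mask=red_mask,
        true_red_fraction=true_red_fraction,
        maturity_label=label,
        ssc=float(ssc),
    )


def simulate_ssc(
    maturity_label: int,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
    means: np.ndarray = SSC_MEANS,
    sds: np.ndarray = SSC_SDS,
) -> float | np.ndarray:
    """Draw SSC (degrees Brix) from the class-conditional normal, truncated at 0.

    Truncation is by resampling; at the default parameters the truncated mass
    is negligible, so sample means match the class means.
    """
    if maturity_label not in (0, 1, 2, 3):
        raise ValueError(f"maturity label must be 0..3, got {maturity_label}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = 1 if size is None else int(size)
    mu, sd = float(means[maturity_label]), float(sds[maturity_label])
    out = rng.normal(mu, sd, size=n)
    if sd > 0:
        bad = out <= 0
        while bad.any():
            out[bad] = rng.normal(mu, sd, size=int(bad.sum()))
            bad = out <= 0
    else:
        out = np.maximum(out, 0.0)
    return float(out[0]) if size is None else out


def simulate_samples(
    n_per_class: int,
    template: PhantomConfig | None = None,
    master_seed: int = 0,
    couple_ssc_to_class: bool = True,
) -> list[StrawberryPhantom]:
    """Simulate ``4 * n_per_class`` phantoms, ``n_per_class`` per maturity class.

    Red fractions are drawn uniformly within each class's interval and
    quantized so that the achieved red fraction stays inside the interval
    (the dataset label always matches the drawn class).  With
    ``couple_ssc_to_class=False`` the SSC is drawn from the marginal mixture,
    independent of the maturity label — useful for controlled saliency
    experiments where SSC signal must not leak into the visible bands.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if template is None:
        template = PhantomConfig()
    edges = np.concatenate(([0.0], CLASS_EDGES))
    ss = np.random.SeedSequence(master_seed)
    phantoms: list[StrawberryPhantom] = []
    # fruit-pixel count is a function of geometry only; compute once
    n_fruit = int(_fruit_ellipse(template).sum())
    for label in range(4):
        lo, hi = edges[label], edges[label + 1]
        k_lo, k_hi = int(np.floor(lo * n_fruit)) + 1, int(np.floor(hi * n_fruit))
        for child in ss.spawn(n_per_class):
            rng = np.random.default_rng(child)
            f = rng.uniform(lo, hi)
            k = int(np.clip(round(f * n_fruit), k_lo, k_hi))
            if couple_ssc_to_class:
                ssc = float(simulate_ssc(label, rng=rng))
            else:
                ssc = float(simulate_ssc(int(rng.integers(4)), rng=rng))
            cfg = replace(template, red_fraction=k / n_fruit)
            phantoms.append(simulate_phantom(cfg, ssc=ssc, rng=rng))
            assert phantoms[-1].maturity_label == label
    return phantoms


def simulate_dataset(
    n_per_class: int,
    out_dir: str | Path,
    template: PhantomConfig | None = None,
    master_seed: int = 0,
    couple_ssc_to_class: bool = True,
) -> pd.DataFrame:
    """Simulate a dataset and write it to disk as ENVI cubes plus a manifest.

    Returns the manifest (also written to ``manifest.csv``) with columns
    sample_id, label, red_fraction, ssc, path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc
    phantoms = simulate_samples(n_per_class, template, master_seed, couple_ssc_to_class)
    records = []
    for i, ph in enumerate(phantoms):
        sample_id = f"berry_{i:04d}"
        hdr = write_envi(ph.cube, out_dir / sample_id)
        records.append(
            {
                "sample_id": sample_id,
                "label": ph.maturity_label,
                "red_fraction": ph.true_red_fraction,
                "ssc": ph.ssc,
                "path": str(hdr),
            }
        )
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
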