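"""Hyperspectral cube container and ENVI-format I/O.

A :class:`HyperCube` is a (rows, cols, bands) reflectance array plus the
wavelength (nm) of each band.  Cubes are exchanged on disk in the ENVI
convention: a plain-text ``.hdr`` file describing dimensions, data type and
the wavelength list, next to a raw band-sequential (BSQ) binary payload.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["HyperCube", "read_envi", "write_envi"]

# ENVI data type codes we support (code -> numpy dtype)
_ENVI_DTYPES = {2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16, 1: np.uint8}
_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


@dataclass
class HyperCube:
    """Reflectance cube with its wavelength axis.

    Parameters
    ----------
    values : ndarray, shape (rows, cols, bands)
        Reflectance (unitless); must be finite.
    wavelengths : ndarray, shape (bands,)
        Band centres in nm, strictly increasing.
    """

    values: np.ndarray
    wavelengths: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"cube must be 3-D (rows, cols, bands), got ndim={self.values.ndim}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.values.shape[2]:
            raise ValueError(
                f"wavelength vector length {self.wavelengths.size} does not match "
                f"band dimension {self.values.shape[2]}"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def copy(self) -> "HyperCube":
        return HyperCube(self.values.copy(), self.wavelengths.copy())


def write_envi(cube: HyperCube, path: str | Path) -> Path:
    """Write *cube* as ENVI header + BSQ binary.

    ``path`` may or may not carry an extension; the data file is written at
    ``<path>.raw`` and the header at ``<path>.hdr``.  Returns the header path.
    """
    base = Path(path)
    if base.suffix in {".hdr", ".raw", ".img"}:
        base = base.with_suffix("")
    rows, cols, bands = cube.shape
    data = np.ascontiguousarray(np.transpose(cube.values, (2, 0, 1)), dtype=np.float32)
    raw_path = base.with_suffix(".raw")
    hdr_path = base.with_suffix(".hdr")
    data.tofile(raw_path)
    wl = ",\n ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr_path.write_text(
        "ENVI\n"
        "description = {berryspec hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(np.float32)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {\n " + wl + "}\n"
    )
    return hdr_path


def _parse_header(text: str) -> dict:
    """Parse an ENVI header into a flat dict (keys lower-cased)."""
    # join {...} blocks onto one logical line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(path: str | Path) -> HyperCube:
    """Read an ENVI cube written by :func:`write_envi` (or compatible)."""
    hdr_path = Path(path)
    if hdr_path.suffix != ".hdr":
        hdr_path = hdr_path.with_suffix(".hdr")
    fields = _parse_header(hdr_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _ENVI_DTYPES[int(fields.get("data type", "4"))]
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValueError(f"unsupported interleave {interleave!r}; only bsq is handled")
    wl_text = fields.get("wavelength", "")
    wl = np.array([float(t) for t in re.findall(r"[-+0-9.eE]+", wl_text)], dtype=float)
    if wl.size != bands:
        raise ValueError(f"header lists {wl.size} wavelengths for {bands} bands")
    raw_path = hdr_path.with_suffix(".raw")
    if not raw_path.exists():  # tolerate .img payloads from other writers
        raw_path = hdr_path.with_suffix(".img")
    data = np.fromfile(raw_path, dtype=dtype, count=rows * cols * bands)
    if data.size != rows * cols * bands:
        raise ValueError("binary payload size does not match header dimensions")
    values = np.transpose(data.reshape(bands, rows, cols), (1, 2, 0)).astype(np.float64)
    return HyperCube(values, wl)
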