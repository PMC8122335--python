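"""Hypercube containers, ENVI-style I/O and dark/white reflectance calibration.

A line-scan VNIR imager produces a 3-D hypercube of ``lines x samples x
bands`` raw intensity counts plus dark-current and white-reference frames.
Reflectance is recovered band-wise as ``R = (I - D) / (W - D)``.

The on-disk carrier is the ENVI dialect common in hyperspectral practice: a
plain-text ``.hdr`` describing shape, interleave and the wavelength list,
next to a headerless binary raster.  Only BSQ interleave is produced here
(band-sequential, the natural order for band-wise processing); BSQ, BIL and
BIP are all accepted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Hypercube",
    "Image2D",
    "read_envi",
    "write_envi",
    "calibrate_reflectance",
    "band_image",
    "mean_spectrum",
    "write_hdf5",
    "read_hdf5",
]

#: default spectral axis: 128 evenly spaced band centers on 400-1000 nm
DEFAULT_WAVELENGTHS = np.linspace(400.0, 1000.0, 128)

# ENVI 'data type' codes <-> numpy dtypes (little-endian subset we emit/accept)
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


class EnviFormatError(ValueError):
    """Raised for missing or mutually inconsistent ENVI header fields."""


@dataclass
class Hypercube:
    """Calibrated or raw hyperspectral datacube.

    Parameters
    ----------
    data : ndarray, shape (lines, samples, bands)
        Raw counts or reflectance.
    wavelengths : ndarray, shape (bands,)
        Band-center wavelengths in nm, strictly ascending.
    kind : {"raw", "reflectance"}
    """

    data: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (lines, samples, bands), got ndim={self.data.ndim}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {len(self.wavelengths)} does not match "
                f"band count {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class Image2D:
    """Single-band (or derived) 2-D image sharing a cube's spatial grid."""

    data: np.ndarray
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("Image2D requires a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _parse_envi_header(header_path: Path) -> dict:
    text = header_path.read_text()
    if not text.lstrip().upper().startswith("ENVI"):
        raise EnviFormatError(f"{header_path}: missing ENVI magic line")
    # strip the magic, then parse "key = value" with {...} multiline blocks
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{.*?\}|[^\n]*)", re.M | re.S)
    pos = 0
    while True:
        m = pattern.search(body, pos)
        if m is None:
            break
        fields[m.group(1).strip().lower()] = m.group(2).strip()
        pos = m.end()
    return fields


def _require(fields: dict, key: str) -> str:
    if key not in fields:
        raise EnviFormatError(f"required ENVI header field missing: {key!r}")
    return fields[key]


def read_envi(header_path, data_path=None) -> Hypercube:
    """Read an ENVI header + binary raster pair into a :class:`Hypercube`.

    ``data_path`` defaults to the header path with the ``.hdr`` suffix
    stripped (the common ``cube.raw`` / ``cube.raw.hdr`` convention) or
    replaced by ``.img``.
    """
    header_path = Path(header_path)
    if data_path is None:
        if header_path.suffix == ".hdr":
            candidate = header_path.with_suffix("")
            data_path = candidate if candidate.exists() else header_path.with_suffix(".img")
        else:
            raise EnviFormatError("cannot infer data path from header name; pass data_path")
    data_path = Path(data_path)

    fields = _parse_envi_header(header_path)
    lines = int(_require(fields, "lines"))
    samples = int(_require(fields, "samples"))
    bands = int(_require(fields, "bands"))
    dtype_code = int(_require(fields, "data type"))
    interleave = fields.get("interleave", "bsq").lower()
    byte_order = int(fields.get("byte order", "0"))
    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if byte_order == 1:
        dtype = dtype.newbyteorder(">")

    wl_raw = _require(fields, "wavelength")
    wavelengths = np.array(
        [float(tok) for tok in wl_raw.strip("{} \n").replace("\n", ",").split(",") if tok.strip()]
    )
    if len(wavelengths) != bands:
        raise EnviFormatError(
            f"header declares bands={bands} but wavelength list has {len(wavelengths)} entries"
        )

    expected = lines * samples * bands * dtype.itemsize
    actual = data_path.stat().st_size
    if actual != expected:
        raise EnviFormatError(
            f"{data_path}: file size {actual} does not match "
            f"lines*samples*bands*itemsize = {expected}"
        )

    flat = np.fromfile(data_path, dtype=dtype)
    if interleave == "bsq":
        cube = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = flat.reshape(lines, samples, bands)
    else:
        raise EnviFormatError(f"unknown interleave {interleave!r}")

    kind = fields.get("hsiplate kind", "raw").strip()
    if kind not in ("raw", "reflectance"):
        kind = "raw"
    return Hypercube(np.ascontiguousarray(cube), wavelengths, kind=kind)


def write_envi(cube: Hypercube, header_path, data_path=None) -> tuple[Path, Path]:
    """Write ``cube`` as a BSQ ENVI pair; returns (header_path, data_path).

    Reflectance cubes are stored as 32-bit float, raw cubes as 16-bit
    unsigned (values clipped to the uint16 range), matching line-scan HSI
    practice.  Round-trips are bit-exact for the stored datatype.
    """
    header_path = Path(header_path)
    if data_path is None:
        if header_path.suffix != ".hdr":
            raise EnviFormatError("header path must end in .hdr when data_path is omitted")
        data_path = header_path.with_suffix("")
    data_path = Path(data_path)

    if cube.kind == "reflectance":
        out = cube.data.astype(np.float32)
    else:
        out = np.clip(np.round(cube.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    dtype_code = _DTYPE_CODES[out.dtype]

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {hsiplate hypercube}\n"
        f"samples = {cube.samples}\n"
        f"lines = {cube.lines}\n"
        f"bands = {cube.bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {dtype_code}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"hsiplate kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    out.transpose(2, 0, 1).tofile(data_path)
    return header_path, data_path


def calibrate_reflectance(
    raw: Hypercube,
    dark,
    white,
    clip_policy: tuple[float, float] | None = (0.0, 2.0),
) -> Hypercube:
    """Convert raw counts to reflectance, ``R = (I - D) / (W - D)``.

    ``dark`` and ``white`` may be full cubes, per-band 2-D reference frames
    (averaged over scan lines internally), or anything broadcastable to the
    raw array.  Full reference cubes are collapsed to per-band frames by
    averaging over the line axis before division, the usual treatment for
    line-scan references.

    Parameters
    ----------
    clip_policy : (low, high) or None
        Reflectance is clipped into this interval; specular metal pixels can
        legitimately exceed 1, hence the default upper bound of 2.  ``None``
        disables clipping.  The number of clipped values is recorded on the
        returned cube as ``clipped_count``.
    """
    if raw.kind != "raw":
        raise ValueError("calibrate_reflectance expects a raw-count cube")

    def _as_reference(ref):
        if isinstance(ref, Hypercube):
            ref = ref.data
        ref = np.asarray(ref, dtype=np.float64)
        if ref.ndim == 3:
            # collapse scan lines -> per-band 2-D frame (samples x bands)
            ref = ref.mean(axis=0)
        return ref

    d = _as_reference(dark)
    w = _as_reference(white)
    denom = w - d
    if np.any(denom <= 0):
        raise ValueError(
            "degenerate references: white must exceed dark everywhere "
            f"({np.count_nonzero(denom <= 0)} offending values)"
        )
    refl = (raw.data.astype(np.float64) - d) / denom
    clipped = 0
    if clip_policy is not None:
        lo, hi = clip_policy
        clipped = int(np.count_nonzero((refl < lo) | (refl > hi)))
        refl = np.clip(refl, lo, hi)
    if not np.all(np.isfinite(refl)):
        raise FloatingPointError("non-finite reflectance after calibration")
    out = Hypercube(refl.astype(np.float32), raw.wavelengths.copy(), kind="reflectance")
    out.clipped_count = clipped  # type: ignore[attr-defined]
    return out


def band_image(cube: Hypercube, wavelength_nm: float) -> Image2D:
    """Extract the 2-D band slice whose center is nearest ``wavelength_nm``."""
    lo, hi = cube.wavelengths[0], cube.wavelengths[-1]
    if not (lo <= wavelength_nm <= hi):
        raise ValueError(f"wavelength {wavelength_nm} nm outside cube range [{lo}, {hi}] nm")
    idx = cube.band_index(wavelength_nm)
    return Image2D(cube.data[:, :, idx], wavelength_nm=float(cube.wavelengths[idx]))


def mean_spectrum(cube: Hypercube, mask: np.ndarray) -> np.ndarray:
    """Per-band mean spectrum over the True pixels of ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match cube spatial shape")
    if not mask.any():
        raise ValueError("mean_spectrum over an empty mask")
    return cube.data[mask].mean(axis=0)


def write_hdf5(cube: Hypercube, path) -> Path:
    """Export a cube as HDF5 (datasets ``data``/``wavelengths``, attr ``kind``)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=cube.data)
        f.create_dataset("wavelengths", data=cube.wavelengths)
        f.attrs["kind"] = cube.kind
    return path


def read_hdf5(path) -> Hypercube:
    with h5py.File(path, "r") as f:
        return Hypercube(f["data"][()], f["wavelengths"][()], kind=str(f.attrs["kind"]))
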