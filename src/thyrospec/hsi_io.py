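"""Hyperspectral cube, label-mask and case-container I/O.

Cubes are exchanged as a raw binary stream plus a minimal ENVI-compatible
ASCII header (keys: samples, lines, bands, data type, interleave, wavelength).
The native layout is Band-Interleaved-by-Pixel (BIP): all bands of one pixel
are contiguous, i.e. the band index varies fastest.  BIL and BSQ streams are
also read and converted to the in-memory (row, col, band) order.

Label masks use integer codes 0=background, 1=normal tissue, 2=benign nodule,
3=malignant nodule and are stored as single-channel 8-bit PNG or as a dataset
inside the HDF5 case container.  A case container bundles cube, mask, white
and dark reference frames and the case-level diagnosis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

from thyrospec.errors import (
    CorruptFileError,
    ShapeError,
    UnsupportedFormatError,
)

# label-mask codes
BACKGROUND = 0
NORMAL = 1
BENIGN = 2
MALIGNANT = 3
LABEL_CODES = (BACKGROUND, NORMAL, BENIGN, MALIGNANT)

#: mask code -> binary class label used by the classifier (benign=0, malignant=1)
NODULE_CLASS = {BENIGN: 0, MALIGNANT: 1}

_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperCube:
    """A 3-D spectral image indexed (row, col, band) with wavelength metadata.

    Parameters
    ----------
    data
        Nonnegative array of shape ``(rows, cols, bands)``.
    wavelengths
        Strictly increasing band-centre wavelengths in nanometres,
        length equal to the band count.
    bit_depth
        ADC bit depth of the sensor; raw counts must fit in it.
    units
        Either ``"raw_counts"`` or ``"reflectance"``.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    bit_depth: int = 12
    units: str = "raw_counts"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.validate()

    # -- geometry ---------------------------------------------------------
    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def validate(self) -> None:
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ShapeError(f"cube must be 3-D with all dims >= 1, got {self.data.shape}")
        if self.wavelengths.shape != (self.n_bands,):
            raise ShapeError(
                f"wavelength list length {self.wavelengths.size} != band count {self.n_bands}"
            )
        if self.n_bands > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.units not in ("raw_counts", "reflectance"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be positive")
        if self.units == "raw_counts":
            top = 2 ** self.bit_depth - 1
            lo, hi = self.data.min(), self.data.max()
            if lo < 0 or hi > top:
                raise ValueError(
                    f"raw counts outside [0, {top}]: min={lo}, max={hi}"
                )


@dataclass
class LabelMask:
    """Per-pixel class codes matching a cube's spatial grid."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ShapeError("mask must be 2-D")
        if not np.isin(self.labels, LABEL_CODES).all():
            bad = np.unique(self.labels[~np.isin(self.labels, LABEL_CODES)])
            raise ValueError(f"mask contains invalid codes {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class CaseRecord:
    """One patient: cube, label mask, reference frames and diagnosis."""

    case_id: str
    diagnosis: str  # "benign" | "malignant"
    cube: HyperCube
    mask: LabelMask
    white_ref: HyperCube
    dark_ref: HyperCube
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis not in ("benign", "malignant"):
            raise ValueError(f"diagnosis must be benign/malignant, got {self.diagnosis!r}")
        bands = self.cube.n_bands
        if self.white_ref.n_bands != bands or self.dark_ref.n_bands != bands:
            raise ShapeError("cube and reference frames must share the band count")
        if self.mask.shape != (self.cube.rows, self.cube.cols):
            raise ShapeError("mask shape must match cube spatial shape")
        codes = set(np.unique(self.mask.labels).tolist())
        own = BENIGN if self.diagnosis == "benign" else MALIGNANT
        other = MALIGNANT if self.diagnosis == "benign" else BENIGN
        if own not in codes or other in codes:
            raise ValueError(
                f"case {self.case_id}: mask codes {sorted(codes)} inconsistent "
                f"with diagnosis {self.diagnosis!r}"
            )


# ---------------------------------------------------------------------------
# ENVI-style header + raw binary
# ---------------------------------------------------------------------------

def _default_header_path(path: str | Path) -> Path:
    return Path(str(path) + ".hdr")


def write_header(header_path: str | Path, rows: int, cols: int, bands: int,
                 dtype: np.dtype, wavelengths: np.ndarray, bit_depth: int,
                 interleave: str = "bip", units: str = "raw_counts") -> None:
    dtype = np.dtype(dtype)
    if dtype not in _ENVI_CODES:
        raise UnsupportedFormatError(f"dtype {dtype} has no ENVI code")
    wl = ", ".join(f"{w:.6g}" for w in np.asarray(wavelengths))
    text = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"bit depth = {bit_depth}\n"
        f"units = {units}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    Path(header_path).write_text(text)


def read_header(header_path: str | Path) -> dict:
    """Parse a minimal ENVI-style ASCII header into a dict."""
    text = Path(header_path).read_text()
    # fold wavelength braces onto one logical value
    fields: dict[str, str] = {}
    for m in re.finditer(r"^\s*([a-z ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)\s*$",
                         text, re.MULTILINE | re.DOTALL | re.IGNORECASE):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    out = {
        "rows": int(fields["lines"]),
        "cols": int(fields["samples"]),
        "bands": int(fields["bands"]),
        "interleave": fields.get("interleave", "bip").lower(),
        "bit_depth": int(fields.get("bit depth", 12)),
        "units": fields.get("units", "raw_counts"),
    }
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise UnsupportedFormatError(f"ENVI data type {code} unsupported")
    out["dtype"] = np.dtype(_ENVI_DTYPES[code])
    wl_text = fields.get("wavelength", "")
    wl = [float(t) for t in re.findall(r"[-+0-9.eE]+", wl_text)]
    if wl and len(wl) != out["bands"]:
        raise CorruptFileError(
            f"header lists {len(wl)} wavelengths for {out['bands']} bands"
        )
    out["wavelengths"] = np.asarray(wl) if wl else np.arange(out["bands"], dtype=float)
    return out


def read_cube(path: str | Path, header: str | Path | None = None) -> HyperCube:
    """Read a raw cube described by an ENVI-style header.

    The stream is validated against the declared geometry; BIP, BIL and BSQ
    interleaves are accepted and returned in (row, col, band) memory order
    with the pixel spectral order of the stream preserved.
    """
    header = _default_header_path(path) if header is None else header
    h = read_header(header)
    rows, cols, bands = h["rows"], h["cols"], h["bands"]
    if h["interleave"] not in ("bip", "bil", "bsq"):
        raise UnsupportedFormatError(f"interleave {h['interleave']!r} unsupported")
    expected = rows * cols * bands * h["dtype"].itemsize
    actual = Path(path).stat().st_size
    if actual != expected:
        raise CorruptFileError(
            f"{path}: stream is {actual} bytes, header implies {expected}"
        )
    flat = np.fromfile(str(path), dtype=h["dtype"])
    if h["interleave"] == "bip":
        data = flat.reshape(rows, cols, bands)
    elif h["interleave"] == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bsq
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    return HyperCube(np.ascontiguousarray(data), h["wavelengths"],
                     bit_depth=h["bit_depth"], units=h["units"])


def write_cube(cube: HyperCube, path: str | Path,
               header: str | Path | None = None) -> Path:
    """Write a cube as raw BIP binary plus its sidecar header."""
    path = Path(path)
    header = _default_header_path(path) if header is None else Path(header)
    data = np.ascontiguousarray(cube.data)  # (row, col, band) C-order == BIP
    data.tofile(str(path))
    write_header(header, cube.rows, cube.cols, cube.n_bands, data.dtype,
                 cube.wavelengths, cube.bit_depth, "bip", cube.units)
    return path


def pseudo_color(cube: HyperCube, band_triplet: tuple[int, int, int]) -> np.ndarray:
    """Render three bands as an RGB preview, each min-max rescaled to [0, 1].

    A constant band maps to all zeros.
    """
    rgb = np.zeros((cube.rows, cube.cols, 3), dtype=float)
    for c, b in enumerate(band_triplet):
        if not 0 <= b < cube.n_bands:
            raise IndexError(f"band index {b} out of range [0, {cube.n_bands})")
        band = cube.data[:, :, b].astype(float)
        lo, hi = band.min(), band.max()
        if hi > lo:
            rgb[:, :, c] = (band - lo) / (hi - lo)
    return rgb


# ---------------------------------------------------------------------------
# PNG masks
# ---------------------------------------------------------------------------

def write_mask_png(mask: LabelMask, path: str | Path) -> Path:
    Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(str(path))
    return Path(path)


def read_mask_png(path: str | Path) -> LabelMask:
    img = Image.open(str(path))
    if img.mode != "L":
        img = img.convert("L")
    return LabelMask(np.asarray(img, dtype=np.uint8))


# ---------------------------------------------------------------------------
# HDF5 case container
# ---------------------------------------------------------------------------

def _save_cube_group(grp: h5py.Group, cube: HyperCube) -> None:
    grp.create_dataset("data", data=cube.data)
    grp.create_dataset("wavelengths", data=cube.wavelengths)
    grp.attrs["bit_depth"] = cube.bit_depth
    grp.attrs["units"] = cube.units


def _load_cube_group(grp: h5py.Group) -> HyperCube:
    return HyperCube(grp["data"][()], grp["wavelengths"][()],
                     bit_depth=int(grp.attrs["bit_depth"]),
                     units=str(grp.attrs["units"]))


def save_case(case: CaseRecord, path: str | Path) -> Path:
    """Write one case (cube, mask, references, diagnosis) to an HDF5 file."""
    with h5py.File(str(path), "w") as f:
        f.attrs["case_id"] = case.case_id
        f.attrs["diagnosis"] = case.diagnosis
        _save_cube_group(f.create_group("cube"), case.cube)
        _save_cube_group(f.create_group("white_ref"), case.white_ref)
        _save_cube_group(f.create_group("dark_ref"), case.dark_ref)
        f.create_dataset("mask", data=case.mask.labels.astype(np.uint8))
    return Path(path)


def load_case(path: str | Path) -> CaseRecord:
    with h5py.File(str(path), "r") as f:
        return CaseRecord(
            case_id=str(f.attrs["case_id"]),
            diagnosis=str(f.attrs["diagnosis"]),
            cube=_load_cube_group(f["cube"]),
            mask=LabelMask(f["mask"][()]),
            white_ref=_load_cube_group(f["white_ref"]),
            dark_ref=_load_cube_group(f["dark_ref"]),
        )
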