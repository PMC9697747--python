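"""ENVI-format I/O for hyperspectral cubes.

Line-scan spectral cameras (e.g. the 400-1000 nm, 204-band instruments used
for intra-oral capture) emit a plain-text ENVI header next to a raw binary
file.  This module reads and writes that dialect and carries the cube in
memory as a ``SpectralCube``: a ``rows x cols x bands`` array plus the band
center wavelengths in nm.

Coordinate convention
---------------------
Row index 0 is the **top** of the image.  In the capture geometry used for
anterior teeth (chin rest, camera level with the incisors) the top of the
image is the gingival side, so the cervical third of a tooth occupies the
smallest row indices.  Downstream region code relies on this.
"""

from __future__ import annotations

import re
import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "CubeKind",
    "SpectralCube",
    "EnviFormatError",
    "EnviMetadataError",
    "EmptySelectionError",
    "read_envi_cube",
    "write_envi_cube",
    "crop_spectral_range",
]


class EnviFormatError(ValueError):
    """Binary/header inconsistency or unsupported ENVI layout."""


class EnviMetadataError(ValueError):
    """Required header metadata missing or contradictory."""


class EmptySelectionError(ValueError):
    """A spectral selection matched no bands."""


class CubeKind(str, Enum):
    RAW_COUNTS = "raw_counts"
    REFLECTANCE = "reflectance"


# ENVI numeric codes for the supported sample types: unsigned 16-bit camera
# counts and 32/64-bit float reflectance.  Other codes are rejected.
_DTYPE_TO_CODE = {
    np.dtype(np.uint16): 12,
    np.dtype(np.float32): 4,
    np.dtype(np.float64): 5,
}
_CODE_TO_DTYPE = {v: k for k, v in _DTYPE_TO_CODE.items()}

_WAVELENGTH_BOUNDS = (300.0, 1100.0)


@dataclass
class SpectralCube:
    """A wavelength-indexed raster of sensor counts or reflectance.

    Parameters
    ----------
    data:
        ``rows x cols x bands`` array, non-negative.  ``uint16`` for raw
        counts, ``float32``/``float64`` for reflectance.
    wavelengths:
        Band-center wavelengths in nm, strictly increasing, all within
        300-1100 nm.
    kind:
        Whether values are raw sensor counts or reflectance fractions.
        Reflectance above 1 is legal (specular pixels) and merely counted
        by :meth:`n_above_unity`; clipping happens only at colorimetric
        integration.
    meta:
        Free-form header fields (integration time, capture id, ...).  Keys
        and values must be ASCII; non-ASCII entries are rejected at write
        time so the header round-trips bit-exactly.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: CubeKind = CubeKind.REFLECTANCE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.kind = CubeKind(self.kind)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise EnviFormatError(
                f"cube data must be 3-D (rows x cols x bands), got ndim={self.data.ndim}"
            )
        if self.data.size == 0:
            raise EnviFormatError("cube has no pixels")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise EnviMetadataError(
                f"{len(self.wavelengths)} wavelengths for {self.data.shape[2]} bands"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise EnviMetadataError("wavelengths must be strictly increasing")
        lo, hi = _WAVELENGTH_BOUNDS
        if self.wavelengths[0] < lo or self.wavelengths[-1] > hi:
            raise EnviMetadataError(f"wavelengths must lie within [{lo}, {hi}] nm")
        if self.data.dtype not in _DTYPE_TO_CODE:
            raise EnviFormatError(
                f"unsupported dtype {self.data.dtype}; use uint16, float32 or float64"
            )
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.all(np.isfinite(self.data)):
                raise EnviFormatError("cube contains non-finite values")
            if self.data.min() < 0:
                raise EnviFormatError("cube values must be non-negative")

    # -- convenience --------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def n_above_unity(self) -> int:
        """Count of reflectance samples above 1 (specular-pixel quality flag)."""
        if self.kind is not CubeKind.REFLECTANCE:
            return 0
        return int(np.count_nonzero(self.data > 1.0))

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


# ---------------------------------------------------------------------------
# header parsing / writing
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("samples", "lines", "bands", "data type", "interleave")


def _parse_header(text: str) -> dict:
    """Parse an ENVI ``key = value`` header, honouring ``{...}`` blocks."""
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("missing ENVI magic line")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # Values in braces may span lines; normalise them to one line first.
    pattern = re.compile(r"^\s*([^={}\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip() if val.endswith("}") else val[1:].strip()
            val = re.sub(r"\s+", " ", val)
        fields[key] = val
    return fields


def _header_path_pair(header_path: Path) -> tuple[Path, Path]:
    header_path = Path(header_path)
    stem = header_path.with_suffix("")
    for ext in (".raw", ".dat", ".img", ".bin", ""):
        cand = stem.with_suffix(ext) if ext else stem
        if cand.exists() and cand != header_path:
            return header_path, cand
    raise FileNotFoundError(f"no companion binary found for {header_path}")


def read_envi_cube(header_path: str | Path) -> SpectralCube:
    """Read an ENVI header + binary pair into a :class:`SpectralCube`.

    The stored interleave (BSQ, BIL or BIP) and byte order are undone so the
    returned array is always ``rows x cols x bands`` in native order.

    Raises
    ------
    FileNotFoundError
        Header or companion binary missing.
    EnviMetadataError
        No wavelength list, or its length contradicts ``bands``.
    EnviFormatError
        Declared dimensions inconsistent with the binary file size, or an
        unsupported data type / interleave.
    """
    header_path, data_path = _header_path_pair(Path(header_path))
    fields = _parse_header(header_path.read_text())

    for key in _REQUIRED_KEYS:
        if key not in fields:
            raise EnviMetadataError(f"header lacks required field '{key}'")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    interleave = fields["interleave"].lower()
    byte_order = int(fields.get("byte order", "0"))
    offset = int(fields.get("header offset", "0"))

    if code not in _CODE_TO_DTYPE:
        raise EnviFormatError(f"unsupported ENVI data type code {code}")
    dtype = _CODE_TO_DTYPE[code].newbyteorder("<" if byte_order == 0 else ">")

    if "wavelength" not in fields:
        raise EnviMetadataError("header lacks a wavelength list")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].split(",") if tok.strip()]
    )
    if len(wavelengths) != bands:
        raise EnviMetadataError(
            f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
        )

    expected = samples * lines * bands * dtype.itemsize
    actual = data_path.stat().st_size - offset
    if actual != expected:
        raise EnviFormatError(
            f"binary size {actual} B does not match declared "
            f"{lines}x{samples}x{bands} ({expected} B)"
        )

    flat = np.fromfile(data_path, dtype=dtype, offset=offset)
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    else:
        raise EnviFormatError(f"unsupported interleave '{interleave}'")
    data = np.ascontiguousarray(data).astype(dtype.newbyteorder("="), copy=False)

    kind = CubeKind(fields.get("cube kind", "raw_counts" if code == 12 else "reflectance"))
    reserved = set(_REQUIRED_KEYS) | {
        "byte order", "header offset", "wavelength", "wavelength units",
        "file type", "cube kind",
    }
    meta = {k: v for k, v in fields.items() if k not in reserved}
    return SpectralCube(data=data, wavelengths=wavelengths, kind=kind, meta=meta)


def write_envi_cube(
    cube: SpectralCube,
    header_path: str | Path,
    interleave: str = "bsq",
    byte_order: int | None = None,
) -> Path:
    """Write ``cube`` as an ENVI header (+ ``.raw`` binary) pair.

    ``read_envi_cube`` inverts this bit-exactly for every supported dtype,
    interleave and byte order.  Returns the header path.
    """
    cube.validate()
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise EnviFormatError(f"unsupported interleave '{interleave}'")
    if byte_order is None:
        byte_order = 0 if sys.byteorder == "little" else 1
    for k, v in cube.meta.items():
        if not (str(k).isascii() and str(v).isascii()):
            raise EnviMetadataError(f"non-ASCII meta entry {k!r}; ENVI headers are ASCII")

    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    data_path = header_path.with_suffix(".raw")
    rows, cols, bands = cube.shape

    dtype = cube.data.dtype.newbyteorder("<" if byte_order == 0 else ">")
    if interleave == "bsq":
        arr = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)
    else:
        arr = cube.data
    np.ascontiguousarray(arr).astype(dtype).tofile(data_path)

    wl = ", ".join(f"{w:.6f}".rstrip("0").rstrip(".") for w in cube.wavelengths)
    lines = [
        "ENVI",
        "file type = ENVI Standard",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        f"data type = {_DTYPE_TO_CODE[cube.data.dtype]}",
        f"interleave = {interleave}",
        f"byte order = {byte_order}",
        f"cube kind = {cube.kind.value}",
        "wavelength units = Nanometers",
        "wavelength = {" + wl + "}",
    ]
    lines += [f"{k} = {v}" for k, v in cube.meta.items()]
    header_path.write_text("\n".join(lines) + "\n")
    return header_path


def crop_spectral_range(cube: SpectralCube, lo_nm: float, hi_nm: float) -> SpectralCube:
    """Keep exactly the bands with ``lo_nm <= wavelength <= hi_nm``.

    Idempotent for a fixed range.  Raises :class:`EmptySelectionError` when
    no band falls inside the range.
    """
    if not lo_nm < hi_nm:
        raise ValueError(f"need lo_nm < hi_nm, got [{lo_nm}, {hi_nm}]")
    keep = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    if not keep.any():
        raise EmptySelectionError(
            f"no band in [{lo_nm}, {hi_nm}] nm "
            f"(cube covers {cube.wavelengths[0]:.1f}-{cube.wavelengths[-1]:.1f} nm)"
        )
    return SpectralCube(
        data=cube.data[:, :, keep],
        wavelengths=cube.wavelengths[keep],
        kind=cube.kind,
        meta=dict(cube.meta),
    )
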