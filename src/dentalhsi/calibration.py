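"""Dark/gray flat-field correction of raw cubes to spectral reflectance.

A raw capture mixes the tooth's reflectance with the sensor's dark offset
and with spectrally and spatially non-uniform illumination.  Two companion
captures taken with identical settings — a dark frame (lens capped) and a
matt diffuse gray ceramic tile of known reflectance — cancel both:

    R(x, y, l) = (I_raw - I_dark) / (I_gray - I_dark) * R_tile(l)

Pixels whose gray-minus-dark denominator is (near) zero carry no usable
reference signal; they are flagged ``unstable_reference`` and excluded from
all downstream means.  Saturated pixels are detected separately on the raw
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .envi import CubeKind, SpectralCube

__all__ = [
    "ReferenceTile",
    "PixelQuality",
    "AlignmentError",
    "CoverageError",
    "flat_field_correct",
    "detect_saturation",
    "resample_spectrum",
]

#: Default denominator threshold, as a fraction of full scale, below which a
#: pixel's gray reference is considered unstable.
DEFAULT_EPSILON_FRACTION = 1e-6


class AlignmentError(ValueError):
    """Cubes or spectra do not share shape/wavelength grids."""


class CoverageError(ValueError):
    """A tabulated spectrum does not cover the requested wavelengths."""


@dataclass
class ReferenceTile:
    """Calibrated reflectance spectrum of the gray reference tile.

    Values must lie in (0, 1]; wavelengths strictly increasing (nm).
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    name: str = "gray-tile"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise AlignmentError("tile wavelengths and reflectance differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("tile wavelengths must be strictly increasing")
        if np.any(self.reflectance <= 0) or np.any(self.reflectance > 1):
            raise ValueError("tile reflectance must lie in (0, 1]")

    @classmethod
    def flat(cls, wavelengths, value: float = 0.40, name: str = "flat-gray") -> "ReferenceTile":
        """Spectrally flat tile — the default stand-in when the tile's
        calibration certificate is unavailable."""
        wavelengths = np.asarray(wavelengths, dtype=float)
        return cls(wavelengths, np.full_like(wavelengths, value), name=name)

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "ReferenceTile":
        """Load a two-column CSV (wavelength_nm, reflectance)."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("tile CSV needs two columns: wavelength_nm, reflectance")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   name=name or Path(path).stem)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "reflectance": self.reflectance}
        ).to_csv(path, index=False)


@dataclass
class PixelQuality:
    """Boolean per-pixel quality masks sharing the cube's spatial shape."""

    saturated: np.ndarray
    unstable_reference: np.ndarray

    def __post_init__(self) -> None:
        self.saturated = np.asarray(self.saturated, dtype=bool)
        self.unstable_reference = np.asarray(self.unstable_reference, dtype=bool)
        if self.saturated.shape != self.unstable_reference.shape:
            raise AlignmentError("quality masks differ in shape")

    @classmethod
    def clean(cls, shape: tuple[int, int]) -> "PixelQuality":
        return cls(np.zeros(shape, bool), np.zeros(shape, bool))

    @property
    def valid(self) -> np.ndarray:
        """Pixels that survived every quality flag."""
        return ~(self.saturated | self.unstable_reference)

    def merge(self, other: "PixelQuality") -> "PixelQuality":
        return PixelQuality(
            self.saturated | other.saturated,
            self.unstable_reference | other.unstable_reference,
        )

    def to_tiff(self, path: str | Path) -> None:
        """Export the combined validity mask as an 8-bit TIFF (255 = valid)."""
        import tifffile

        tifffile.imwrite(str(path), (self.valid * 255).astype(np.uint8))


def resample_spectrum(
    wavelengths,
    values,
    target_wavelengths,
    extrapolate: bool = False,
) -> np.ndarray:
    """Piecewise-linear resampling of a tabulated spectrum.

    Extrapolation outside the source hull is forbidden by default and raises
    :class:`CoverageError`; with ``extrapolate=True`` the boundary values are
    held constant instead.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.asarray(values, dtype=float)
    target = np.asarray(target_wavelengths, dtype=float)
    if wavelengths.ndim != 1 or wavelengths.shape != values.shape:
        raise AlignmentError("spectrum wavelengths/values length mismatch")
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("source wavelengths must be strictly increasing")
    if not extrapolate and (
        target.min() < wavelengths[0] or target.max() > wavelengths[-1]
    ):
        raise CoverageError(
            f"target range [{target.min():.1f}, {target.max():.1f}] nm exceeds "
            f"source hull [{wavelengths[0]:.1f}, {wavelengths[-1]:.1f}] nm"
        )
    return np.interp(target, wavelengths, values)


def _as_reference_cube(ref, like: SpectralCube, what: str) -> np.ndarray:
    """Accept a cube, a per-band spectrum, or a scalar as a dark/gray
    reference and broadcast it to ``like``'s full shape (counts, float64)."""
    if isinstance(ref, SpectralCube):
        if ref.shape != like.shape:
            raise AlignmentError(
                f"{what} cube shape {ref.shape} != raw shape {like.shape}"
            )
        if not np.array_equal(ref.wavelengths, like.wavelengths):
            raise AlignmentError(f"{what} cube wavelengths differ from raw cube")
        return ref.data.astype(np.float64)
    arr = np.asarray(ref, dtype=np.float64)
    if arr.ndim == 0:
        return np.broadcast_to(arr, like.shape)
    if arr.ndim == 1:
        if arr.size != like.n_bands:
            raise AlignmentError(f"{what} spectrum has {arr.size} bands, cube has {like.n_bands}")
        return np.broadcast_to(arr, like.shape)
    raise AlignmentError(f"{what} must be a SpectralCube, spectrum or scalar")


def flat_field_correct(
    raw: SpectralCube,
    dark,
    gray,
    tile: ReferenceTile,
    epsilon: float | None = None,
    full_scale: float = 65535.0,
) -> tuple[SpectralCube, PixelQuality]:
    """Convert raw counts to reflectance by dark/gray flat-field correction.

    Parameters
    ----------
    raw:
        Raw counts cube of the scene.
    dark, gray:
        Dark-frame and gray-tile captures with identical settings.  Either
        full cubes (same shape and wavelengths as ``raw``), per-band
        spectra, or scalars (spatially constant references).
    tile:
        Calibrated reflectance of the gray tile; resampled onto the cube's
        wavelength grid (its tabulation must cover the cube's range).
    epsilon:
        Absolute denominator threshold below which a pixel is flagged
        ``unstable_reference``.  Default ``1e-6 * full_scale``.

    Returns
    -------
    (reflectance_cube, quality)
        Negative numerators are floored at 0, so reflectance is >= 0
        everywhere.  Values above 1 (specular highlights) are retained, not
        clipped.  Unstable pixels get reflectance 0 across all bands and
        must be excluded from downstream statistics via ``quality``.
    """
    if raw.kind is not CubeKind.RAW_COUNTS:
        raise ValueError("flat_field_correct expects a raw_counts cube")
    if epsilon is None:
        epsilon = DEFAULT_EPSILON_FRACTION * full_scale

    dark_arr = _as_reference_cube(dark, raw, "dark")
    gray_arr = _as_reference_cube(gray, raw, "gray")
    tile_r = resample_spectrum(tile.wavelengths, tile.reflectance, raw.wavelengths)

    numerator = np.maximum(raw.data.astype(np.float64) - dark_arr, 0.0)
    denominator = gray_arr - dark_arr

    unstable = np.any(np.abs(denominator) < epsilon, axis=2)
    safe_den = np.where(np.abs(denominator) < epsilon, 1.0, denominator)
    reflectance = numerator / safe_den * tile_r[None, None, :]
    reflectance = np.maximum(reflectance, 0.0)
    reflectance[unstable, :] = 0.0

    cube = SpectralCube(
        data=reflectance,
        wavelengths=raw.wavelengths.copy(),
        kind=CubeKind.REFLECTANCE,
        meta={**raw.meta, "calibration": f"flat-field ({tile.name})"},
    )
    quality = PixelQuality(
        saturated=np.zeros(unstable.shape, bool), unstable_reference=unstable
    )
    return cube, quality


def detect_saturation(
    cube: SpectralCube, full_scale: float, guard: float = 0.0
) -> PixelQuality:
    """Flag pixels with any band at or above ``full_scale * (1 - guard)``.

    ``guard`` (default 0) widens the margin below full scale that already
    counts as saturated, for sensors that clip softly.
    """
    if full_scale <= 0:
        raise ValueError("full_scale must be positive")
    if not 0 <= guard < 1:
        raise ValueError("guard must lie in [0, 1)")
    threshold = full_scale * (1.0 - guard)
    saturated = np.any(cube.data.astype(np.float64) >= threshold, axis=2)
    return PixelQuality(
        saturated=saturated, unstable_reference=np.zeros(saturated.shape, bool)
    )
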