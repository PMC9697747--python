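"""Per-pixel Lab images, tooth masks, cervical/middle/incisal thirds and
per-third mean CIELAB extraction.

Orientation contract: row 0 is the top of the image, which in the chin-rest
capture geometry is the gingival side.  The cervical third is therefore the
minimal-row band of the tooth mask and the incisal third the maximal-row
band; flipping an image vertically swaps the two exactly.

Thirds are delimited geometrically — equal division of the mask's bounding
rows — rather than by equal pixel counts, matching the anatomical depiction
of crown thirds and staying deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import AlignmentError, PixelQuality
from .colorimetry import (
    LabColor,
    ObserverIlluminantTable,
    lab_image_from_reflectance,
)
from .envi import CubeKind, SpectralCube

__all__ = [
    "RegionLabel",
    "RegionMask",
    "LabImage",
    "ThirdStats",
    "ToothColorProfile",
    "EmptyMaskError",
    "DegenerateMaskError",
    "EmptyThirdError",
    "cube_to_lab_image",
    "threshold_tooth_mask",
    "split_thirds",
    "mean_lab_per_third",
    "profiles_to_csv",
    "profiles_from_csv",
]

THIRDS = ("cervical", "middle", "incisal")


class EmptyMaskError(ValueError):
    """Tooth segmentation produced no pixels."""


class DegenerateMaskError(ValueError):
    """Mask too short (fewer than 3 bounding rows) to split into thirds."""


class EmptyThirdError(ValueError):
    """A third contains no valid pixels to average."""


class RegionLabel(str, Enum):
    TOOTH = "tooth"
    CERVICAL = "cervical"
    MIDDLE = "middle"
    INCISAL = "incisal"
    BACKGROUND = "background"


@dataclass
class RegionMask:
    mask: np.ndarray
    label: RegionLabel = RegionLabel.TOOTH

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.label = RegionLabel(self.label)
        if self.mask.ndim != 2:
            raise ValueError("region mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.mask))

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(str(path), (self.mask * 255).astype(np.uint8))

    @classmethod
    def from_tiff(cls, path: str | Path, label: RegionLabel = RegionLabel.TOOTH) -> "RegionMask":
        import tifffile

        return cls(np.asarray(tifffile.imread(str(path))) > 0, label)


@dataclass
class LabImage:
    """Per-pixel CIELAB rasters plus a validity mask (pixels that survived
    saturation/reference quality flags)."""

    L_star: np.ndarray
    a_star: np.ndarray
    b_star: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.L_star, self.a_star, self.b_star, self.valid)}
        if len(shapes) != 1:
            raise AlignmentError("Lab rasters and validity mask differ in shape")
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.L_star.shape

    def chroma(self) -> np.ndarray:
        return np.hypot(self.a_star, self.b_star)


@dataclass(frozen=True)
class ThirdStats:
    """Mean, SD and pixel count of each CIELAB coordinate over one third."""

    mean: LabColor
    sd: tuple[float, float, float]
    n_pixels: int


@dataclass
class ToothColorProfile:
    """Mean L*, a*, b* (with SDs and pixel counts) per crown third of one
    tooth — the unit of result every comparison is built on."""

    tooth_id: str
    cervical: ThirdStats
    middle: ThirdStats
    incisal: ThirdStats

    def third(self, name: str) -> ThirdStats:
        if name not in THIRDS:
            raise KeyError(f"unknown third {name!r}")
        return getattr(self, name)

    @classmethod
    def from_means(
        cls,
        tooth_id: str,
        cervical: tuple[float, float, float],
        middle: tuple[float, float, float],
        incisal: tuple[float, float, float],
        sds: dict | None = None,
        n_pixels: int = 1,
    ) -> "ToothColorProfile":
        """Build a profile from bare per-third mean Lab triplets (e.g. a
        published table), with optional SDs."""
        sds = sds or {}
        stats = {
            name: ThirdStats(
                mean=LabColor(*vals),
                sd=tuple(sds.get(name, (0.0, 0.0, 0.0))),
                n_pixels=n_pixels,
            )
            for name, vals in zip(THIRDS, (cervical, middle, incisal))
        }
        return cls(tooth_id=tooth_id, **stats)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def cube_to_lab_image(
    cube: SpectralCube,
    table: ObserverIlluminantTable,
    quality: PixelQuality | None = None,
) -> LabImage:
    """Convert a reflectance cube to a per-pixel CIELAB image.

    The cube must already be cropped to the colorimetric range and the table
    built on the cube's own wavelength grid.  Pixels flagged saturated or
    unstable_reference come out with ``valid = False``.
    """
    if cube.kind is not CubeKind.REFLECTANCE:
        raise ValueError("cube_to_lab_image expects a reflectance cube")
    if not np.array_equal(cube.wavelengths, table.wavelengths):
        raise AlignmentError("table was not built on the cube's wavelengths")
    L, a, b = lab_image_from_reflectance(cube.data, table)
    if quality is None:
        valid = np.ones(cube.shape[:2], bool)
    else:
        if quality.valid.shape != cube.shape[:2]:
            raise AlignmentError("quality masks do not match cube spatial shape")
        valid = quality.valid.copy()
    return LabImage(L_star=L, a_star=a, b_star=b, valid=valid)


# 4-connectivity for connected-component labelling.
_CONN4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def threshold_tooth_mask(
    lab: LabImage, min_L: float = 45.0, max_ab_radius: float = 40.0
) -> RegionMask:
    """Segment the tooth as the bright, low-chroma region of the Lab image.

    A pixel is a candidate iff it is valid, L* >= ``min_L`` and its chroma
    sqrt(a*^2 + b*^2) <= ``max_ab_radius``; the largest 4-connected
    candidate component is retained.  When the tooth outline is known (e.g.
    drawn manually), bypass this and supply a :class:`RegionMask` directly.
    """
    candidates = lab.valid & (lab.L_star >= min_L) & (lab.chroma() <= max_ab_radius)
    if not candidates.any():
        raise EmptyMaskError("no pixel satisfies the tooth criteria")
    labels, n = ndimage.label(candidates, structure=_CONN4)
    largest = int(np.argmax(ndimage.sum_labels(candidates, labels, range(1, n + 1)))) + 1
    return RegionMask(mask=labels == largest, label=RegionLabel.TOOTH)


def split_thirds(tooth: RegionMask) -> tuple[RegionMask, RegionMask, RegionMask]:
    """Split a tooth mask into cervical / middle / incisal thirds.

    The bounding rows [r0, r1] of the mask are cut at
    ``r0 + round(h/3)`` and ``r0 + round(2h/3)`` with ``h = r1 - r0 + 1``;
    the cervical third is the top band intersected with the mask, the
    incisal third the bottom band.  The three outputs partition the mask.
    """
    rows = np.flatnonzero(tooth.mask.any(axis=1))
    if rows.size == 0:
        raise EmptyMaskError("cannot split an empty mask")
    r0, r1 = int(rows[0]), int(rows[-1])
    h = r1 - r0 + 1
    if h < 3:
        raise DegenerateMaskError(f"mask spans only {h} rows; need >= 3")
    # round-half-up on integer thirds, e.g. h=10 -> cuts at 3 and 7
    cut1 = r0 + int(np.floor(h / 3 + 0.5))
    cut2 = r0 + int(np.floor(2 * h / 3 + 0.5))

    row_idx = np.arange(tooth.mask.shape[0])[:, None]
    bands = {
        RegionLabel.CERVICAL: row_idx < cut1,
        RegionLabel.MIDDLE: (row_idx >= cut1) & (row_idx < cut2),
        RegionLabel.INCISAL: row_idx >= cut2,
    }
    return tuple(
        RegionMask(mask=tooth.mask & band, label=label)
        for label, band in bands.items()
    )


def mean_lab_per_third(
    lab: LabImage,
    thirds: tuple[RegionMask, RegionMask, RegionMask],
    tooth_id: str = "tooth",
) -> ToothColorProfile:
    """Arithmetic mean and SD of L*, a*, b* over the valid pixels of each
    third.

    Averaging happens in Lab space (mean of per-pixel Lab values), the same
    statistic reported per crown third in shade studies; note this differs
    from averaging spectra first because the Lab transform is nonlinear.
    SDs are sample SDs (n-1) when a third has more than one pixel.
    Invariant to pixel order and to adding invalid pixels.
    """
    stats: dict[str, ThirdStats] = {}
    for name, region in zip(THIRDS, thirds):
        sel = region.mask & lab.valid
        n = int(np.count_nonzero(sel))
        if n == 0:
            raise EmptyThirdError(f"{name} third of {tooth_id!r} has no valid pixels")
        coords = np.stack([lab.L_star[sel], lab.a_star[sel], lab.b_star[sel]])
        means = coords.mean(axis=1)
        sds = coords.std(axis=1, ddof=1) if n > 1 else np.zeros(3)
        stats[name] = ThirdStats(
            mean=LabColor(*map(float, means)),
            sd=tuple(map(float, sds)),
            n_pixels=n,
        )
    return ToothColorProfile(tooth_id=tooth_id, **stats)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["tooth_id", "third", "L", "a", "b", "sd_L", "sd_a", "sd_b", "n_pixels"]


def profiles_to_csv(profiles, path: str | Path) -> pd.DataFrame:
    """Write tooth color profiles as a long-format CSV (one row per third)."""
    rows = []
    for p in profiles:
        for name in THIRDS:
            s = p.third(name)
            rows.append(
                [p.tooth_id, name, s.mean.L_star, s.mean.a_star, s.mean.b_star,
                 *s.sd, s.n_pixels]
            )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False)
    return df


def profiles_from_csv(path: str | Path) -> list[ToothColorProfile]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV lacks columns {sorted(missing)}")
    profiles = []
    for tooth_id, grp in df.groupby("tooth_id", sort=False):
        grp = grp.set_index("third")
        if set(THIRDS) - set(grp.index):
            raise ValueError(f"profile {tooth_id!r} lacks some thirds")
        stats = {}
        for name in THIRDS:
            row = grp.loc[name]
            stats[name] = ThirdStats(
                mean=LabColor(float(row["L"]), float(row["a"]), float(row["b"])),
                sd=(
                    float(row.get("sd_L", 0.0)),
                    float(row.get("sd_a", 0.0)),
                    float(row.get("sd_b", 0.0)),
                ),
                n_pixels=int(row.get("n_pixels", 1)),
            )
        profiles.append(ToothColorProfile(tooth_id=str(tooth_id), **stats))
    return profiles
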