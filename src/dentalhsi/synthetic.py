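"""Synthetic hyperspectral tooth scenes with known ground truth.

No raw intra-oral captures are publicly deposited for this kind of study,
so every pipeline stage is exercised against a forward model of the capture
instead:

* four rectangular "incisors" on a dark background, each with a
  cervical -> incisal reflectance gradient (cervical redder and yellower,
  middle lightest — the qualitative pattern shade studies report);
* a centred Gaussian illumination vignette with a linear spectral tilt
  (the spatially and spectrally non-uniform illumination that flat-field
  correction exists to cancel);
* a dark offset, a sensor gain and additive Gaussian read noise truncated
  to the sensor's range.

``render_scene`` returns the raw/dark/gray capture trio plus a
:class:`SyntheticSceneTruth` holding the noise-free reflectance, the exact
masks and the noise-free per-third Lab profiles, computed through the same
colorimetry tables the pipeline under test uses — so parameter-recovery
tests compare like with like.

Tooth reflectance model
-----------------------
A tooth spectrum is a sigmoid edge

    R(l) = clip(base + amp / (1 + exp(-(l - edge_nm) / slope_nm)), 0, 1)

monotone non-decreasing in wavelength: low reflectance in the blue rising
to a plateau in the red/NIR, the generic shape of dental hard tissue.
Moving the edge redder and deepening the blue trough makes a third redder
and yellower (cervical); raising the base lightens it (middle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import PixelQuality, ReferenceTile
from .colorimetry import build_table
from .envi import CubeKind, SpectralCube, crop_spectral_range
from .regions import (
    RegionLabel,
    RegionMask,
    ToothColorProfile,
    cube_to_lab_image,
    mean_lab_per_third,
    split_thirds,
)

__all__ = [
    "ToothSpectrumParams",
    "ToothPlacement",
    "SceneParams",
    "SyntheticSceneTruth",
    "tooth_reflectance",
    "render_scene",
    "table1_fixture",
    "TOOTH_ORDER",
]

TOOTH_ORDER = ("ULI1", "UCI1", "UCI2", "ULI2")


@dataclass(frozen=True)
class ToothSpectrumParams:
    """Sigmoid-edge reflectance parameters for one crown third."""

    base: float
    amp: float
    edge_nm: float
    slope_nm: float

    def __post_init__(self) -> None:
        if self.slope_nm <= 0:
            raise ValueError("slope_nm must be positive")
        if not 0 <= self.base <= 1 or self.amp < 0:
            raise ValueError("base must be in [0, 1] and amp non-negative")
        if self.base + self.amp > 1.05:
            raise ValueError("base + amp must not exceed 1.05 (pre-clip)")


def tooth_reflectance(p: ToothSpectrumParams, wavelengths) -> np.ndarray:
    """Evaluate the sigmoid-edge tooth reflectance on ``wavelengths`` (nm)."""
    wl = np.asarray(wavelengths, dtype=float)
    r = p.base + p.amp / (1.0 + np.exp(-(wl - p.edge_nm) / p.slope_nm))
    return np.clip(r, 0.0, 1.0)


# Per-third spectral presets.  Chosen so that, after conversion under
# D65/2-degree, the cervical third is redder (higher a*) and yellower
# (higher b*) than middle and incisal, and the middle third is lightest —
# with Lab values in the range reported for natural incisors.
_THIRD_PRESETS: dict[str, ToothSpectrumParams] = {
    "cervical": ToothSpectrumParams(base=0.22, amp=0.42, edge_nm=535.0, slope_nm=33.0),
    "middle": ToothSpectrumParams(base=0.42, amp=0.30, edge_nm=495.0, slope_nm=45.0),
    "incisal": ToothSpectrumParams(base=0.33, amp=0.27, edge_nm=505.0, slope_nm=48.0),
}

#: Flat dark-gray background reflectance (well below any tooth).
_BACKGROUND_REFLECTANCE = 0.06


@dataclass(frozen=True)
class ToothPlacement:
    """Axis-aligned rectangular crown footprint: (top row, left col,
    height, width) with the cervical side at the top row."""

    tooth_id: str
    row0: int
    col0: int
    height: int
    width: int

    @property
    def rows(self) -> slice:
        return slice(self.row0, self.row0 + self.height)

    @property
    def cols(self) -> slice:
        return slice(self.col0, self.col0 + self.width)

    def overlaps(self, other: "ToothPlacement") -> bool:
        return not (
            self.row0 + self.height <= other.row0
            or other.row0 + other.height <= self.row0
            or self.col0 + self.width <= other.col0
            or other.col0 + other.width <= self.col0
        )


def _default_placements(shape: tuple[int, int]) -> tuple[ToothPlacement, ...]:
    """Four incisors left -> right: lateral, central, central, lateral.
    Centrals 60x90 px and laterals 45x80 px at 512x512, scaled with the
    frame."""
    rows, cols = shape
    sr, sc = rows / 512.0, cols / 512.0

    def scaled(tooth_id, row0, col0, h, w):
        return ToothPlacement(
            tooth_id,
            row0=int(round(row0 * sr)),
            col0=int(round(col0 * sc)),
            height=max(int(round(h * sr)), 6),
            width=max(int(round(w * sc)), 4),
        )

    return (
        scaled("ULI1", 210, 80, 80, 45),
        scaled("UCI1", 200, 155, 90, 60),
        scaled("UCI2", 200, 245, 90, 60),
        scaled("ULI2", 210, 335, 80, 45),
    )


@dataclass
class SceneParams:
    """Forward-model parameters of a synthetic capture.

    Defaults emulate the study conditions: a 512 x 512 frame with 204 bands
    spanning 400-1000 nm, a 12-bit-like sensor scale, a centred vignette of
    amplitude 0.3, a +/-10% linear spectral tilt across the range, and read
    noise of 1% of the typical gray-tile signal.
    """

    shape: tuple[int, int] = (512, 512)
    n_bands: int = 204
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    placements: tuple[ToothPlacement, ...] | None = None
    third_presets: dict[str, ToothSpectrumParams] = field(
        default_factory=lambda: dict(_THIRD_PRESETS)
    )
    vignette_amplitude: float = 0.3
    vignette_width: float | None = None  # pixels; default 0.5 * min(shape)
    spectral_tilt: float = 0.10
    dark_level: float = 1000.0
    gain: float = 40000.0
    noise_sd: float = 160.0  # counts; ~1% of the gray-tile signal at default gain
    full_scale: float = 65535.0
    tile_reflectance: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dark_level < self.full_scale:
            raise ValueError("need 0 <= dark_level < full_scale")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.placements is None:
            self.placements = _default_placements(self.shape)
        for i, a in enumerate(self.placements):
            if a.row0 < 0 or a.col0 < 0 or \
               a.row0 + a.height > self.shape[0] or a.col0 + a.width > self.shape[1]:
                raise ValueError(f"placement {a.tooth_id} exceeds the frame")
            for b in self.placements[i + 1:]:
                if a.overlaps(b):
                    raise ValueError(
                        f"tooth placements {a.tooth_id} and {b.tooth_id} overlap"
                    )

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)


@dataclass
class SyntheticSceneTruth:
    """Ground truth of a rendered scene: the noise-free reflectance cube,
    exact per-tooth masks, and noise-free per-third Lab profiles computed
    through the pipeline's own colorimetry tables."""

    reflectance: SpectralCube
    masks: dict[str, RegionMask]
    profiles: dict[str, ToothColorProfile]
    illumination: np.ndarray  # rows x cols spatial gain field
    spectral_tilt: np.ndarray  # per-band illumination factor


def _third_weights(height: int) -> np.ndarray:
    """Per-row interpolation weights over the three thirds.

    Row positions are mapped to normalised depth t in [0, 1]; spectral
    parameters interpolate linearly between third anchors at t = 1/6, 1/2,
    5/6 (constant beyond), giving a smooth cervical -> incisal gradient with
    no hard boundary at the third cuts."""
    t = (np.arange(height) + 0.5) / height
    anchors = np.array([1 / 6, 1 / 2, 5 / 6])
    w = np.zeros((height, 3))
    for i, ti in enumerate(t):
        if ti <= anchors[0]:
            w[i] = (1, 0, 0)
        elif ti >= anchors[2]:
            w[i] = (0, 0, 1)
        elif ti <= anchors[1]:
            a = (ti - anchors[0]) / (anchors[1] - anchors[0])
            w[i] = (1 - a, a, 0)
        else:
            a = (ti - anchors[1]) / (anchors[2] - anchors[1])
            w[i] = (0, 1 - a, a)
    return w


def _tooth_rows_reflectance(
    presets: dict[str, ToothSpectrumParams], height: int, wavelengths: np.ndarray
) -> np.ndarray:
    """height x bands reflectance: per-row linear blend of the three third
    spectra."""
    spectra = np.stack(
        [tooth_reflectance(presets[name], wavelengths)
         for name in ("cervical", "middle", "incisal")]
    )  # 3 x bands
    return _third_weights(height) @ spectra


def render_scene(
    s: SceneParams,
) -> tuple[SpectralCube, SpectralCube, SpectralCube, SyntheticSceneTruth]:
    """Render a raw/dark/gray capture trio plus ground truth.

    Forward model per pixel (x, y) and band l::

        raw = dark_level + gain * g(x,y) * tilt(l) * R_scene(x,y,l) + eps
        eps ~ Normal(0, noise_sd), truncated to [0, full_scale]

    The gray capture substitutes the tile reflectance for ``R_scene`` under
    the identical illumination, offset and noise; the dark capture is
    offset plus noise.  With ``noise_sd = 0`` flat-field correction inverts
    the model exactly.
    """
    rng = np.random.default_rng(s.seed)
    rows, cols = s.shape
    wl = s.wavelengths
    n_bands = wl.size

    # scene reflectance + truth masks
    reflectance = np.full((rows, cols, n_bands), _BACKGROUND_REFLECTANCE)
    masks: dict[str, RegionMask] = {}
    for pl in s.placements:
        block = _tooth_rows_reflectance(s.third_presets, pl.height, wl)
        reflectance[pl.rows, pl.cols, :] = block[:, None, :]
        m = np.zeros((rows, cols), bool)
        m[pl.rows, pl.cols] = True
        masks[pl.tooth_id] = RegionMask(mask=m, label=RegionLabel.TOOTH)

    # illumination field
    if s.vignette_width is None:
        width = 0.5 * min(rows, cols)
    else:
        width = float(s.vignette_width)
    r_idx = np.arange(rows) - (rows - 1) / 2.0
    c_idx = np.arange(cols) - (cols - 1) / 2.0
    d2 = r_idx[:, None] ** 2 + c_idx[None, :] ** 2
    g = 1.0 - s.vignette_amplitude * (1.0 - np.exp(-d2 / (2.0 * width**2)))
    tilt = 1.0 + s.spectral_tilt * (
        2.0 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1.0
    )

    signal_scale = s.gain * g[:, :, None] * tilt[None, None, :]

    # Noisy captures are quantised to uint16 counts like a real sensor;
    # noise-free renders stay float64 so flat-field correction inverts the
    # forward model to floating-point accuracy.
    quantise = s.noise_sd > 0 and s.full_scale <= 65535

    def capture(scene_reflectance: np.ndarray, frame: str) -> SpectralCube:
        counts = s.dark_level + signal_scale * scene_reflectance
        if s.noise_sd > 0:
            counts = counts + rng.normal(0.0, s.noise_sd, counts.shape)
        counts = np.clip(counts, 0.0, s.full_scale)
        return SpectralCube(
            data=np.round(counts).astype(np.uint16) if quantise else counts,
            wavelengths=wl,
            kind=CubeKind.RAW_COUNTS,
            meta={"synthetic": "true", "seed": str(s.seed), "frame": frame},
        )

    raw = capture(reflectance, "raw")
    dark_counts = np.full((rows, cols, n_bands), s.dark_level)
    if s.noise_sd > 0:
        dark_counts = dark_counts + rng.normal(0.0, s.noise_sd, dark_counts.shape)
    dark_counts = np.clip(dark_counts, 0.0, s.full_scale)
    dark = SpectralCube(
        data=np.round(dark_counts).astype(np.uint16) if quantise else dark_counts,
        wavelengths=wl,
        kind=CubeKind.RAW_COUNTS,
        meta={"synthetic": "true", "frame": "dark"},
    )
    gray = capture(np.broadcast_to(s.tile_reflectance, (rows, cols, n_bands)), "gray")

    truth_cube = SpectralCube(
        data=reflectance, wavelengths=wl, kind=CubeKind.REFLECTANCE,
        meta={"synthetic": "true", "frame": "truth"},
    )
    truth = SyntheticSceneTruth(
        reflectance=truth_cube,
        masks=masks,
        profiles=_truth_profiles(truth_cube, masks),
        illumination=g,
        spectral_tilt=tilt,
    )
    return raw, dark, gray, truth


def _truth_profiles(
    truth_cube: SpectralCube, masks: dict[str, RegionMask]
) -> dict[str, ToothColorProfile]:
    """Noise-free per-third Lab profiles of the rendered scene, obtained by
    pushing the true reflectance through the identical colorimetric path."""
    from .colorimetry import VISIBLE_RANGE_NM

    visible = crop_spectral_range(truth_cube, *VISIBLE_RANGE_NM)
    table = build_table(visible.wavelengths)
    quality = PixelQuality.clean(truth_cube.shape[:2])
    lab = cube_to_lab_image(visible, table, quality)
    profiles = {}
    for tooth_id, mask in masks.items():
        thirds = split_thirds(mask)
        profiles[tooth_id] = mean_lab_per_third(lab, thirds, tooth_id=tooth_id)
    return profiles


def default_tile(wavelengths, value: float = 0.40) -> ReferenceTile:
    """Flat gray reference tile matching the scene defaults."""
    return ReferenceTile.flat(wavelengths, value=value)


# ---------------------------------------------------------------------------
# published per-third means as a worked-example fixture
# ---------------------------------------------------------------------------

# Mean (SD) CIELAB coordinates per crown third of the four maxillary
# incisors, as reported across 30 participants by an in-vivo hyperspectral
# shade study; order per third: (L*, a*, b*).
_TABLE1: dict[str, dict[str, tuple]] = {
    "ULI1": {
        "cervical": ((68.78, 8.60, 19.36), (4.58, 1.38, 2.54)),
        "middle": ((70.95, 4.79, 16.94), (4.89, 1.00, 2.89)),
        "incisal": ((67.01, 4.51, 12.53), (4.65, 1.07, 2.66)),
    },
    "UCI1": {
        "cervical": ((75.34, 6.84, 18.85), (5.30, 1.14, 2.83)),
        "middle": ((79.02, 2.82, 16.18), (5.67, 0.77, 2.61)),
        "incisal": ((73.70, 2.99, 14.35), (4.64, 1.07, 2.75)),
    },
    "UCI2": {
        "cervical": ((74.70, 7.08, 18.58), (5.30, 1.34, 2.93)),
        "middle": ((78.51, 3.08, 16.18), (5.58, 0.98, 3.04)),
        "incisal": ((73.39, 3.25, 14.42), (5.08, 1.16, 2.90)),
    },
    "ULI2": {
        "cervical": ((67.97, 8.61, 18.90), (4.90, 1.12, 2.69)),
        "middle": ((70.65, 4.71, 16.86), (5.29, 1.03, 2.63)),
        "incisal": ((66.54, 4.59, 12.68), (5.48, 1.47, 2.68)),
    },
}


def table1_fixture() -> list[ToothColorProfile]:
    """The published per-third mean (and SD) CIELAB values of the four
    upper incisors, as profiles in the order ULI1, UCI1, UCI2, ULI2.

    These printed group means are the worked-example input: feeding them
    through the analysis module reproduces every published overall,
    per-third and within-tooth color difference.
    """
    profiles = []
    for tooth_id in TOOTH_ORDER:
        entry = _TABLE1[tooth_id]
        profiles.append(
            ToothColorProfile.from_means(
                tooth_id,
                cervical=entry["cervical"][0],
                middle=entry["middle"][0],
                incisal=entry["incisal"][0],
                sds={name: entry[name][1] for name in entry},
                n_pixels=30,  # participants averaged, not pixels
            )
        )
    return profiles
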