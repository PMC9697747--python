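"""Hyperspectral dental colorimetry.

End-to-end pipeline for color analysis of anterior teeth from hyperspectral
reflectance captures: ENVI cube I/O, dark/gray flat-field calibration,
CIELAB conversion under the CIE 2-degree observer and D65, division of the
crown into cervical/middle/incisal thirds, and CIELAB / CIEDE2000 color
differences judged against the dental perceptibility and acceptability
thresholds.  A synthetic scene generator with exact ground truth stands in
for in-vivo captures.
"""

from __future__ import annotations

from . import analysis, calibration, colorimetry, envi, regions, synthetic
from .analysis import (
    ADJACENT_PAIRS,
    CONTRALATERAL_PAIRS,
    PairComparison,
    WithinToothComparison,
    build_report,
    overall_difference,
    per_third_difference,
    within_tooth_differences,
)
from .calibration import (
    PixelQuality,
    ReferenceTile,
    detect_saturation,
    flat_field_correct,
    resample_spectrum,
)
from .colorimetry import (
    VISIBLE_RANGE_NM,
    ColorDifference,
    DE2000Params,
    DeltaEFormula,
    LabColor,
    ObserverIlluminantTable,
    ThresholdSet,
    Verdict,
    XYZColor,
    build_table,
    ciede2000,
    classify,
    delta_e_ab,
    reflectance_to_xyz,
    round_half_up,
    xyz_to_lab,
)
from .envi import (
    CubeKind,
    SpectralCube,
    crop_spectral_range,
    read_envi_cube,
    write_envi_cube,
)
from .regions import (
    LabImage,
    RegionMask,
    ToothColorProfile,
    cube_to_lab_image,
    mean_lab_per_third,
    profiles_from_csv,
    profiles_to_csv,
    split_thirds,
    threshold_tooth_mask,
)
from .synthetic import (
    SceneParams,
    SyntheticSceneTruth,
    ToothSpectrumParams,
    render_scene,
    table1_fixture,
    tooth_reflectance,
)

__version__ = "0.1.0"


def extract_profile(
    reflectance: SpectralCube,
    quality: PixelQuality | None = None,
    mask: RegionMask | None = None,
    tooth_id: str = "tooth",
    min_L: float = 45.0,
    max_ab_radius: float = 40.0,
) -> ToothColorProfile:
    """Reflectance cube -> per-third mean CIELAB profile of one tooth.

    Crops to the visible integration range, converts to a per-pixel Lab
    image, segments the tooth (unless ``mask`` is given), splits it into
    cervical/middle/incisal thirds and averages each.
    """
    visible = crop_spectral_range(reflectance, *VISIBLE_RANGE_NM)
    table = build_table(visible.wavelengths)
    lab = cube_to_lab_image(visible, table, quality)
    if mask is None:
        mask = threshold_tooth_mask(lab, min_L=min_L, max_ab_radius=max_ab_radius)
    thirds = split_thirds(mask)
    return mean_lab_per_third(lab, thirds, tooth_id=tooth_id)
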