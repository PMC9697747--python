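"""Color-difference analysis between and within anterior teeth.

Comparisons mirror how shade studies of the four maxillary incisors report
results:

* **contralateral** pairs — same tooth type across the midline
  (UCI1-UCI2, ULI1-ULI2);
* **adjacent** pairs — central vs lateral on the same side
  (UCI1-ULI1, UCI2-ULI2);
* **within-tooth** — cervical vs middle, cervical vs incisal and middle vs
  incisal thirds of one tooth.

All between-teeth differences are computed on the per-third *mean* CIELAB
coordinates (difference of means, not mean of per-pixel differences), and a
pair's **overall** difference is the unweighted arithmetic mean of its three
per-third values — the operative definition that reproduces published
overall values exactly from per-third tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .colorimetry import (
    ColorDifference,
    DE2000Params,
    DeltaEFormula,
    ThresholdSet,
    Verdict,
    ciede2000,
    classify,
    delta_e_ab,
)
from .regions import THIRDS, ToothColorProfile

__all__ = [
    "PairComparison",
    "WithinToothComparison",
    "CONTRALATERAL_PAIRS",
    "ADJACENT_PAIRS",
    "per_third_difference",
    "overall_difference",
    "within_tooth_differences",
    "build_report",
]

CONTRALATERAL_PAIRS = (("UCI1", "UCI2"), ("ULI1", "ULI2"))
ADJACENT_PAIRS = (("UCI1", "ULI1"), ("UCI2", "ULI2"))

_WITHIN_PAIRS = (("cervical", "middle"), ("cervical", "incisal"), ("middle", "incisal"))


def _diff(c1, c2, formula: DeltaEFormula, params: DE2000Params) -> ColorDifference:
    if DeltaEFormula(formula) is DeltaEFormula.CIELAB:
        return delta_e_ab(c1, c2)
    return ciede2000(c1, c2, params)


@dataclass
class PairComparison:
    """Per-third and overall color difference between two teeth, with PT/AT
    verdicts.  ``overall`` is the mean of the three per-third values."""

    pair: tuple[str, str]
    formula: DeltaEFormula
    per_third: dict[str, ColorDifference]
    overall: ColorDifference
    verdicts: dict[str, Verdict]


@dataclass
class WithinToothComparison:
    """Differences between the thirds of one tooth: cervical-middle (d_CM),
    cervical-incisal (d_CI) and middle-incisal (d_MI)."""

    tooth_id: str
    formula: DeltaEFormula
    d_CM: ColorDifference
    d_CI: ColorDifference
    d_MI: ColorDifference
    verdicts: dict[str, Verdict]


def per_third_difference(
    a: ToothColorProfile,
    b: ToothColorProfile,
    formula: DeltaEFormula = DeltaEFormula.CIELAB,
    params: DE2000Params = DE2000Params(),
) -> dict[str, ColorDifference]:
    """Color difference between matching thirds of two teeth, computed on
    the per-third mean Lab coordinates."""
    return {
        name: _diff(a.third(name).mean, b.third(name).mean, formula, params)
        for name in THIRDS
    }


def overall_difference(
    a: ToothColorProfile,
    b: ToothColorProfile,
    formula: DeltaEFormula = DeltaEFormula.CIELAB,
    params: DE2000Params = DE2000Params(),
) -> ColorDifference:
    """Overall difference between two teeth: unweighted mean of the three
    per-third differences."""
    per = per_third_difference(a, b, formula, params)
    value = sum(d.value for d in per.values()) / len(per)
    return ColorDifference(value=value, formula=DeltaEFormula(formula))


def compare_pair(
    a: ToothColorProfile,
    b: ToothColorProfile,
    formula: DeltaEFormula = DeltaEFormula.CIELAB,
    params: DE2000Params = DE2000Params(),
    thresholds: ThresholdSet = ThresholdSet(),
) -> PairComparison:
    per = per_third_difference(a, b, formula, params)
    overall = ColorDifference(
        value=sum(d.value for d in per.values()) / len(per),
        formula=DeltaEFormula(formula),
    )
    verdicts = {name: classify(d, thresholds) for name, d in per.items()}
    verdicts["overall"] = classify(overall, thresholds)
    return PairComparison(
        pair=(a.tooth_id, b.tooth_id),
        formula=DeltaEFormula(formula),
        per_third=per,
        overall=overall,
        verdicts=verdicts,
    )


def within_tooth_differences(
    p: ToothColorProfile,
    formula: DeltaEFormula = DeltaEFormula.CIELAB,
    params: DE2000Params = DE2000Params(),
    thresholds: ThresholdSet = ThresholdSet(),
) -> WithinToothComparison:
    """Differences between the mean colors of the stated third pairs of one
    tooth."""
    d = {
        key: _diff(p.third(x).mean, p.third(y).mean, formula, params)
        for key, (x, y) in zip(("d_CM", "d_CI", "d_MI"), _WITHIN_PAIRS)
    }
    verdicts = {k: classify(v, thresholds) for k, v in d.items()}
    return WithinToothComparison(
        tooth_id=p.tooth_id,
        formula=DeltaEFormula(formula),
        verdicts=verdicts,
        **d,
    )


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def build_report(
    profiles: list[ToothColorProfile],
    thresholds: ThresholdSet = ThresholdSet(),
    params: DE2000Params = DE2000Params(),
) -> dict[str, pd.DataFrame]:
    """Materialise the full result structure as tidy DataFrames.

    Returns a dict with keys:

    ``profiles``
        Per-third mean/SD/pixel-count table (one row per tooth x third).
    ``pairs``
        Contralateral and adjacent comparisons for both formulas: per-third
        and overall values with verdicts.  Only the canonical incisor pairs
        whose both members are present are emitted.
    ``within``
        Third-vs-third differences of each tooth for both formulas.

    Ordering is deterministic (canonical pair order, profile input order).
    """
    ids = [p.tooth_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate tooth_id in profiles: {ids}")
    by_id = {p.tooth_id: p for p in profiles}

    prof_rows = []
    for p in profiles:
        for name in THIRDS:
            s = p.third(name)
            prof_rows.append(
                {
                    "tooth_id": p.tooth_id, "third": name,
                    "L": s.mean.L_star, "a": s.mean.a_star, "b": s.mean.b_star,
                    "sd_L": s.sd[0], "sd_a": s.sd[1], "sd_b": s.sd[2],
                    "n_pixels": s.n_pixels,
                }
            )
    profiles_df = pd.DataFrame(prof_rows)

    pair_rows = []
    for relation, pairs in (
        ("contralateral", CONTRALATERAL_PAIRS),
        ("adjacent", ADJACENT_PAIRS),
    ):
        for id_a, id_b in pairs:
            if id_a not in by_id or id_b not in by_id:
                continue
            for formula in DeltaEFormula:
                cmp_ = compare_pair(
                    by_id[id_a], by_id[id_b], formula, params, thresholds
                )
                for name in THIRDS:
                    pair_rows.append(
                        {
                            "pair": f"{id_a}-{id_b}", "relation": relation,
                            "formula": formula.value, "scope": name,
                            "delta_e": cmp_.per_third[name].value,
                            "verdict": cmp_.verdicts[name].value,
                        }
                    )
                pair_rows.append(
                    {
                        "pair": f"{id_a}-{id_b}", "relation": relation,
                        "formula": formula.value, "scope": "overall",
                        "delta_e": cmp_.overall.value,
                        "verdict": cmp_.verdicts["overall"].value,
                    }
                )
    pair_cols = ["pair", "relation", "formula", "scope", "delta_e", "verdict"]
    pairs_df = pd.DataFrame(pair_rows, columns=pair_cols)

    within_rows = []
    for p in profiles:
        for formula in DeltaEFormula:
            w = within_tooth_differences(p, formula, params, thresholds)
            for key, label in (("d_CM", "cervical-middle"),
                               ("d_CI", "cervical-incisal"),
                               ("d_MI", "middle-incisal")):
                within_rows.append(
                    {
                        "tooth_id": p.tooth_id, "formula": formula.value,
                        "thirds": label,
                        "delta_e": getattr(w, key).value,
                        "verdict": w.verdicts[key].value,
                    }
                )
    within_cols = ["tooth_id", "formula", "thirds", "delta_e", "verdict"]
    within_df = pd.DataFrame(within_rows, columns=within_cols)

    return {"profiles": profiles_df, "pairs": pairs_df, "within": within_df}
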