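"""Wet-lab quantification scores.

The German semiquantitative immunoreactivity score (IRS) used to grade
immunohistochemical staining — nuclear staining intensity (0-3) times the
extent of positively stained cells (0-4), binned into low/medium/high
expression — and relative qPCR expression by the 2^-ΔΔCt method against a
reference gene (e.g. GAPDH) and a calibrator sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

INTENSITY_SCORES = {"none": 0, "weak": 1, "moderate": 2, "strong": 3}

# Extent bins: 0-5% = 0, 5-25% = 1, 26-50% = 2, 51-75% = 3, 76-100% = 4.
# The printed ranges overlap at 5% and leave (25, 26) open; percentages are
# rounded to whole percent first and an exact 5% goes to the higher bin.
_EXTENT_EDGES = ((0, 4, 0), (5, 25, 1), (26, 50, 2), (51, 75, 3), (76, 100, 4))

IRS_BINS = ((0, 7, "low"), (8, 10, "medium"), (11, 12, "high"))


def intensity_score(category: str) -> int:
    """Map a nuclear staining intensity category to its 0-3 score."""
    try:
        return INTENSITY_SCORES[category.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown staining intensity {category!r}; "
            f"expected one of {sorted(INTENSITY_SCORES)}"
        ) from None


def extent_score(positive_fraction: float) -> int:
    """Map the percentage of positively stained cells to its 0-4 score."""
    if not 0 <= positive_fraction <= 100:
        raise ValueError(f"positive fraction {positive_fraction!r} outside [0, 100]")
    pct = int(round(positive_fraction))
    for lo, hi, score in _EXTENT_EDGES:
        if lo <= pct <= hi:
            return score
    raise AssertionError("unreachable: extent bins cover 0-100")


def irs(intensity: int, extent: int) -> tuple[int, str]:
    """Immunoreactivity score = intensity x extent, with its expression bin.

    Bins: low (0-7), medium (8-10), high (11-12).
    """
    if intensity not in range(4):
        raise ValueError(f"intensity score {intensity!r} outside 0-3")
    if extent not in range(5):
        raise ValueError(f"extent score {extent!r} outside 0-4")
    score = intensity * extent
    for lo, hi, name in IRS_BINS:
        if lo <= score <= hi:
            return score, name
    raise AssertionError("unreachable: IRS bins cover 0-12")


def score_observation(category: str, positive_fraction: float) -> tuple[int, str]:
    """Convenience: full IRS for one (intensity category, extent %) pair."""
    return irs(intensity_score(category), extent_score(positive_fraction))


@dataclass(frozen=True)
class QpcrMeasurement:
    """Paired Ct values for a sample and the calibrator."""

    ct_target: float
    ct_reference: float
    ct_target_cal: float
    ct_reference_cal: float

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference", "ct_target_cal", "ct_reference_cal"):
            v = getattr(self, name)
            if not (v > 0 and v < float("inf")):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")


def fold_change_ddct(m: QpcrMeasurement) -> float:
    """Relative expression by 2^-ΔΔCt.

    ΔCt = Ct(target) - Ct(reference) per sample; ΔΔCt = ΔCt(sample) -
    ΔCt(calibrator); fold change = 2^-ΔΔCt (1 = same as calibrator,
    2 = one-cycle-earlier detection = twice the template).
    """
    dct_sample = m.ct_target - m.ct_reference
    dct_cal = m.ct_target_cal - m.ct_reference_cal
    return float(2.0 ** -(dct_sample - dct_cal))


def score_ihc_table(table: pd.DataFrame) -> pd.DataFrame:
    """Score a TSV-shaped table of IHC observations.

    Needs columns ``intensity`` (category) and ``positive_pct``; returns the
    table with added intensity_score, extent_score, irs and bin columns.
    """
    out = table.copy()
    out["intensity_score"] = [intensity_score(c) for c in table["intensity"]]
    out["extent_score"] = [extent_score(p) for p in table["positive_pct"]]
    scored = [irs(i, e) for i, e in zip(out["intensity_score"], out["extent_score"])]
    out["irs"] = [s for s, _ in scored]
    out["bin"] = [b for _, b in scored]
    return out
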