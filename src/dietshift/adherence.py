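"""Green-MED adherence score.

A 9-item median-split index over calorie-normalized daily intakes.
Seven components are beneficial (walnuts, vegetables, legumes, fruits,
fish, green tea, Mankai): intake at or above the cohort median scores 1.
Two are penalized (red meat, processed meat): intake strictly below the
median scores 1.  The total ranges from 0 (minimal adherence) to 9
(perfect adherence).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

BENEFICIAL = (
    "walnuts",
    "vegetables",
    "legumes",
    "fruits",
    "fish",
    "green_tea",
    "mankai",
)
PENALIZED = ("red_meat", "processed_meat")
COMPONENTS = BENEFICIAL + PENALIZED
ENERGY_COL = "energy_kcal"


@dataclass
class AdherenceScore:
    scores: pd.Series  # integer 0..9 per subject
    indicators: pd.DataFrame  # subjects x 9 components, values 0/1
    medians: pd.Series  # cohort medians of normalized intake

    def __post_init__(self) -> None:
        if not self.scores.equals(self.indicators.sum(axis=1)):
            raise ValueError("score must equal the sum of component indicators")


def _check_columns(intake: pd.DataFrame) -> None:
    missing = [c for c in COMPONENTS + (ENERGY_COL,) if c not in intake.columns]
    if missing:
        raise ValueError(f"intake table missing component column(s): {missing}")


def normalize_intake(intake: pd.DataFrame) -> pd.DataFrame:
    """Divide each component's grams/day by the subject's total kcal/day."""
    _check_columns(intake)
    if (intake[ENERGY_COL] <= 0).any():
        bad = intake.index[intake[ENERGY_COL] <= 0].tolist()
        raise ValueError(f"non-positive energy intake for subject(s): {bad}")
    if (intake[list(COMPONENTS)] < 0).to_numpy().any():
        raise ValueError("negative component intake")
    return intake[list(COMPONENTS)].div(intake[ENERGY_COL], axis=0)


def greenmed_score(
    intake: pd.DataFrame, medians: pd.Series | None = None
) -> AdherenceScore:
    """Compute the 9-item Green-MED score over a cohort intake table.

    Medians are taken over the supplied cohort unless precomputed ones
    are passed in (e.g. per-arm medians).  Ties at the median follow the
    score definition literally: beneficial components count "at or
    above"; meats count strictly "below".
    """
    if medians is None and len(intake) < 2:
        raise ValueError("cohort medians need at least 2 subjects")
    norm = normalize_intake(intake)
    if medians is None:
        medians = norm.median(axis=0)

    indicators = pd.DataFrame(index=norm.index, columns=list(COMPONENTS), dtype=int)
    for comp in BENEFICIAL:
        indicators[comp] = (norm[comp] >= medians[comp]).astype(int)
    for comp in PENALIZED:
        indicators[comp] = (norm[comp] < medians[comp]).astype(int)

    return AdherenceScore(indicators.sum(axis=1), indicators, medians)
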