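"""Subsetting rules and trait derivation for the life-history analysis.

The analysis subset keeps only females that (i) lived long enough to be
offered at least six mating opportunities, (ii) mated at least once, and
(iii) died a natural death (escaped or accidentally killed females are
excluded).  From each retained record three counts are derived: early-life
mating frequency (matings accepted in opportunities 1–6), later-life mating
frequency (opportunity 7 to death), and lifetime mating frequency, their
sum.  Counts may be log(x+1)-transformed for significance testing; genetic
parameters are extracted from untransformed fits so that mean-standardized
evolvabilities remain comparable across studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import FemaleLifeHistoryRecord

__all__ = [
    "AnalysisRecord",
    "filter_analysis_subset",
    "derive_traits",
    "analysis_frame",
    "log1p_transform",
]

EARLY_OPPORTUNITIES = 6


@dataclass(frozen=True)
class AnalysisRecord:
    female_id: str
    sire_id: str
    dam_id: str
    longevity: int
    early_life_matings: int
    later_life_matings: int
    lifetime_matings: int
    start_date: int
    body_size: float


def filter_analysis_subset(
    records: Sequence[FemaleLifeHistoryRecord],
    *,
    min_opportunities: int = EARLY_OPPORTUNITIES,
    early_only: bool = False,
) -> list[FemaleLifeHistoryRecord]:
    """Apply the three inclusion rules; order preserved, input untouched.

    ``early_only=True`` tightens "mated at least once" to the first
    ``min_opportunities`` opportunities instead of anywhere in life.
    """
    out = []
    for r in records:
        if len(r.mating_outcomes) < min_opportunities:
            continue
        mated = (
            sum(r.mating_outcomes[:min_opportunities]) if early_only else sum(r.mating_outcomes)
        )
        if mated < 1:
            continue
        if r.death_cause != "natural":
            continue
        out.append(r)
    return out


def derive_traits(records: Sequence[FemaleLifeHistoryRecord]) -> list[AnalysisRecord]:
    """Split each female's mating record at opportunity 6.

    Raises ``ValueError`` if any record was offered fewer than six
    opportunities (such records must be filtered out first).
    """
    out = []
    for r in records:
        if len(r.mating_outcomes) < EARLY_OPPORTUNITIES:
            raise ValueError(
                f"record {r.female_id} has {len(r.mating_outcomes)} < "
                f"{EARLY_OPPORTUNITIES} mating opportunities; filter first"
            )
        early = int(sum(r.mating_outcomes[:EARLY_OPPORTUNITIES]))
        later = int(sum(r.mating_outcomes[EARLY_OPPORTUNITIES:]))
        out.append(
            AnalysisRecord(
                female_id=r.female_id,
                sire_id=r.sire_id,
                dam_id=r.dam_id,
                longevity=r.longevity,
                early_life_matings=early,
                later_life_matings=later,
                lifetime_matings=early + later,
                start_date=r.start_date,
                body_size=r.body_size,
            )
        )
    return out


def analysis_frame(records: Sequence[AnalysisRecord]) -> pd.DataFrame:
    """Analysis records as a DataFrame (one row per female)."""
    return pd.DataFrame([r.__dict__ for r in records])


def log1p_transform(values) -> np.ndarray:
    """Natural log(x + 1), elementwise; rejects negative input."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log1p_transform requires non-negative values")
    return np.log1p(arr)
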