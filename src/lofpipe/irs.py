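"""Immunoreactive score (IRS, Remmele-Stegner) for tissue-microarray cores.

Each core is scored by staining intensity (0 none, 1 weak, 2 moderate,
3 strong) and by the percentage of positive cells, binned into a
proportion score 0-4. The IRS is intensity x proportion score (0-12),
grouped as negative (0-1), weak (2-3), moderate (4-8) or strong (9-12).
Cases with several cores take the mean core IRS, with the group bins
extended continuously: [0,2) negative, [2,4) weak, [4,9) moderate,
[9,12] strong. Association between IRS group and histological grade
(G2 vs G3; undetermined Gx cases are excluded) is tested with the Pearson
chi-square test, without continuity correction.

The published proportion bins overlap at exactly 50% ("10-50%" and
"50-80%"); this implementation assigns 50% to the lower bin (score 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "CoreScore",
    "CaseIRS",
    "proportion_score",
    "compute_irs",
    "case_aggregate",
    "aggregate_table",
    "grade_association",
    "GROUP_NAMES",
]

GROUP_NAMES = {0: "negative", 1: "weak", 2: "moderate", 3: "strong"}
GRADES = ("G2", "G3", "Gx")


@dataclass(frozen=True)
class CoreScore:
    case_id: str
    core_id: str
    intensity: int
    percent_positive: float

    def __post_init__(self):
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError("intensity must be one of 0, 1, 2, 3")
        if not (0.0 <= self.percent_positive <= 100.0):
            raise ValueError("percent_positive must lie in [0, 100]")


@dataclass(frozen=True)
class CaseIRS:
    case_id: str
    mean_irs: float
    group: int
    grade: str


def proportion_score(percent_positive: float) -> int:
    """Bin percent-positive cells into the proportion score 0-4.

    Bins: [0,1) -> 0, [1,10) -> 1, [10,50] -> 2, (50,80] -> 3, (80,100] -> 4.
    """
    pct = float(percent_positive)
    if not (0.0 <= pct <= 100.0):
        raise ValueError("percent positive must lie in [0, 100]")
    if pct < 1:
        return 0
    if pct < 10:
        return 1
    if pct <= 50:
        return 2
    if pct <= 80:
        return 3
    return 4


def _group_from_irs(irs: float) -> int:
    """Continuous extension of the printed integer IRS groups."""
    if irs < 2:
        return 0
    if irs < 4:
        return 1
    if irs < 9:
        return 2
    return 3


def compute_irs(intensity: int, prop_score: int):
    """IRS = intensity x proportion score; returns ``(irs, group)``."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity must be one of 0, 1, 2, 3")
    if prop_score not in (0, 1, 2, 3, 4):
        raise ValueError("proportion score must be one of 0..4")
    irs = intensity * prop_score
    return irs, _group_from_irs(irs)


def case_aggregate(cores: list[CoreScore], grade: str = "Gx") -> CaseIRS:
    """Mean IRS over a case's cores, grouped by the continuous bins."""
    if not cores:
        raise ValueError("a case needs at least one core")
    case_ids = {c.case_id for c in cores}
    if len(case_ids) != 1:
        raise ValueError("cores belong to more than one case")
    if grade not in GRADES:
        raise ValueError(f"grade must be one of {GRADES}")
    values = [compute_irs(c.intensity, proportion_score(c.percent_positive))[0]
              for c in cores]
    mean_irs = float(np.mean(values))
    return CaseIRS(case_id=cores[0].case_id, mean_irs=mean_irs,
                   group=_group_from_irs(mean_irs), grade=grade)


def aggregate_table(cores: pd.DataFrame) -> pd.DataFrame:
    """Case-level aggregation of a core table.

    Expects columns case_id, core_id, intensity, percent_positive, grade
    (grade constant within a case). Returns one row per case with mean_irs,
    group, group_name and grade.
    """
    required = {"case_id", "core_id", "intensity", "percent_positive", "grade"}
    missing = required - set(cores.columns)
    if missing:
        raise ValueError(f"core table missing columns: {sorted(missing)}")
    rows = []
    for case_id, sub in cores.groupby("case_id", sort=True):
        grades = set(sub["grade"].astype(str))
        if len(grades) != 1:
            raise ValueError(f"case {case_id!r} has inconsistent grades")
        core_objs = [
            CoreScore(str(case_id), str(r.core_id), int(r.intensity),
                      float(r.percent_positive))
            for r in sub.itertuples()
        ]
        case = case_aggregate(core_objs, grade=grades.pop())
        rows.append({"case_id": case.case_id, "mean_irs": case.mean_irs,
                     "group": case.group, "group_name": GROUP_NAMES[case.group],
                     "grade": case.grade})
    return pd.DataFrame(rows)


def grade_association(cases: pd.DataFrame):
    """Chi-square association between IRS group and tumor grade.

    Gx cases are omitted; the contingency table is grades (rows) x IRS
    groups 0-3 (columns). Columns with zero margin are dropped by the
    chi-square routine (flagged). Returns ``(table, statistic, df, p)``.
    """
    kept = cases[cases["grade"].astype(str) != "Gx"]
    grades = sorted(set(kept["grade"].astype(str)))
    if len(grades) < 2 or kept.empty:
        raise ValueError("need at least two grades after excluding Gx cases")
    table = pd.DataFrame(0, index=grades, columns=sorted(GROUP_NAMES), dtype=int)
    for r in kept.itertuples():
        table.loc[str(r.grade), int(r.group)] += 1
    stat, dof, p, _ = stats.chi_square_independence(table.values)
    return table, stat, dof, p
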