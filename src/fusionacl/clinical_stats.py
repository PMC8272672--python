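"""Injury-grade data types and clinical concordance statistics.

ACL injury on MRI is graded on a four-level ordinal scale: grade 0 (no
abnormality), grade I (partial damage, < 50% of the ligament), grade II
(damage >= 50% with some continuous fibres) and grade III (complete
rupture).  When the same knees are graded by two modalities — e.g. MRI and
arthroscopy, the surgical gold standard — the agreement of the two grade
distributions is assessed with Pearson's chi-square test, and binary
diagnostic performance (grade 0 = negative, grades I-III = positive) with
sensitivity/specificity/accuracy.  Concomitant-injury positive rates
(meniscus tear, bone contusion, collateral ligament, cartilage, effusion)
are compared between acute and chronic tears with a 2x2 chi-square.

The module ships the grade table and concomitant counts of a 30-patient
(60-knee) knee-injury cohort in which every knee was graded by both MRI
and arthroscopy, as a worked example and test input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import ConfigurationError, DataIOError
from . import metrics as _metrics


class InjuryGrade(IntEnum):
    """Four-level ordinal MRI grading of ACL injury."""

    GRADE_0 = 0  # no abnormality
    GRADE_I = 1  # damage area < 50%
    GRADE_II = 2  # damage area >= 50%
    GRADE_III = 3  # complete rupture

    @property
    def is_positive(self) -> bool:
        return self != InjuryGrade.GRADE_0


GRADE_COLUMNS = ("grade0", "gradeI", "gradeII", "gradeIII")


@dataclass(frozen=True)
class GradeTable:
    """Counts per grade (0, I, II, III) for each of two modalities."""

    modalities: tuple[str, str]
    counts: tuple[tuple[int, int, int, int], tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        for row in self.counts:
            if len(row) != 4 or any(c < 0 or int(c) != c for c in row):
                raise ConfigurationError("grade counts must be nonnegative integers")
        if sum(self.counts[0]) != sum(self.counts[1]):
            raise ConfigurationError(
                "both modalities must grade the same knees (equal row sums)"
            )

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def n_knees(self) -> int:
        return int(sum(self.counts[0]))


@dataclass(frozen=True)
class ConcomitantCounts:
    """Positives and group sizes for one concomitant-injury category."""

    category: str
    acute_pos: int
    acute_n: int
    chronic_pos: int
    chronic_n: int

    def __post_init__(self) -> None:
        if self.acute_n <= 0 or self.chronic_n <= 0:
            raise ConfigurationError("group sizes must be positive")
        if not 0 <= self.acute_pos <= self.acute_n:
            raise ConfigurationError("acute positives must be within group size")
        if not 0 <= self.chronic_pos <= self.chronic_n:
            raise ConfigurationError("chronic positives must be within group size")


# Reference cohort: 30 patients / 60 knees graded by MRI and arthroscopy,
# with 43 acute and 17 chronic ACL injuries.
STUDY_GRADE_TABLE = GradeTable(
    modalities=("MRI", "arthroscopy"),
    counts=((6, 10, 10, 34), (2, 11, 13, 34)),
)

# (acute, chronic) case counts by injury grade; grades I and 0 are pooled
# as reported for this cohort.
STUDY_INJURY_TIMING = {
    "grade_III": (24, 10),
    "grade_II": (6, 4),
    "grade_I_and_0": (13, 3),
}

STUDY_CONCOMITANT_COUNTS = (
    ConcomitantCounts("meniscus_tear", 30, 43, 12, 17),
    ConcomitantCounts("medial_collateral_ligament", 20, 43, 7, 17),
    ConcomitantCounts("lateral_collateral_ligament", 13, 43, 5, 17),
    ConcomitantCounts("cartilage_injury", 15, 43, 7, 17),
    ConcomitantCounts("bone_contusion", 10, 43, 3, 17),
)


def chi_square(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a 2 x k contingency table.

    Returns (statistic, degrees of freedom, p-value); no Yates continuity
    correction unless requested.  Raises if any expected count is zero,
    naming the offending cell.
    """
    if isinstance(table, GradeTable):
        table = table.to_array()
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ConfigurationError("chi_square expects a 2 x k table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    bad = np.argwhere(expected == 0)
    if bad.size:
        r, c = bad[0]
        raise ConfigurationError(f"expected count is zero in cell (row {r}, col {c})")
    stat, p, dof, _ = chi2_contingency(obs, correction=correction)
    return float(stat), int(dof), float(p)


def diagnostic_stats(pairs) -> dict[str, float]:
    """Sensitivity/specificity/accuracy of an index modality vs a reference.

    ``pairs`` is a sequence of (index grade, reference grade); grade 0 is
    negative, grades I-III positive.  Undefined ratios (e.g. specificity
    with no reference negatives) come back as NaN.
    """
    pairs = list(pairs)
    if not pairs:
        raise ConfigurationError("diagnostic_stats needs at least one pair")
    calls = [int(InjuryGrade(int(a)).is_positive) for a, _ in pairs]
    labels = [int(InjuryGrade(int(b)).is_positive) for _, b in pairs]
    cm = _metrics.confusion(calls, labels)
    return {
        "sensitivity": _metrics.sensitivity(cm),
        "specificity": _metrics.specificity(cm),
        "accuracy": _metrics.accuracy(cm),
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
    }


def positive_rates(counts: ConcomitantCounts) -> tuple[float, float, float]:
    """Acute and chronic positive rates plus the 2x2 chi-square p-value."""
    acute_rate = counts.acute_pos / counts.acute_n
    chronic_rate = counts.chronic_pos / counts.chronic_n
    table = [
        [counts.acute_pos, counts.acute_n - counts.acute_pos],
        [counts.chronic_pos, counts.chronic_n - counts.chronic_pos],
    ]
    _, _, p = chi_square(table)
    return acute_rate, chronic_rate, p


# ---------------------------------------------------------------------------
# CSV input and report output
# ---------------------------------------------------------------------------

def read_grade_table(path) -> GradeTable:
    """CSV columns: modality, grade0, gradeI, gradeII, gradeIII (two rows)."""
    df = pd.read_csv(path)
    required = ["modality", *GRADE_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataIOError(f"grade table missing columns: {missing}")
    if len(df) != 2:
        raise DataIOError("grade table must have exactly two modality rows")
    return GradeTable(
        modalities=tuple(df["modality"].tolist()),
        counts=tuple(tuple(int(df.iloc[i][c]) for c in GRADE_COLUMNS) for i in range(2)),
    )


def read_concomitant_counts(path) -> list[ConcomitantCounts]:
    """CSV columns: category, acute_pos, acute_n, chronic_pos, chronic_n."""
    df = pd.read_csv(path)
    required = ["category", "acute_pos", "acute_n", "chronic_pos", "chronic_n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataIOError(f"concomitant counts missing columns: {missing}")
    return [
        ConcomitantCounts(r.category, int(r.acute_pos), int(r.acute_n),
                          int(r.chronic_pos), int(r.chronic_n))
        for r in df.itertuples(index=False)
    ]


def concordance_report(grade_table: GradeTable,
                       concomitant: list[ConcomitantCounts] | tuple = ()) -> dict:
    """Full JSON-serializable concordance report for one cohort."""
    stat, dof, p = chi_square(grade_table)
    report = {
        "grade_table": {
            "modalities": list(grade_table.modalities),
            "counts": [list(r) for r in grade_table.counts],
            "n_knees": grade_table.n_knees,
            "chi_square": {"statistic": stat, "df": dof, "p_value": p},
        },
        "concomitant_injuries": {},
    }
    for cc in concomitant:
        acute, chronic, p2 = positive_rates(cc)
        report["concomitant_injuries"][cc.category] = {
            "acute_rate": acute, "chronic_rate": chronic, "p_value": p2,
            "acute": [cc.acute_pos, cc.acute_n],
            "chronic": [cc.chronic_pos, cc.chronic_n],
        }
    return report


def summarize(report: dict) -> str:
    """Plain-text summary of :func:`concordance_report` output."""
    g = report["grade_table"]
    chi = g["chi_square"]
    lines = [
        f"Grade distribution ({' vs '.join(g['modalities'])}, n={g['n_knees']} knees):",
        f"  chi-square = {chi['statistic']:.4f}, df = {chi['df']}, "
        f"p = {chi['p_value']:.4f}"
        + ("  (no significant difference)" if chi["p_value"] > 0.05 else ""),
    ]
    for cat, d in report["concomitant_injuries"].items():
        lines.append(
            f"  {cat}: acute {100 * d['acute_rate']:.2f}% "
            f"vs chronic {100 * d['chronic_rate']:.2f}% (p = {d['p_value']:.4f})"
        )
    return "\n".join(lines)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
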