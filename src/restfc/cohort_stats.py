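"""Demographic and neuropsychological group comparisons.

Continuous variables are compared with the pooled-variance (Student)
two-sample t-test — computable from either raw values or published
summary statistics (mean, SD, n) — and categorical variables with the
Pearson chi-square test of independence without continuity correction.
These are the variants that reproduce the published cohort table's
p-values; Welch and Yates-corrected alternatives sit behind flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SubjectRecord

__all__ = [
    "GroupSummary",
    "pooled_t_from_summary",
    "pooled_t_from_raw",
    "chi_square_independence",
    "demographics_report",
]

CONTINUOUS_VARS = (
    ("age", "Age at imaging"),
    ("yoe", "Years of education"),
    ("pss", "Processing speed score"),
    ("psy", "Psychomotor speed score"),
    ("n_fights", "Number of fights"),
    ("years_fighting", "Years of fighting"),
    ("knockouts", "Knock-outs"),
    ("rms_motion_mm", "fMRI motion (mm)"),
)
CATEGORICAL_VARS = (("sex", "Sex"), ("race", "Race"))


@dataclass
class GroupSummary:
    """Per-variable group summaries and test results as a tidy table."""

    table: pd.DataFrame
    groups: tuple

    def flagged(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p"] < alpha]


def pooled_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics; returns (t, df, p).

    Pooled-variance Student test by default; ``welch=True`` uses the
    Welch-Satterthwaite approximation.  p is two-sided.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if welch:
        se2_1, se2_2 = s1**2 / n1, s2**2 / n2
        se = math.sqrt(se2_1 + se2_2)
        if se == 0:
            if m1 == m2:
                return 0.0, float(n1 + n2 - 2), 1.0
            raise ValueError("zero variance with unequal means: t undefined")
        df = (se2_1 + se2_2) ** 2 / (se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1))
        t = (m1 - m2) / se
    else:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        df = float(n1 + n2 - 2)
        if sp2 == 0:
            if m1 == m2:
                return 0.0, df, 1.0
            raise ValueError("zero pooled variance with unequal means: t undefined")
        t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pooled_t_from_raw(x1, x2, welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t from raw values via the summary-statistic formula."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[np.isfinite(x1)], x2[np.isfinite(x2)]
    return pooled_t_from_summary(
        x1.mean(), x1.std(ddof=1), x1.size, x2.mean(), x2.std(ddof=1), x2.size, welch=welch
    )


def chi_square_independence(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test on an r x c contingency table.

    Returns (chi2, df, p).  No continuity correction by default; warns
    when any expected count is below 5.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("need a 2-D table of nonnegative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    res = stats.chi2_contingency(table, correction=correction)
    if np.any(res.expected_freq < 5):
        warnings.warn("expected count below 5: chi-square approximation may be poor")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _split(subjects: list[SubjectRecord], grouping: str):
    if grouping == "nc_vs_fighters":
        a = [s for s in subjects if s.group == "nc"]
        b = [s for s in subjects if s.group != "nc"]
        names = ("NC", "Fighters")
    elif grouping == "non_vs_impaired":
        a = [s for s in subjects if s.group == "non_impaired"]
        b = [s for s in subjects if s.group == "impaired"]
        names = ("Non-impaired", "Impaired")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if not a or not b:
        raise ValueError(f"grouping {grouping!r} has an empty group")
    return a, b, names


def demographics_report(
    subjects: list[SubjectRecord], grouping: str = "nc_vs_fighters", alpha: float = 0.05
) -> GroupSummary:
    """Group-comparison table over demographics, scores and motion.

    Continuous rows report mean, SD and n per group with the pooled t
    p-value; categorical rows report category counts with the chi-square
    p-value.  Variables absent in a group (e.g. fighting history for
    controls) are skipped for that comparison.
    """
    a, b, names = _split(subjects, grouping)
    rows = []
    for attr, label in CONTINUOUS_VARS:
        xa = np.array([getattr(s, attr) for s in a], dtype=float)
        xb = np.array([getattr(s, attr) for s in b], dtype=float)
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        if xa.size < 2 or xb.size < 2:
            continue
        t, df, p = pooled_t_from_raw(xa, xb)
        rows.append(
            dict(variable=label, kind="continuous",
                 group1=f"{xa.mean():.2f} ± {xa.std(ddof=1):.2f}",
                 group2=f"{xb.mean():.2f} ± {xb.std(ddof=1):.2f}",
                 n1=xa.size, n2=xb.size, stat=t, df=df, p=p, significant=p < alpha)
        )
    for attr, label in CATEGORICAL_VARS:
        va = [int(getattr(s, attr)) for s in a]
        vb = [int(getattr(s, attr)) for s in b]
        cats = sorted(set(va) | set(vb))
        counts = np.array(
            [[sum(v == c for v in grp) for c in cats] for grp in (va, vb)], dtype=float
        )
        keep = counts.sum(axis=0) > 0
        counts = counts[:, keep]
        if counts.shape[1] < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi2, df, p = chi_square_independence(counts)
        rows.append(
            dict(variable=label, kind="categorical",
                 group1="/".join(str(int(c)) for c in counts[0]),
                 group2="/".join(str(int(c)) for c in counts[1]),
                 n1=len(va), n2=len(vb), stat=chi2, df=df, p=p, significant=p < alpha)
        )
    return GroupSummary(pd.DataFrame(rows), names)
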