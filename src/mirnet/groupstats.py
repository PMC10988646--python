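"""Cohort-level comparisons across Braak-stage groups.

Categorical variables (sex, ApoE, CERAD, NIA-Reagan) are compared with
the Pearson chi-square test on the group contingency table, without
continuity correction (tables here are larger than 2x2).  Numeric and
ordinal variables use the Kruskal-Wallis rank ANOVA with tie correction
and, post hoc, Dunn's z-test approximation for the pairwise contrasts
(reported raw and Bonferroni-adjusted side by side, since the adjustment
convention varies between labs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CohortTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTestResult",
    "DunnResult",
    "chi_square",
    "kruskal_wallis",
    "dunn_posthoc",
    "cohort_summary",
    "contingency",
]


@dataclass(frozen=True)
class DunnResult:
    group_i: str
    group_j: str
    z: float
    p_raw: float
    p_bonferroni: float


@dataclass(frozen=True)
class GroupTestResult:
    variable: str
    test: str  # 'chi_square' | 'kruskal_wallis'
    statistic: float
    df: int
    p_value: float
    posthoc: tuple[DunnResult, ...] | None = None


def chi_square(table, variable: str = "") -> GroupTestResult:
    """Pearson chi-square on an r x c contingency table.

    No continuity correction.  A warning is logged (but computation
    proceeds) when any expected count is below 5, as is routine with
    autopsy-cohort cell sizes.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("chi_square needs an r x c table, r, c >= 2")
    if (t < 0).any():
        raise ValidationError("chi_square: negative count")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValidationError("chi_square: all-zero row or column")
    chi2, p, df, expected = stats.chi2_contingency(t, correction=False)
    if (expected < 5).any():
        logger.warning(
            "chi_square(%s): %d expected count(s) < 5; asymptotic p is approximate",
            variable or "table",
            int((expected < 5).sum()),
        )
    return GroupTestResult(variable, "chi_square", float(chi2), int(df), float(p))


def kruskal_wallis(groups, variable: str = "") -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with the chi-square approximation."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("kruskal_wallis needs >= 2 groups of >= 2 values")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        # all observations identical: H = 0 by definition
        return GroupTestResult(variable, "kruskal_wallis", 0.0, len(groups) - 1, 1.0)
    h, p = stats.kruskal(*groups)
    return GroupTestResult(variable, "kruskal_wallis", float(h), len(groups) - 1, float(p))


def dunn_posthoc(groups, labels=None) -> tuple[DunnResult, ...]:
    """Dunn's z-test approximation for all pairwise group contrasts.

    z = (Rbar_i - Rbar_j) / SE with the tie-corrected pooled variance
    SE^2 = (N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j);
    two-sided p from the standard normal, with Bonferroni over the
    k(k-1)/2 pairs reported alongside the raw value.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("dunn_posthoc needs >= 2 groups of >= 2 values")
    if labels is None:
        labels = [str(i + 1) for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled, method="average")
    sizes = [len(g) for g in groups]
    means, start = [], 0
    for sz in sizes:
        means.append(ranks[start : start + sz].mean())
        start += sz
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                z, p = 0.0, 1.0
            else:
                z = (means[i] - means[j]) / se
                p = float(2.0 * stats.norm.sf(abs(z)))
            out.append(
                DunnResult(labels[i], labels[j], float(z), p, min(1.0, n_pairs * p))
            )
    return tuple(out)


def contingency(cohort: CohortTable, column: str) -> pd.DataFrame:
    """Group x level contingency table for a categorical cohort column."""
    tab = pd.crosstab(cohort.df["group"], cohort.df[column])
    return tab


_NUMERIC_ROWS = [
    ("age_at_death", "Age at death (years)"),
    ("education", "Education (years)"),
    ("mmse", "MMSE score"),
    ("gcs", "GCS"),
]
_CATEGORICAL_ROWS = [("sex", "Sex"), ("apoe", "ApoE status"), ("cerad", "CERAD"), ("nia_reagan", "NIA-Reagan")]
_LOAD_ROWS = [("amyloid_load_6e10", "PCC 6E10 load"), ("tangle_load_at8", "PCC AT8 load")]


def cohort_summary(cohort: CohortTable) -> pd.DataFrame:
    """Per-group cohort characteristics with the matching group test.

    Mirrors the layout of a subject-characteristics table: n (male,
    female) with chi-square on sex; min-max (median) for age, education,
    MMSE and GCS with Kruskal-Wallis; level counts with chi-square for
    ApoE/CERAD/NIA-Reagan; mean pathology loads with Kruskal-Wallis.
    Single-group cohorts get summaries without tests.
    """
    df = cohort.df
    group_order = sorted(df["group"].unique(), key=lambda g: ("I-II", "III", "IV", "V-VI").index(g))
    groups = {g: df[df["group"] == g] for g in group_order}
    testable = len(group_order) >= 2 and all(len(sub) >= 2 for sub in groups.values())
    rows = []

    def add(variable, cells, result: GroupTestResult | None):
        row = {"variable": variable}
        for g, cell in zip(group_order, cells):
            row[g] = cell
        if result is not None:
            row["test"] = result.test
            row["statistic"] = result.statistic
            row["p"] = result.p_value
        else:
            row["test"], row["statistic"], row["p"] = "", np.nan, np.nan
        rows.append(row)

    cells = [
        f"n={len(sub)} ({(sub['sex'] == 'male').sum()}, {(sub['sex'] == 'female').sum()})"
        for sub in groups.values()
    ]
    res = chi_square(contingency(cohort, "sex").to_numpy(), "sex") if testable else None
    add("n (male, female)", cells, res)

    for col, label in _NUMERIC_ROWS:
        vals = [sub[col].astype(float) for sub in groups.values()]
        cells = [f"{v.min():g}-{v.max():g} ({v.median():g})" for v in vals]
        res = kruskal_wallis(vals, col) if testable else None
        if res is not None:
            res = GroupTestResult(
                col, res.test, res.statistic, res.df, res.p_value,
                dunn_posthoc(vals, labels=group_order),
            )
        add(label, cells, res)

    for col, label in _CATEGORICAL_ROWS[1:]:
        cells = [
            "; ".join(f"{lvl} n={n}" for lvl, n in sub[col].value_counts().sort_index().items())
            for sub in groups.values()
        ]
        res = None
        if testable:
            tab = contingency(cohort, col).to_numpy()
            tab = tab[:, tab.sum(axis=0) > 0]
            if tab.shape[1] >= 2:
                res = chi_square(tab, col)
        add(label, cells, res)

    for col, label in _LOAD_ROWS:
        vals = [sub[col].dropna().astype(float) for sub in groups.values()]
        cells = [f"{v.mean():.1f} (n={len(v)})" for v in vals]
        res = kruskal_wallis(vals, col) if testable and all(len(v) >= 2 for v in vals) else None
        add(label, cells, res)

    return pd.DataFrame(rows, columns=["variable"] + group_order + ["test", "statistic", "p"])
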