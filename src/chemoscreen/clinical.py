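"""Clinicopathologic scoring and association statistics.

Immunohistochemistry expression is graded with a 0-12 H-score —
staining intensity (0-3) times stained-cell proportion quartile (0-4) —
and dichotomized at >= 8 into low/high expression groups.  Associations
between tumor characteristics and the expression group are tested with
the Pearson chi-square test (no continuity correction) on labeled
contingency tables; rows with a not-available (N/A) level can either be
dropped or kept as their own category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "classify_hscore",
    "chisq_association",
    "contingency_from_long",
    "HScore",
    "ChisqResult",
]

H_SCORE_HIGH_CUTOFF = 8


@dataclass(frozen=True)
class HScore:
    intensity: int   # 0-3
    proportion: int  # 0-4 (quartile grade of stained-cell percentage)
    score: int       # 0-12
    expression_class: str  # 'low' | 'high'


def classify_hscore(intensity: int, proportion: int) -> HScore:
    """H-score = intensity grade x proportion grade; >= 8 is 'high'."""
    if not (isinstance(intensity, (int, np.integer)) and 0 <= intensity <= 3):
        raise ValueError("staining intensity grade must be an integer in 0-3")
    if not (isinstance(proportion, (int, np.integer)) and 0 <= proportion <= 4):
        raise ValueError("stained-proportion grade must be an integer in 0-4")
    score = int(intensity) * int(proportion)
    cls = "high" if score >= H_SCORE_HIGH_CUTOFF else "low"
    return HScore(int(intensity), int(proportion), score, cls)


@dataclass
class ChisqResult:
    chi2: float
    df: int
    p_value: float
    p_rounded: float  # 3 decimals, the reporting convention
    warnings: list


def chisq_association(
    table,
    na_policy: str = "exclude",
    na_labels: tuple = ("N/A", "NA", "n/a"),
) -> ChisqResult:
    """Pearson chi-square association test on a labeled contingency table.

    ``table`` is a DataFrame of counts with characteristic levels as
    rows and expression groups as columns (a plain 2-D array works
    too).  ``na_policy='exclude'`` drops rows whose label is an N/A
    marker before testing; ``'as_category'`` keeps them as a level.
    No continuity correction.  Any zero expected count raises; expected
    counts below 5 produce a small-sample warning in ``warnings``.
    """
    if isinstance(table, pd.DataFrame):
        df_tab = table.copy()
        if na_policy == "exclude":
            keep = [str(i) not in na_labels for i in df_tab.index]
            df_tab = df_tab.loc[keep]
        elif na_policy != "as_category":
            raise ValueError("na_policy must be 'exclude' or 'as_category'")
        counts = df_tab.to_numpy(dtype=float)
    else:
        counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after the N/A policy")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if counts.sum() <= 0:
        raise ValueError("grand total must be > 0")

    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ValueError("a zero expected count makes the chi-square statistic undefined")
    warn_list = []
    if np.any(expected < 5):
        msg = f"{int(np.sum(expected < 5))} expected count(s) < 5; chi-square approximation may be poor"
        warn_list.append(msg)
        warnings.warn(msg, stacklevel=2)
    chi2, p, df, _ = chi2_contingency(counts, correction=False)
    return ChisqResult(
        chi2=float(chi2),
        df=int(df),
        p_value=float(p),
        p_rounded=float(round(p, 3)),
        warnings=warn_list,
    )


def contingency_from_long(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pivot a long table (characteristic, level, group, count) into one
    labeled contingency table per characteristic."""
    required = {"characteristic", "level", "group", "count"}
    if not required.issubset(records.columns):
        raise ValueError(f"long table needs columns {sorted(required)}")
    out = {}
    for char, grp in records.groupby("characteristic"):
        out[char] = (
            grp.pivot(index="level", columns="group", values="count").fillna(0).astype(int)
        )
    return out
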