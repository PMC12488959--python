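"""Stratified cohort descriptives and norm-set comparison.

Covers the descriptive side of a norming study — per sex x age-band score
summaries and demographic frequency tables — plus a symmetric comparison of
two norm sets: per-cell mean raw-score differences and shifts in the raw
scores that define the <=25th/20th/15th/10th percentile screening cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .bridging_analysis import ParticipantRecord, SummaryStats, summarize_scores
from .normative_tables import AGE_CATEGORIES, SEXES, NormSet, age_category
from .percentile_engine import percentile_cutoff_score

CUTOFF_PERCENTILES = (25, 20, 15, 10)

__all__ = [
    "CUTOFF_PERCENTILES",
    "NormComparison",
    "stratified_score_summary",
    "demographic_summary",
    "compare_norm_sets",
]


def stratified_score_summary(
    records: Iterable[ParticipantRecord], which: str = "revised"
) -> Dict[Tuple[str, str], SummaryStats]:
    """Per sex x age-category score summaries (+ n) over the cohort.

    ``which`` selects ``"revised"`` or ``"original"`` scores; records missing
    that score are skipped; empty cells are absent from the result.  All ages
    must be >= 60 (norming domain); violations raise with the offending ids.
    """
    if which not in ("revised", "original"):
        raise ValueError(f"which must be 'revised' or 'original': {which!r}")
    recs = list(records)
    under = [r.id for r in recs if r.age < 60]
    if under:
        raise ValueError(f"records below age 60 not allowed in cohort summary: {under}")
    cells: Dict[Tuple[str, str], List[float]] = {}
    attr = f"score_{which}"
    for r in recs:
        score = getattr(r, attr)
        if score is None:
            continue
        cells.setdefault((r.sex, age_category(r.age)), []).append(float(score))
    return {key: summarize_scores(vals) for key, vals in sorted(cells.items())}


def demographic_summary(
    records: Iterable[ParticipantRecord], strata: Sequence[str]
) -> pd.DataFrame:
    """Counts and column percentages per level of each stratifying field.

    Missing values (None/NaN/empty) are tallied in a separate ``Missing`` row
    and excluded from the percentage denominator.  Unknown fields raise.
    """
    df = pd.DataFrame([vars(r) for r in records])
    rows = []
    for field_name in strata:
        if field_name not in df.columns:
            raise ValueError(f"unknown field: {field_name!r}")
        col = df[field_name].replace("", None)
        non_missing = col.dropna()
        n_valid = len(non_missing)
        for level, count in non_missing.value_counts().sort_index().items():
            rows.append({
                "variable": field_name,
                "level": str(level),
                "count": int(count),
                "percent": round(100.0 * count / n_valid) if n_valid else None,
            })
        n_missing = len(col) - n_valid
        if n_missing:
            rows.append({
                "variable": field_name, "level": "Missing",
                "count": int(n_missing), "percent": None,
            })
    return pd.DataFrame(rows, columns=["variable", "level", "count", "percent"])


@dataclass(frozen=True)
class NormComparison:
    """Cell-wise differences between two norm sets (b minus a)."""

    label_a: str
    label_b: str
    #: (sex, age_category) -> difference of summary means, or None if either
    #: table lacks a summary
    mean_differences: Mapping[Tuple[str, str], Optional[float]]
    #: (sex, age_category) -> {P: cutoff-score difference or None}
    cutoff_differences: Mapping[Tuple[str, str], Mapping[int, Optional[int]]]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (sex, cat), md in self.mean_differences.items():
            row = {"sex": sex, "age_category": cat, "mean_difference": md}
            for p, d in self.cutoff_differences[(sex, cat)].items():
                row[f"cutoff_le_{p}_difference"] = d
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "a": self.label_a,
            "b": self.label_b,
            "cells": [
                {
                    "sex": sex,
                    "age_category": cat,
                    "mean_difference": self.mean_differences[(sex, cat)],
                    "cutoff_differences": {
                        str(p): d
                        for p, d in self.cutoff_differences[(sex, cat)].items()
                    },
                }
                for sex in SEXES
                for cat in AGE_CATEGORIES
            ],
        }


def compare_norm_sets(norms_a: NormSet, norms_b: NormSet) -> NormComparison:
    """Compare two norm sets cell by cell: b minus a.

    Per cell the summary-mean difference, and per cutoff percentile
    P in {25, 20, 15, 10} the shift in the raw score defining the <=P
    percentile.  A cutoff undefined in either set yields None for that cell/P.
    The comparison is antisymmetric: compare(a, b) == -compare(b, a).
    """
    if set(norms_a.tables) != set(norms_b.tables):
        raise ValueError("norm sets do not cover the same sex x age cells")
    mean_diffs: Dict[Tuple[str, str], Optional[float]] = {}
    cut_diffs: Dict[Tuple[str, str], Dict[int, Optional[int]]] = {}
    for key in sorted(norms_a.tables):
        ta, tb = norms_a.tables[key], norms_b.tables[key]
        if ta.summary is not None and tb.summary is not None:
            mean_diffs[key] = tb.summary.mean - ta.summary.mean
        else:
            mean_diffs[key] = None
        per_p: Dict[int, Optional[int]] = {}
        for p in CUTOFF_PERCENTILES:
            ca = percentile_cutoff_score(ta, p)
            cb = percentile_cutoff_score(tb, p)
            per_p[p] = None if (ca is None or cb is None) else cb - ca
        cut_diffs[key] = per_p
    return NormComparison(
        label_a=norms_a.label,
        label_b=norms_b.label,
        mean_differences=mean_diffs,
        cutoff_differences=cut_diffs,
    )
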