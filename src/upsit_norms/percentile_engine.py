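"""Quantile definition and percentile-table construction for discrete 0-40 test scores.

The engine implements the empirical-distribution-function-with-averaging
quantile (the "def-5" rule: an integer ``n*p`` averages two adjacent order
statistics), a mid-rank percentile oracle, and the grid-inversion algorithm
that turns a raw-score sample into an age/sex percentile lookup table with
the tie and rounding conventions used for published smell-test norms:

* the quantile grid is the integer percents ``p = 1..100``;
* a raw score hit by several grid quantiles takes the *median* of those
  percents (which may end in .5);
* a raw score falling strictly between two assigned scores takes the mean of
  the bordering values, rounded *up* to the nearest integer;
* scores below every assigned score are floored to the 1st percentile;
* scores above every assigned score are capped at 100 and rendered ">99.5".
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

SCORE_MIN = 0
SCORE_MAX = 40
#: values strictly above this render as ">99.5" in the published tables
DISPLAY_CAP_THRESHOLD = 99.5

__all__ = [
    "SCORE_MIN",
    "SCORE_MAX",
    "DISPLAY_CAP_THRESHOLD",
    "ScoreSummary",
    "PercentileTable",
    "quantile_edf_averaging",
    "midrank_percentile",
    "build_grid",
    "build_percentile_table",
    "percentile_cutoff_score",
]

# n*p is computed in floating point; a true integer n*p (p = k/100, n a few
# thousand) is off by at most ~1e-11, far inside this band.
_INT_TOL = 1e-8


def _as_sorted_array(values: Sequence[float]) -> np.ndarray:
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("empty sample")
    return x


def quantile_edf_averaging(values: Sequence[float], p: float) -> float:
    """Quantile of ``values`` at probability ``p`` under the averaging rule.

    With sorted values ``x(1..n)`` and ``np = n*p``: if ``np`` is an integer
    ``j < n`` the result is ``(x(j) + x(j+1)) / 2``; if ``np == n`` it is
    ``x(n)``; otherwise it is ``x(ceil(np))``.

    Raises ``ValueError`` on an empty sample or ``p`` outside ``(0, 1]``.
    """
    x = _as_sorted_array(values)
    if not (0.0 < p <= 1.0):
        raise ValueError(f"invalid probability: {p!r} not in (0, 1]")
    n = x.size
    npk = n * p
    j = round(npk)
    if abs(npk - j) <= _INT_TOL * max(1.0, npk) and j >= 1:
        if j < n:
            return float((x[j - 1] + x[j]) / 2.0)
        return float(x[n - 1])
    return float(x[math.ceil(npk - _INT_TOL) - 1])


def midrank_percentile(values: Sequence[float], score: float) -> float:
    """Mid-rank percentile of ``score`` within ``values``: ``100*(L + E/2)/n``.

    ``L`` counts values strictly below ``score`` and ``E`` counts ties; this
    is the continuous counterpart of the averaged-EDF quantile and serves as
    an independent oracle for table construction.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    lower = int(np.count_nonzero(x < score))
    equal = int(np.count_nonzero(x == score))
    return 100.0 * (lower + equal / 2.0) / x.size


@dataclass(frozen=True)
class ScoreSummary:
    """Descriptive summary of a raw-score sample (score units)."""

    mean: float
    sd: float
    median: float
    min: float
    max: float

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "min": self.min,
            "max": self.max,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreSummary":
        return cls(
            mean=float(d["mean"]),
            sd=float(d["sd"]),
            median=float(d["median"]),
            min=float(d["min"]),
            max=float(d["max"]),
        )


@dataclass(frozen=True)
class PercentileTable:
    """Raw score (0-40) -> percentile mapping for one sex x age-category cell.

    ``entries[s]`` is the numeric percentile of raw score ``s``; scores in
    ``capped`` render as ``">99.5"``.  Invariants (validated on
    construction): an entry for every integer score 0..40, values in
    ``[1, 100]`` and non-decreasing in the score.
    """

    sex: str
    age_category: str
    entries: Mapping[int, float]
    capped: frozenset = field(default_factory=frozenset)
    n: int = 0
    summary: Optional[ScoreSummary] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        scores = sorted(self.entries)
        if scores != list(range(SCORE_MIN, SCORE_MAX + 1)):
            raise ValueError(
                f"table {self.sex}/{self.age_category}: entries must cover "
                f"every integer score {SCORE_MIN}..{SCORE_MAX}"
            )
        prev = None
        for s in scores:
            v = self.entries[s]
            if not (1.0 <= v <= 100.0):
                raise ValueError(
                    f"table {self.sex}/{self.age_category}: entry({s})={v} "
                    "outside [1, 100]"
                )
            if prev is not None and v < prev:
                raise ValueError(
                    f"table {self.sex}/{self.age_category}: entries not "
                    f"non-decreasing at score {s} ({prev} -> {v})"
                )
            prev = v

    def value(self, score: int) -> float:
        if score not in self.entries:
            raise ValueError(f"score must be an integer in [{SCORE_MIN}, {SCORE_MAX}]: {score!r}")
        return self.entries[score]

    def is_capped(self, score: int) -> bool:
        return score in self.capped

    def display(self, score: int) -> str:
        """Rendered percentile: ">99.5" when capped, else int or one decimal."""
        if self.is_capped(score):
            return ">99.5"
        v = self.value(score)
        if float(v).is_integer():
            return str(int(v))
        return f"{v:g}"

    def cutoff_score(self, percentile: int) -> Optional[int]:
        return percentile_cutoff_score(self, percentile)

    def to_dict(self) -> dict:
        entries = {}
        for s in range(SCORE_MIN, SCORE_MAX + 1):
            if s in self.capped:
                entries[str(s)] = ">99.5"
            else:
                v = self.entries[s]
                entries[str(s)] = int(v) if float(v).is_integer() else v
        d = {
            "sex": self.sex,
            "age_category": self.age_category,
            "n": self.n,
            "entries": entries,
            "provenance": self.provenance,
        }
        if self.summary is not None:
            d["summary"] = self.summary.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PercentileTable":
        entries: dict = {}
        capped = set()
        for key, raw in d["entries"].items():
            s = int(key)
            if isinstance(raw, str):
                if raw.strip() != ">99.5":
                    raise ValueError(f"unrecognised entry value {raw!r} at score {s}")
                entries[s] = 100.0
                capped.add(s)
            else:
                v = float(raw)
                entries[s] = v
                if v > DISPLAY_CAP_THRESHOLD:
                    capped.add(s)
        return cls(
            sex=d["sex"],
            age_category=d["age_category"],
            entries=entries,
            capped=frozenset(capped),
            n=int(d.get("n", 0)),
            summary=ScoreSummary.from_dict(d["summary"]) if "summary" in d else None,
            provenance=str(d.get("provenance", "")),
        )


def _validate_integer_scores(values: Sequence[float]) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(x)) or np.any(x != np.round(x)) or np.any(
        (x < SCORE_MIN) | (x > SCORE_MAX)
    ):
        raise ValueError(f"scores must be integers in [{SCORE_MIN}, {SCORE_MAX}]")
    return x.astype(int)


def build_grid(values: Sequence[float]) -> dict:
    """Quantile grid ``{p: q_p}`` for integer percents ``p = 1..100``."""
    x = _validate_integer_scores(values)
    return {p: quantile_edf_averaging(x, p / 100.0) for p in range(1, 101)}


def build_percentile_table(
    values: Sequence[float],
    sex: str,
    age_category: str,
    provenance: str = "",
) -> PercentileTable:
    """Construct a percentile lookup table from one cell's raw-score sample.

    Inverts the 1..100 quantile grid onto the integer score axis.  A grid
    quantile is an average of two integer order statistics and is therefore
    an integer or a half-integer; only integer quantiles are assigned to a
    score (a half-integer falls between scores and feeds the
    between-percentiles rule).  See the module docstring for the full set of
    tie, interpolation, floor and cap rules.
    """
    x = _validate_integer_scores(values)
    grid = build_grid(x)

    hit: dict = {}
    for p, q in grid.items():
        s = round(q)
        if abs(q - s) <= 1e-6:  # integer quantile -> assigned to score s
            hit.setdefault(int(s), []).append(p)

    assigned = {s: float(statistics.median(ps)) for s, ps in hit.items()}
    assigned_scores = sorted(assigned)

    entries: dict = {}
    capped = set()
    lo, hi = assigned_scores[0], assigned_scores[-1]
    for s in range(SCORE_MIN, SCORE_MAX + 1):
        if s in assigned:
            v = assigned[s]
        elif s < lo:
            v = 1.0  # below every assigned score: floored to 1st percentile
        elif s > hi:
            v = 100.0
            capped.add(s)
        else:
            below = max(t for t in assigned_scores if t < s)
            above = min(t for t in assigned_scores if t > s)
            v = float(math.ceil((assigned[below] + assigned[above]) / 2.0))
        v = max(1.0, min(100.0, v))
        if v > DISPLAY_CAP_THRESHOLD:
            capped.add(s)
        entries[s] = v

    n = int(x.size)
    summary = ScoreSummary(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if n > 1 else 0.0,
        median=quantile_edf_averaging(x, 0.5),
        min=float(x.min()),
        max=float(x.max()),
    )
    return PercentileTable(
        sex=sex,
        age_category=age_category,
        entries=entries,
        capped=frozenset(capped),
        n=n,
        summary=summary,
        provenance=provenance,
    )


def percentile_cutoff_score(table: PercentileTable, percentile: int) -> Optional[int]:
    """Largest raw score whose tabulated percentile is <= ``percentile``.

    Returns ``None`` when no entry lies at or below the cutoff.  ``percentile``
    must be in ``[1, 99]``.
    """
    if not (1 <= percentile <= 99):
        raise ValueError(f"cutoff percentile must be in [1, 99]: {percentile!r}")
    eligible = [s for s, v in table.entries.items() if v <= percentile]
    return max(eligible) if eligible else None
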