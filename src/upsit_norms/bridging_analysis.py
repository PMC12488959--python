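"""Within-subject bridging-study statistics for two test versions.

Each participant takes both the original and the revised 40-item smell test;
the analysis summarises both versions and their per-subject differences,
tests the paired shift (Wilcoxon signed-rank), compares the shift across
groups and block orders (Wilcoxon rank-sum), counts improvement directions,
and quantifies agreement with Bland-Altman limits.

The signed-rank and rank-sum tests are implemented here rather than taken
from scipy because the required behaviour — exact enumeration *with
mid-ranks for ties* on small samples, a tie-corrected continuity-corrected
normal approximation otherwise, and an explicit record of which branch ran —
is not what scipy exposes.  scipy's versions serve as independent
cross-checks in the test suite on the regimes where the definitions agree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm as _normal, rankdata

from .normative_tables import NormSet, lookup_percentile, normalize_sex
from .percentile_engine import SCORE_MAX, SCORE_MIN, quantile_edf_averaging

logger = logging.getLogger(__name__)

GROUPS = ("HC", "PD")
BLOCK_ORDERS = ("original_first", "revised_first")

#: sample-size ceiling for the exact signed-rank branch.  The exact null is
#: computed by dynamic programming over the doubled mid-ranks (equivalent to
#: enumerating all 2^m sign assignments, at polynomial cost), so it stays
#: cheap far beyond the sizes where direct enumeration would be feasible;
#: far-tail accuracy matters for claims like "p < 0.0001", where the normal
#: approximation is conservative by roughly a factor of two.
EXACT_SIGNED_RANK_MAX = 300
#: pooled-size ceiling for the exact rank-sum branch (no ties only)
EXACT_RANK_SUM_MAX = 12

__all__ = [
    "GROUPS",
    "BLOCK_ORDERS",
    "ParticipantRecord",
    "SummaryStats",
    "WilcoxonResult",
    "DirectionCounts",
    "BlandAltmanStats",
    "BridgingResult",
    "summarize_scores",
    "paired_differences",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "direction_counts",
    "bland_altman",
    "run_bridging",
]


@dataclass(frozen=True)
class ParticipantRecord:
    """One bridging-study subject with paired original/revised raw scores."""

    id: str
    sex: str
    age: float
    site: str = ""
    group: str = "HC"
    block_order: str = "original_first"
    score_original: Optional[int] = None
    score_revised: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", normalize_sex(self.sex))
        for name in ("score_original", "score_revised"):
            v = getattr(self, name)
            if v is None:
                continue
            if not float(v).is_integer() or not (SCORE_MIN <= int(v) <= SCORE_MAX):
                raise ValueError(
                    f"record {self.id!r}: {name}={v!r} must be an integer "
                    f"in [{SCORE_MIN}, {SCORE_MAX}]"
                )
            object.__setattr__(self, name, int(v))

    @property
    def complete(self) -> bool:
        return self.score_original is not None and self.score_revised is not None


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample SD, and the def-5 median/quartiles of a sample."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    sd_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "n": self.n, "mean": self.mean, "sd": self.sd,
            "median": self.median, "q1": self.q1, "q3": self.q3,
            "min": self.min, "max": self.max, "sd_defined": self.sd_defined,
        }


def summarize_scores(values: Sequence[float]) -> SummaryStats:
    """Descriptive summary; quartiles use the averaging quantile rule.

    On n=1 the SD is reported as 0 with ``sd_defined=False``.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    n = int(x.size)
    return SummaryStats(
        n=n,
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if n > 1 else 0.0,
        median=quantile_edf_averaging(x, 0.5),
        q1=quantile_edf_averaging(x, 0.25),
        q3=quantile_edf_averaging(x, 0.75),
        min=float(np.min(x)),
        max=float(np.max(x)),
        sd_defined=n > 1,
    )


def paired_differences(records: Iterable[ParticipantRecord]) -> np.ndarray:
    """Per-record revised - original differences, order-stable.

    Records missing either score are excluded (count logged); zero complete
    pairs is an error.
    """
    recs = list(records)
    complete = [r for r in recs if r.complete]
    dropped = len(recs) - len(complete)
    if dropped:
        logger.info("paired_differences: excluded %d incomplete record(s)", dropped)
    if not complete:
        raise ValueError("no complete original/revised score pairs")
    return np.array(
        [r.score_revised - r.score_original for r in complete], dtype=float
    )


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    n_used: int
    n_zero: int = 0  # signed-rank only: zero differences discarded

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "p_value": self.p_value,
            "method": self.method, "n_used": self.n_used, "n_zero": self.n_zero,
        }


def _two_sided_from_counts(cdf: float, sf: float) -> float:
    # both tails include the point mass at the observed statistic
    return min(1.0, 2.0 * min(cdf, sf))


def _signed_rank_exact(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-sided p by DP over all 2^m sign assignments.

    ``ranks2`` are doubled mid-ranks (integers), ``w2`` the doubled W+.
    The distribution is kept normalized (probabilities, not subset counts)
    so the computation is stable for any m.
    """
    total = int(ranks2.sum())
    probs = np.zeros(total + 1, dtype=float)
    probs[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(probs)
        shifted[r:] = probs[: total + 1 - r]
        probs = (probs + shifted) / 2.0
    cdf = probs[: w2 + 1].sum()
    sf = probs[w2:].sum()
    return _two_sided_from_counts(cdf, sf)


def wilcoxon_signed_rank(diffs: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded (classical treatment; count reported).
    Absolute differences are mid-ranked; W+ is the rank sum of the positive
    differences.  Exact p over all sign assignments (computed by dynamic
    programming) up to ``EXACT_SIGNED_RANK_MAX`` nonzero differences,
    otherwise a normal approximation with tie-corrected variance and a 0.5
    continuity correction.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference sample")
    nz = d[d != 0]
    n_zero = int(d.size - nz.size)
    if nz.size == 0:
        raise ValueError("degenerate: all differences zero")
    if n_zero:
        logger.info("wilcoxon_signed_rank: discarded %d zero difference(s)", n_zero)

    m = int(nz.size)
    ranks = rankdata(np.abs(nz))  # mid-ranks
    w_plus = float(ranks[nz > 0].sum())

    if m <= EXACT_SIGNED_RANK_MAX:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _signed_rank_exact(ranks2, int(round(2 * w_plus)))
        return WilcoxonResult(w_plus, p, "exact", m, n_zero)

    mu = m * (m + 1) / 4.0
    # tie groups are on |d| values
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts)) / 48.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    if var <= 0:
        raise ValueError("degenerate: zero variance in signed-rank statistic")
    z = max(0.0, abs(w_plus - mu) - 0.5) / math.sqrt(var)
    p = float(2.0 * _normal.sf(z))
    return WilcoxonResult(w_plus, min(1.0, p), "normal_approx", m, n_zero)


def _rank_sum_exact(pooled_ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Exact two-sided p for the rank-sum U by DP over subsets of size n_a."""
    ranks = np.sort(pooled_ranks).astype(int)
    total = int(ranks.sum())
    # dp[k, s]: number of k-subsets with rank sum s
    dp = np.zeros((n_a + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks:
        for k in range(min(n_a, len(ranks)), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    dist = dp[n_a]
    denom = dist.sum()
    offset = n_a * (n_a + 1) // 2  # U = rank sum - offset
    u_vals = np.arange(total + 1) - offset
    cdf = dist[u_vals <= u_obs + 1e-9].sum() / denom
    sf = dist[u_vals >= u_obs - 1e-9].sum() / denom
    return _two_sided_from_counts(cdf, sf)


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Statistic is U for the first sample.  Exact p by enumeration when
    ``len(a) + len(b) <= 12`` and the pooled sample has no ties; otherwise a
    normal approximation with tie correction and 0.5 continuity correction.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = int(xa.size), int(xb.size)
    pooled = np.concatenate([xa, xb])
    ranks = rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    u = r_a - n_a * (n_a + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if n_a + n_b <= EXACT_RANK_SUM_MAX and not has_ties:
        p = _rank_sum_exact(ranks, n_a, u)
        return WilcoxonResult(u, p, "exact", n_a + n_b)

    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        raise ValueError("degenerate: zero variance in rank-sum statistic")
    z = max(0.0, abs(u - mu) - 0.5) / math.sqrt(var)
    p = float(2.0 * _normal.sf(z))
    return WilcoxonResult(u, min(1.0, p), "normal_approx", n)


@dataclass(frozen=True)
class DirectionCounts:
    """Counts of subjects scoring higher / lower / the same on the revision."""

    higher: int
    lower: int
    same: int

    @property
    def n(self) -> int:
        return self.higher + self.lower + self.same

    @property
    def percentages(self) -> Tuple[int, int, int]:
        """Percentages of n, rounded to the nearest integer."""
        if self.n == 0:
            return (0, 0, 0)
        return tuple(round(100 * c / self.n) for c in (self.higher, self.lower, self.same))

    def to_dict(self) -> dict:
        pct = self.percentages
        return {
            "higher": self.higher, "lower": self.lower, "same": self.same,
            "n": self.n,
            "pct_higher": pct[0], "pct_lower": pct[1], "pct_same": pct[2],
        }


def direction_counts(records: Iterable[ParticipantRecord]) -> DirectionCounts:
    """Direction of the revised-minus-original change over complete pairs."""
    higher = lower = same = 0
    for r in records:
        if not r.complete:
            continue
        d = r.score_revised - r.score_original
        if d > 0:
            higher += 1
        elif d < 0:
            lower += 1
        else:
            same += 1
    return DirectionCounts(higher, lower, same)


@dataclass(frozen=True)
class BlandAltmanStats:
    """Per-pair (mean, difference) points and limits of agreement."""

    pair_means: Tuple[float, ...]
    pair_diffs: Tuple[float, ...]
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float

    def to_dict(self) -> dict:
        return {
            "n": len(self.pair_means),
            "mean_difference": self.mean_difference,
            "sd_difference": self.sd_difference,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }


def bland_altman(records: Iterable[ParticipantRecord]) -> BlandAltmanStats:
    """Bland-Altman agreement of the two raw scores over complete pairs.

    Limits of agreement are mean difference +/- 1.96 sample SD.
    """
    pairs = [
        (r.score_original, r.score_revised) for r in records if r.complete
    ]
    if len(pairs) < 2:
        raise ValueError("Bland-Altman requires at least 2 complete pairs")
    o = np.array([p[0] for p in pairs], dtype=float)
    v = np.array([p[1] for p in pairs], dtype=float)
    diffs = v - o
    means = (v + o) / 2.0
    md = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanStats(
        pair_means=tuple(float(x) for x in means),
        pair_diffs=tuple(float(x) for x in diffs),
        mean_difference=md,
        sd_difference=sd,
        loa_low=md - 1.96 * sd,
        loa_high=md + 1.96 * sd,
    )


@dataclass(frozen=True)
class BridgingResult:
    """Full bridging-study output on the raw (and optionally percentile) scale."""

    group_summaries: Dict[str, Dict[str, SummaryStats]]
    signed_rank: Dict[str, WilcoxonResult]
    between_group_rank_sum: Optional[WilcoxonResult]
    block_order_rank_sum: Optional[WilcoxonResult]
    directions: DirectionCounts
    bland_altman: BlandAltmanStats
    percentile_summaries: Optional[Dict[str, Dict[str, SummaryStats]]] = None
    percentile_signed_rank: Optional[Dict[str, WilcoxonResult]] = None
    percentile_between_group_rank_sum: Optional[WilcoxonResult] = None
    n_incomplete: int = 0

    def to_dict(self) -> dict:
        def summaries_dict(block):
            return {
                g: {k: s.to_dict() for k, s in d.items()} for g, d in block.items()
            }

        out = {
            "raw": {
                "summaries": summaries_dict(self.group_summaries),
                "signed_rank": {g: r.to_dict() for g, r in self.signed_rank.items()},
                "between_group_rank_sum": (
                    self.between_group_rank_sum.to_dict()
                    if self.between_group_rank_sum else None
                ),
                "block_order_rank_sum": (
                    self.block_order_rank_sum.to_dict()
                    if self.block_order_rank_sum else None
                ),
                "directions": self.directions.to_dict(),
                "bland_altman": self.bland_altman.to_dict(),
            },
            "n_incomplete": self.n_incomplete,
        }
        if self.percentile_summaries is not None:
            out["percentile"] = {
                "summaries": summaries_dict(self.percentile_summaries),
                "signed_rank": {
                    g: r.to_dict() for g, r in (self.percentile_signed_rank or {}).items()
                },
                "between_group_rank_sum": (
                    self.percentile_between_group_rank_sum.to_dict()
                    if self.percentile_between_group_rank_sum else None
                ),
            }
        return out


def _version_summaries(
    complete: List[ParticipantRecord],
    original: Dict[str, float],
    revised: Dict[str, float],
) -> Dict[str, Dict[str, SummaryStats]]:
    out: Dict[str, Dict[str, SummaryStats]] = {}
    for g in GROUPS:
        ids = [r.id for r in complete if r.group == g]
        if not ids:
            continue
        o = [original[i] for i in ids]
        v = [revised[i] for i in ids]
        d = [vi - oi for oi, vi in zip(o, v)]
        out[g] = {
            "original": summarize_scores(o),
            "revised": summarize_scores(v),
            "difference": summarize_scores(d),
        }
    return out


def run_bridging(
    records: Iterable[ParticipantRecord],
    norms_original: Optional[NormSet] = None,
    norms_revised: Optional[NormSet] = None,
) -> BridgingResult:
    """Run the complete bridging analysis over participant records.

    Raw-scale statistics are always produced.  Percentile-scale statistics
    require *both* norm sets (each version converted against its own norms);
    when either is absent the percentile block is skipped with a warning.
    Records aged below the norms' 60+ domain are likewise excluded from the
    percentile block only.
    """
    recs = list(records)
    complete = [r for r in recs if r.complete]
    n_incomplete = len(recs) - len(complete)
    if n_incomplete:
        logger.warning("run_bridging: %d record(s) missing a score; excluded", n_incomplete)
    if not complete:
        raise ValueError("no complete original/revised score pairs")

    raw_o = {r.id: float(r.score_original) for r in complete}
    raw_v = {r.id: float(r.score_revised) for r in complete}
    group_summaries = _version_summaries(complete, raw_o, raw_v)

    signed_rank: Dict[str, WilcoxonResult] = {}
    group_diffs: Dict[str, np.ndarray] = {}
    for g in GROUPS:
        g_recs = [r for r in complete if r.group == g]
        if not g_recs:
            continue
        diffs = paired_differences(g_recs)
        group_diffs[g] = diffs
        if np.any(diffs != 0):
            signed_rank[g] = wilcoxon_signed_rank(diffs)

    between = None
    if "HC" in group_diffs and "PD" in group_diffs:
        between = wilcoxon_rank_sum(group_diffs["HC"], group_diffs["PD"])

    by_order = {
        order: paired_differences([r for r in complete if r.block_order == order])
        for order in BLOCK_ORDERS
        if any(r.block_order == order for r in complete)
    }
    block = None
    if len(by_order) == 2:
        block = wilcoxon_rank_sum(
            by_order["original_first"], by_order["revised_first"]
        )

    result_kwargs = dict(
        group_summaries=group_summaries,
        signed_rank=signed_rank,
        between_group_rank_sum=between,
        block_order_rank_sum=block,
        directions=direction_counts(complete),
        bland_altman=bland_altman(complete),
        n_incomplete=n_incomplete,
    )

    if norms_original is None or norms_revised is None:
        logger.warning(
            "run_bridging: percentile-scale outputs skipped (norm set for "
            "%s not supplied)",
            "original" if norms_original is None else "revised",
        )
        return BridgingResult(**result_kwargs)

    eligible = [r for r in complete if r.age >= 60]
    skipped = len(complete) - len(eligible)
    if skipped:
        logger.warning(
            "run_bridging: %d record(s) below age 60 excluded from the "
            "percentile scale", skipped,
        )
    pct_o = {
        r.id: lookup_percentile(norms_original, r.sex, r.age, r.score_original).value
        for r in eligible
    }
    pct_v = {
        r.id: lookup_percentile(norms_revised, r.sex, r.age, r.score_revised).value
        for r in eligible
    }
    pct_summaries = _version_summaries(eligible, pct_o, pct_v)
    pct_signed: Dict[str, WilcoxonResult] = {}
    pct_group_diffs: Dict[str, np.ndarray] = {}
    for g in GROUPS:
        ids = [r.id for r in eligible if r.group == g]
        if not ids:
            continue
        diffs = np.array([pct_v[i] - pct_o[i] for i in ids])
        pct_group_diffs[g] = diffs
        if np.any(diffs != 0):
            pct_signed[g] = wilcoxon_signed_rank(diffs)
    pct_between = None
    if "HC" in pct_group_diffs and "PD" in pct_group_diffs:
        pct_between = wilcoxon_rank_sum(pct_group_diffs["HC"], pct_group_diffs["PD"])

    return BridgingResult(
        percentile_summaries=pct_summaries,
        percentile_signed_rank=pct_signed,
        percentile_between_group_rank_sum=pct_between,
        **result_kwargs,
    )
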