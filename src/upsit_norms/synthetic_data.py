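"""Seeded generators for bridging cohorts and stratified normative cohorts.

Scores are produced by rounding and clamping normal draws to the 0-40 score
range, optionally mixed with a uniform low-scoring tail (an impaired
subpopulation).  Because the 40-point ceiling attenuates the moments of a
clamped normal, each generator first *calibrates* its latent normal mean —
deterministically, from the exact probability mass function of a rounded,
clamped normal — so that the **observed** means match the requested targets.
The targets are therefore the moments a study would report, not latent
parameters.

Defaults reproduce the published study conditions: the bridging groups
(HC n=89 with original-score mean/SD 32.7/5.4 and difference 1.7/2.6;
PD n=48 with 18.6/7.3 and 2.5/4.5) and the ten sex x age normative cells
(e.g. females 60-64: n=4266, mean 35.2, SD 5.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm as _normal

from .bridging_analysis import BLOCK_ORDERS, GROUPS, ParticipantRecord
from .normative_tables import AGE_CATEGORIES, SEXES
from .percentile_engine import SCORE_MAX, SCORE_MIN

__all__ = [
    "GroupParams",
    "BridgingSimParams",
    "CellParams",
    "CohortSimParams",
    "default_bridging_params",
    "default_cohort_params",
    "generate_bridging_cohort",
    "generate_normative_cohort",
    "rounded_clamped_normal_pmf",
    "calibrate_latent_mean",
]


def rounded_clamped_normal_pmf(
    mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    """Exact PMF over integers ``lo..hi`` of ``round(clamp(N(mean, sd), lo, hi))``.

    Clamping folds each tail onto the boundary value; rounding maps the
    interior to integer bins.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    support = np.arange(lo, hi + 1)
    if sd == 0:
        pmf = np.zeros(support.size)
        target = int(round(min(max(mean, lo), hi)))
        pmf[target - lo] = 1.0
        return pmf
    upper = support + 0.5
    lower = support - 0.5
    cdf_hi = _normal.cdf(upper, loc=mean, scale=sd)
    cdf_lo = _normal.cdf(lower, loc=mean, scale=sd)
    pmf = cdf_hi - cdf_lo
    pmf[0] += cdf_lo[0]          # lower tail clamps onto lo
    pmf[-1] += 1.0 - cdf_hi[-1]  # upper tail clamps onto hi
    return pmf


@lru_cache(maxsize=256)
def calibrate_latent_mean(
    target_mean: float,
    sd: float,
    lo: int = SCORE_MIN,
    hi: int = SCORE_MAX,
    mix_mean: Optional[float] = None,
    mix_weight: float = 0.0,
) -> float:
    """Latent normal mean whose rounded/clamped draws average ``target_mean``.

    With a mixture component of fixed mean ``mix_mean`` and weight
    ``mix_weight``, the normal component is calibrated so the *mixture* mean
    hits the target.  Falls back to the target itself when the sd is (near)
    zero or the target is unreachable within the score range.
    """
    if sd <= 1e-9:
        return target_mean
    w = mix_weight if mix_mean is not None else 0.0
    tail = (mix_mean or 0.0) * w

    support = np.arange(lo, hi + 1)

    def observed(m: float) -> float:
        pmf = rounded_clamped_normal_pmf(m, sd, lo, hi)
        return (1.0 - w) * float(pmf @ support) + tail

    a, b = target_mean - 6 * sd, target_mean + 6 * sd + 2
    fa, fb = observed(a) - target_mean, observed(b) - target_mean
    if fa * fb > 0:  # target outside the attainable range
        return target_mean
    return float(brentq(lambda m: observed(m) - target_mean, a, b, xtol=1e-6))


@dataclass(frozen=True)
class GroupParams:
    """Bridging-generator settings for one study group."""

    n: int
    mean_original: float
    sd_original: float
    mean_diff: float
    sd_diff: float
    age_mean: float
    age_sd: float
    female_fraction: float
    original_first_fraction: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        if min(self.sd_original, self.sd_diff, self.age_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        for name in ("female_fraction", "original_first_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class BridgingSimParams:
    """Two-group bridging-cohort generator settings with a required seed."""

    groups: Mapping[str, GroupParams]
    seed: int

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")


def default_bridging_params(seed: int) -> BridgingSimParams:
    """The published bridging-study conditions (group sizes, score and
    difference moments, age distributions, sex mix, block-order split)."""
    return BridgingSimParams(
        groups={
            "HC": GroupParams(
                n=89, mean_original=32.7, sd_original=5.4,
                mean_diff=1.7, sd_diff=2.6,
                age_mean=67.2, age_sd=5.0,
                female_fraction=53 / 89, original_first_fraction=84 / 89,
            ),
            "PD": GroupParams(
                n=48, mean_original=18.6, sd_original=7.3,
                mean_diff=2.5, sd_diff=4.5,
                age_mean=67.9, age_sd=8.1,
                female_fraction=22 / 48, original_first_fraction=0.5,
            ),
        },
        seed=seed,
    )


def generate_bridging_cohort(params: BridgingSimParams) -> List[ParticipantRecord]:
    """Simulate paired original/revised scores for the bridging design.

    Per subject: original = round(clamp(Normal, 0, 40)); a latent difference
    = round(clamp(Normal, -40, 40)); revised = clamp(original + difference,
    0, 40).  Latent means are calibrated so the observed group means of the
    original score and of the revised-minus-original difference equal the
    requested targets despite the ceiling.  Ages are clamped to [60, 89] so
    that lookups against 60+ norms are always defined.  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(params.seed)
    records: List[ParticipantRecord] = []
    for group in GROUPS:
        if group not in params.groups:
            continue
        g = params.groups[group]
        if g.n == 0:
            continue
        m_orig = calibrate_latent_mean(g.mean_original, g.sd_original)
        m_diff = _calibrate_bridging_diff_mean(m_orig, g)

        original = np.clip(
            np.round(np.clip(rng.normal(m_orig, g.sd_original, g.n), SCORE_MIN, SCORE_MAX)),
            SCORE_MIN, SCORE_MAX,
        ).astype(int)
        latent_diff = np.round(
            np.clip(rng.normal(m_diff, g.sd_diff, g.n), -SCORE_MAX, SCORE_MAX)
        ).astype(int)
        revised = np.clip(original + latent_diff, SCORE_MIN, SCORE_MAX).astype(int)
        ages = np.clip(rng.normal(g.age_mean, g.age_sd, g.n), 60.0, 89.0)
        female = rng.random(g.n) < g.female_fraction
        orig_first = rng.random(g.n) < g.original_first_fraction
        for i in range(g.n):
            records.append(
                ParticipantRecord(
                    id=f"{group}-{i + 1:04d}",
                    sex="female" if female[i] else "male",
                    age=float(round(ages[i], 1)),
                    site="synthetic",
                    group=group,
                    block_order=BLOCK_ORDERS[0] if orig_first[i] else BLOCK_ORDERS[1],
                    score_original=int(original[i]),
                    score_revised=int(revised[i]),
                )
            )
    return records


@lru_cache(maxsize=256)
def _calibrate_bridging_diff_mean(latent_orig_mean: float, g: GroupParams) -> float:
    """Latent difference mean giving the target observed mean difference.

    The observed difference ``clamp(o + d, 0, 40) - o`` couples the original
    and difference draws; its expectation is computed exactly over the two
    independent discrete PMFs and inverted with a root-find.
    """
    if g.sd_diff <= 1e-9:
        return g.mean_diff
    pmf_o = rounded_clamped_normal_pmf(latent_orig_mean, g.sd_original, SCORE_MIN, SCORE_MAX)
    o_vals = np.arange(SCORE_MIN, SCORE_MAX + 1)
    d_vals = np.arange(-SCORE_MAX, SCORE_MAX + 1)

    def observed(m_d: float) -> float:
        pmf_d = rounded_clamped_normal_pmf(m_d, g.sd_diff, -SCORE_MAX, SCORE_MAX)
        summed = np.clip(o_vals[:, None] + d_vals[None, :], SCORE_MIN, SCORE_MAX)
        obs_diff = summed - o_vals[:, None]
        return float(pmf_o @ obs_diff @ pmf_d)

    a = g.mean_diff - 6 * g.sd_diff
    b = g.mean_diff + 6 * g.sd_diff + 2
    if (observed(a) - g.mean_diff) * (observed(b) - g.mean_diff) > 0:
        return g.mean_diff
    return float(brentq(lambda m: observed(m) - g.mean_diff, a, b, xtol=1e-6))


@dataclass(frozen=True)
class CellParams:
    """Normative-cohort generator settings for one sex x age cell."""

    n: int
    mean: float
    sd: float
    low_tail_fraction: float = 0.05
    low_tail_range: Tuple[int, int] = (2, 25)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cell size must be >= 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (0.0 <= self.low_tail_fraction <= 1.0):
            raise ValueError("low_tail_fraction must be in [0, 1]")
        lo, hi = self.low_tail_range
        if not (SCORE_MIN <= lo <= hi <= SCORE_MAX):
            raise ValueError("low_tail_range must be within the score range")


@dataclass(frozen=True)
class CohortSimParams:
    """Per-cell normative-cohort generator settings with a required seed."""

    cells: Mapping[Tuple[str, str], CellParams]
    seed: int

    def __post_init__(self) -> None:
        valid = {(sex, cat) for sex in SEXES for cat in AGE_CATEGORIES}
        unknown = set(self.cells) - valid
        if unknown:
            raise ValueError(f"unknown sex x age cells: {sorted(unknown)}")


#: per-cell (n, mean, sd) of the published normative cohort summary rows
_DEFAULT_CELLS = {
    ("female", "60-64"): (4266, 35.2, 5.0),
    ("female", "65-69"): (3673, 34.3, 5.5),
    ("female", "70-74"): (2299, 33.5, 6.1),
    ("female", "75-79"): (1072, 32.1, 6.7),
    ("female", "80+"): (444, 30.5, 7.3),
    ("male", "60-64"): (1363, 33.3, 6.5),
    ("male", "65-69"): (1517, 32.2, 6.9),
    ("male", "70-74"): (1265, 30.9, 7.4),
    ("male", "75-79"): (718, 29.6, 7.8),
    ("male", "80+"): (355, 27.1, 8.4),
}

#: age bounds per category used when drawing ages uniformly within a cell
_AGE_BOUNDS = {
    "60-64": (60.0, 65.0),
    "65-69": (65.0, 70.0),
    "70-74": (70.0, 75.0),
    "75-79": (75.0, 80.0),
    "80+": (80.0, 95.0),
}


def default_cohort_params(seed: int, scale: float = 1.0) -> CohortSimParams:
    """The published normative-cohort cell conditions (Ns, means, SDs).

    ``scale`` < 1 shrinks every cell size proportionally (minimum 10) for
    quick runs; moments are unchanged.
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    cells = {
        key: CellParams(n=max(10, int(round(n * scale))), mean=mean, sd=sd)
        for key, (n, mean, sd) in _DEFAULT_CELLS.items()
    }
    return CohortSimParams(cells=cells, seed=seed)


def generate_normative_cohort(params: CohortSimParams) -> List[ParticipantRecord]:
    """Simulate a stratified normative cohort (revised-test scores only).

    Per cell, each subject scores either from a rounded clamped normal
    (probability 1 - low_tail_fraction) or uniformly from the integer
    low-tail range (an impaired subpopulation).  The normal component's
    latent mean is calibrated so the cell's observed mean matches the target
    despite the ceiling and the tail.  Ages are uniform within the cell's age
    band.  Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    records: List[ParticipantRecord] = []
    for (sex, cat) in sorted(params.cells):
        cell = params.cells[(sex, cat)]
        if cell.n == 0:
            continue
        lo_t, hi_t = cell.low_tail_range
        mix_mean = (lo_t + hi_t) / 2.0 if cell.low_tail_fraction > 0 else None
        latent = calibrate_latent_mean(
            cell.mean, cell.sd,
            mix_mean=mix_mean, mix_weight=cell.low_tail_fraction,
        )
        normal_scores = np.clip(
            np.round(np.clip(rng.normal(latent, cell.sd, cell.n), SCORE_MIN, SCORE_MAX)),
            SCORE_MIN, SCORE_MAX,
        ).astype(int)
        in_tail = rng.random(cell.n) < cell.low_tail_fraction
        tail_scores = rng.integers(lo_t, hi_t + 1, size=cell.n)
        scores = np.where(in_tail, tail_scores, normal_scores)
        a_lo, a_hi = _AGE_BOUNDS[cat]
        # one decimal, clipped to stay inside the half-open bin
        ages = np.clip(np.round(rng.uniform(a_lo, a_hi, cell.n), 1), a_lo, a_hi - 0.1)
        for i in range(cell.n):
            records.append(
                ParticipantRecord(
                    id=f"{sex[0].upper()}{cat}-{i + 1:05d}",
                    sex=sex,
                    age=float(ages[i]),
                    site="synthetic",
                    group="HC",
                    block_order="original_first",
                    score_original=None,
                    score_revised=int(scores[i]),
                )
            )
    return records
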