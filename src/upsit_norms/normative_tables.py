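"""Published revised-UPSIT norms, lookup, age binning and threshold categories.

The package ships the 2020-revision (UPSIT-R) age- and sex-specific
percentile tables derived from the PPMI Online + ST Direct cohorts
(N = 16,972 aged 60+) as the builtin norm set ``"upsit_r_2020"``.  Norms for
the original 1984 test are not shipped (they were published elsewhere) but
any user-supplied norm set in the same JSON schema is accepted, which keeps
percentile conversion for the original test possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple, Union

from .percentile_engine import (
    SCORE_MAX,
    SCORE_MIN,
    PercentileTable,
)

#: five-year age bands of the norm tables; half-open, last band open-ended
AGE_CATEGORIES = ("60-64", "65-69", "70-74", "75-79", "80+")
SEXES = ("female", "male")

#: raw-score thresholds of the legacy categorical classification
NORMOSMIA_MIN = {"male": 34, "female": 35}
TOTAL_ANOSMIA_MAX = 18

BUILTIN_NORMS = ("upsit_r_2020",)

__all__ = [
    "AGE_CATEGORIES",
    "SEXES",
    "BUILTIN_NORMS",
    "OlfactionCategory",
    "NormSet",
    "PercentileLookup",
    "age_category",
    "normalize_sex",
    "classify_threshold",
    "lookup_percentile",
    "load_norms",
    "save_norms",
]


class OlfactionCategory(str, Enum):
    """Legacy raw-score classification of olfactory function."""

    NORMOSMIA = "normosmia"
    HYPOSMIA = "hyposmia"
    TOTAL_ANOSMIA = "total_anosmia"


def normalize_sex(sex: str) -> str:
    """Map {female, male, F, M} (case-insensitive) onto {'female', 'male'}."""
    s = str(sex).strip().lower()
    if s in ("f", "female"):
        return "female"
    if s in ("m", "male"):
        return "male"
    raise ValueError(f"unrecognised sex code: {sex!r}")


def age_category(age: float) -> str:
    """Five-year age band for ``age`` (years); norms exist for ages 60+ only.

    Bins are half-open: [60, 65), [65, 70), [70, 75), [75, 80), [80, inf).
    """
    if age < 60:
        raise ValueError(f"norms defined for ages 60+ only (got age {age})")
    if age < 65:
        return "60-64"
    if age < 70:
        return "65-69"
    if age < 75:
        return "70-74"
    if age < 80:
        return "75-79"
    return "80+"


def classify_threshold(sex: str, raw: int) -> OlfactionCategory:
    """Categorical olfaction status from the raw score alone.

    Normosmia at raw >= 34 (males) / >= 35 (females); total anosmia at
    raw <= 18 for both sexes; hyposmia in between.
    """
    if not (isinstance(raw, (int,)) or float(raw).is_integer()):
        raise ValueError(f"raw score must be an integer: {raw!r}")
    raw = int(raw)
    if not (SCORE_MIN <= raw <= SCORE_MAX):
        raise ValueError(f"raw score out of range [{SCORE_MIN}, {SCORE_MAX}]: {raw}")
    sex = normalize_sex(sex)
    if raw >= NORMOSMIA_MIN[sex]:
        return OlfactionCategory.NORMOSMIA
    if raw <= TOTAL_ANOSMIA_MAX:
        return OlfactionCategory.TOTAL_ANOSMIA
    return OlfactionCategory.HYPOSMIA


@dataclass(frozen=True)
class PercentileLookup:
    """Result of a norm lookup: numeric percentile plus display convention."""

    value: float
    capped: bool
    sex: str
    age_category: str
    raw: int

    @property
    def display(self) -> str:
        if self.capped:
            return ">99.5"
        return str(int(self.value)) if float(self.value).is_integer() else f"{self.value:g}"


@dataclass(frozen=True)
class NormSet:
    """A complete set of norms: one PercentileTable per sex x age cell."""

    label: str
    tables: Mapping[Tuple[str, str], PercentileTable]
    provenance: str = ""

    def __post_init__(self) -> None:
        expected = {(sex, cat) for sex in SEXES for cat in AGE_CATEGORIES}
        got = set(self.tables)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(
                f"norm set {self.label!r}: expected exactly one table per "
                f"sex x age cell; missing {missing}, unexpected {extra}"
            )

    def table(self, sex: str, age_cat: str) -> PercentileTable:
        return self.tables[(normalize_sex(sex), age_cat)]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "provenance": self.provenance,
            "tables": [
                self.tables[(sex, cat)].to_dict()
                for sex in SEXES
                for cat in AGE_CATEGORIES
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormSet":
        if "tables" not in d:
            raise ValueError("norm-set JSON must contain a 'tables' list")
        tables: Dict[Tuple[str, str], PercentileTable] = {}
        for td in d["tables"]:
            t = PercentileTable.from_dict(td)
            key = (normalize_sex(t.sex), t.age_category)
            if key in tables:
                raise ValueError(f"duplicate table for cell {key}")
            tables[key] = t
        return cls(
            label=str(d.get("label", "")),
            tables=tables,
            provenance=str(d.get("provenance", "")),
        )


def lookup_percentile(
    norms: NormSet, sex: str, age: float, raw: int
) -> PercentileLookup:
    """Percentile of a raw score against ``norms`` for a given sex and age."""
    if not float(raw).is_integer() or not (SCORE_MIN <= int(raw) <= SCORE_MAX):
        raise ValueError(f"raw score must be an integer in [{SCORE_MIN}, {SCORE_MAX}]: {raw!r}")
    raw = int(raw)
    sex = normalize_sex(sex)
    cat = age_category(age)
    table = norms.tables[(sex, cat)]
    return PercentileLookup(
        value=table.value(raw),
        capped=table.is_capped(raw),
        sex=sex,
        age_category=cat,
        raw=raw,
    )


def load_norms(source: Union[str, Path]) -> NormSet:
    """Load a norm set from a builtin id (e.g. ``"upsit_r_2020"``) or a JSON path."""
    if isinstance(source, str) and source in BUILTIN_NORMS:
        text = (
            resources.files("upsit_norms.data")
            .joinpath(f"{source}.json")
            .read_text(encoding="utf-8")
        )
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(
                f"norm set {source!r} is neither a builtin id {BUILTIN_NORMS} "
                "nor an existing file"
            )
        text = path.read_text(encoding="utf-8")
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"norm-set file {source!r} is not valid JSON: {exc}") from exc
    return NormSet.from_dict(payload)


def save_norms(norms: NormSet, path: Union[str, Path]) -> None:
    """Serialize a NormSet to JSON (bit-exact round-trip with load_norms)."""
    Path(path).write_text(
        json.dumps(norms.to_dict(), indent=1, sort_keys=False) + "\n",
        encoding="utf-8",
    )
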