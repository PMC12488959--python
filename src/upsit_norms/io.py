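"""CSV readers/writers for participant records, with row-level validation.

Dialect: comma-separated, UTF-8, header required, empty field = missing,
decimal point only.  Sex codes {female, male, F, M} (any case) are
normalized on read.  Every validation error names the offending row and
field.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

from .bridging_analysis import BLOCK_ORDERS, ParticipantRecord
from .normative_tables import normalize_sex
from .percentile_engine import SCORE_MAX, SCORE_MIN

CSV_COLUMNS = (
    "id", "sex", "age", "site", "group", "block_order",
    "score_original", "score_revised",
)

__all__ = ["CSV_COLUMNS", "read_participants", "write_participants"]


class ParticipantValidationError(ValueError):
    """Malformed participant CSV content; message cites row and field."""


def _parse_score(raw: str, row: int, field: str) -> Optional[int]:
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError:
        raise ParticipantValidationError(
            f"row {row}: field {field!r}: not a number: {raw!r}"
        ) from None
    if not value.is_integer() or not (SCORE_MIN <= value <= SCORE_MAX):
        raise ParticipantValidationError(
            f"row {row}: field {field!r}: score must be an integer in "
            f"[{SCORE_MIN}, {SCORE_MAX}]: {raw!r}"
        )
    return int(value)


def read_participants(path: Union[str, Path]) -> List[ParticipantRecord]:
    """Read and validate participant records from CSV."""
    path = Path(path)
    records: List[ParticipantRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise ParticipantValidationError(
                f"missing required column(s): {', '.join(missing)}"
            )
        for row_no, row in enumerate(reader, start=2):  # 1 is the header
            rid = (row.get("id") or "").strip()
            if not rid:
                raise ParticipantValidationError(f"row {row_no}: field 'id': empty")
            try:
                sex = normalize_sex(row["sex"])
            except ValueError as exc:
                raise ParticipantValidationError(
                    f"row {row_no}: field 'sex': {exc}"
                ) from None
            try:
                age = float(row["age"])
            except (TypeError, ValueError):
                raise ParticipantValidationError(
                    f"row {row_no}: field 'age': not a number: {row.get('age')!r}"
                ) from None
            block = (row.get("block_order") or "").strip() or BLOCK_ORDERS[0]
            if block not in BLOCK_ORDERS:
                raise ParticipantValidationError(
                    f"row {row_no}: field 'block_order': expected one of "
                    f"{BLOCK_ORDERS}: {block!r}"
                )
            records.append(
                ParticipantRecord(
                    id=rid,
                    sex=sex,
                    age=age,
                    site=(row.get("site") or "").strip(),
                    group=(row.get("group") or "").strip(),
                    block_order=block,
                    score_original=_parse_score(
                        (row.get("score_original") or "").strip(), row_no, "score_original"
                    ),
                    score_revised=_parse_score(
                        (row.get("score_revised") or "").strip(), row_no, "score_revised"
                    ),
                )
            )
    return records


def _format_age(age: float) -> str:
    return f"{age:.6g}"


def write_participants(
    records: Iterable[ParticipantRecord], path: Union[str, Path]
) -> None:
    """Write records to CSV; inverse of :func:`read_participants`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow([
                r.id, r.sex, _format_age(r.age), r.site, r.group, r.block_order,
                "" if r.score_original is None else r.score_original,
                "" if r.score_revised is None else r.score_revised,
            ])
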