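"""Delimited-text readers and writers for twin-pair records.

The on-disk format is one row per twin pair with header
``pair_id, zygosity_group, age, sex1, sex2, status1, status2`` and,
optionally, 18 extra 0/1 columns ``sym1_1..sym1_9, sym2_1..sym2_9`` for
per-twin DSM symptom indicators.  TSV is the default dialect; CSV is
selected by file extension or explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .synthetic_cohort import TwinPairRecord

__all__ = ["ReadResult", "read_twin_table", "write_twin_table"]

_REQUIRED = ["pair_id", "zygosity_group", "age", "sex1", "sex2", "status1", "status2"]
_SYM_COLS = [f"sym{t}_{i}" for t in (1, 2) for i in range(1, 10)]


@dataclass
class ReadResult:
    """Outcome of reading a twin table: valid records plus a row-error report."""

    records: list[TwinPairRecord]
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.errors)


def _sep_for(path: Path, dialect: Optional[str]) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    return "," if path.suffix.lower() == ".csv" else "\t"


def write_twin_table(records: Sequence[TwinPairRecord], path, dialect: Optional[str] = None) -> None:
    """Write records as delimited text; symptom columns appear only if present."""
    path = Path(path)
    with_sym = any(r.symptoms1 is not None for r in records)
    rows = []
    for r in records:
        row = {
            "pair_id": r.pair_id,
            "zygosity_group": r.zygosity_group,
            "age": repr(r.age),  # shortest round-trip representation
            "sex1": r.sex1,
            "sex2": r.sex2,
            "status1": r.status1,
            "status2": r.status2,
        }
        if with_sym:
            s1 = r.symptoms1 or (0,) * 9
            s2 = r.symptoms2 or (0,) * 9
            for i in range(9):
                row[f"sym1_{i + 1}"] = s1[i]
                row[f"sym2_{i + 1}"] = s2[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path, dialect), index=False)


def read_twin_table(path, dialect: Optional[str] = None) -> ReadResult:
    """Read and validate a twin-pair table.

    Missing required columns or an empty file raise ``ValueError``;
    individually malformed rows (bad status, bad age, unknown zygosity
    group, inconsistent sexes) are collected into ``errors`` with their
    1-based line numbers and skipped, so one bad row does not poison a
    cohort file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    has_sym = all(c in df.columns for c in _SYM_COLS)

    records: list[TwinPairRecord] = []
    errors: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            status1, status2 = int(row["status1"]), int(row["status2"])
            if status1 not in (0, 1, 2) or status2 not in (0, 1, 2):
                raise ValueError(f"status outside {{0,1,2}}: ({row['status1']}, {row['status2']})")
            group = str(row["zygosity_group"])
            sym1 = sym2 = None
            if has_sym:
                sym1 = tuple(int(row[f"sym1_{i}"]) for i in range(1, 10))
                sym2 = tuple(int(row[f"sym2_{i}"]) for i in range(1, 10))
            rec = TwinPairRecord(
                pair_id=str(row["pair_id"]),
                zygosity_group=group,
                age=float(row["age"]),
                status1=status1,
                status2=status2,
                symptoms1=sym1,
                symptoms2=sym2,
            )
            if (rec.sex1, rec.sex2) != (str(row["sex1"]), str(row["sex2"])):
                raise ValueError(
                    f"sexes ({row['sex1']}, {row['sex2']}) inconsistent with group {group}"
                )
            records.append(rec)
        except (ValueError, TypeError) as exc:
            errors.append((line, str(exc)))
    return ReadResult(records=records, errors=errors)
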