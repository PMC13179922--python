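"""Delimited-table input/output for LTRC samples.

There is no standard interchange format for left-truncated right-censored
triplets, so the package reads plain delimited text with a header row and
configurable column names: one row per subject with entry time ``U``,
observed time ``Y``, status ``Δ`` (1 = event observed, 0 = censored) and a
group label.  Validation errors are reported with 1-based data-row numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import LTRCError, LTRCSample, validate_sample

__all__ = ["LTRCTableSchema", "TableFormatError", "read_ltrc_table", "write_ltrc_table"]


class TableFormatError(LTRCError):
    """The input table does not conform to the schema."""


@dataclass(frozen=True)
class LTRCTableSchema:
    """Column names and dialect of an LTRC data table."""

    entry: str = "entry"
    time: str = "time"
    status: str = "status"
    group: str = "group"
    delimiter: str = "\t"

    def __post_init__(self) -> None:
        names = (self.entry, self.time, self.status, self.group)
        if len(set(names)) != 4:
            raise TableFormatError(f"column names must be distinct, got {names}")

    @property
    def columns(self) -> tuple[str, str, str, str]:
        return (self.entry, self.time, self.status, self.group)


def read_ltrc_table(
    path: str | Path, schema: LTRCTableSchema | None = None
) -> list[LTRCSample]:
    """Read a delimited table into one validated sample per group.

    Groups are returned in sorted label order.  Parsing or validation
    failures raise with the offending 1-based data-row numbers.
    """
    schema = schema or LTRCTableSchema()
    df = pd.read_csv(path, sep=schema.delimiter)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing columns {missing} in {path}")
    status_raw = pd.to_numeric(df[schema.status], errors="coerce")
    bad = ~status_raw.isin((0, 1))
    if bad.any():
        rows = (np.nonzero(bad.to_numpy())[0] + 1).tolist()
        raise TableFormatError(f"unparseable status (rows {rows[:10]}) in {path}")
    entry = pd.to_numeric(df[schema.entry], errors="coerce").to_numpy(float)
    time = pd.to_numeric(df[schema.time], errors="coerce").to_numpy(float)
    status = status_raw.to_numpy(int)
    samples = []
    for label in sorted(df[schema.group].astype(str).unique()):
        mask = (df[schema.group].astype(str) == label).to_numpy()
        try:
            samples.append(
                validate_sample(entry[mask], time[mask], status[mask], label)
            )
        except LTRCError as exc:
            rows = (np.nonzero(mask)[0] + 1).tolist()
            bad_rows = _offending_rows(entry[mask], time[mask], rows)
            where = f"rows {bad_rows[:10]}" if bad_rows else f"group rows {rows[:5]}..."
            raise TableFormatError(f"group {label!r} ({where}): {exc}") from exc
    return samples


def _offending_rows(entry: np.ndarray, time: np.ndarray, rows: Sequence[int]) -> list[int]:
    bad = ~np.isfinite(entry) | ~np.isfinite(time) | (entry > time)
    return [rows[i] for i in np.nonzero(bad)[0]]


def write_ltrc_table(
    samples: Sequence[LTRCSample],
    path: str | Path,
    schema: LTRCTableSchema | None = None,
) -> None:
    """Write samples back to a delimited table (round-trips with the reader)."""
    schema = schema or LTRCTableSchema()
    frames = [
        pd.DataFrame(
            {
                schema.entry: s.entry,
                schema.time: s.time,
                schema.status: s.status,
                schema.group: str(s.label),
            }
        )
        for s in samples
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=schema.delimiter, index=False
    )
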