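"""CSV dialects for plate wells and animal observations.

Both dialects are UTF-8, comma-separated, dot-decimal, with a mandatory
header. Units are carried in column names or dedicated unit columns so a
file can never silently change units. Malformed data rows are collected
with their line numbers instead of aborting the read; a missing mandatory
column or an empty file is a hard format error.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .dose_response import BackgroundDose, WellRecord
from .errors import CombindexError, FormatError
from .invivo import TumorObservation

__all__ = [
    "ReadResult",
    "read_plate_csv",
    "write_plate_csv",
    "read_animal_csv",
    "write_animal_csv",
]

PLATE_COLUMNS = [
    "experiment_id",
    "varied_agent",
    "dose",
    "dose_unit",
    "background",
    "replicate",
    "viability",
]
ANIMAL_COLUMNS = ["mouse_id", "group", "day", "diam_a_mm", "diam_b_mm", "weight_g"]
_ANIMAL_REQUIRED = ANIMAL_COLUMNS[:5]  # weight_g is optional


@dataclass
class ReadResult:
    """Parsed records plus an error report of (line number, message) for
    rows that failed to parse."""

    records: list
    errors: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _serialize_background(background) -> str:
    return ";".join(f"{b.agent}={b.dose:g} {b.unit}" for b in background)


def _parse_background(text: str) -> tuple:
    text = (text or "").strip()
    if not text:
        return ()
    parts = []
    for chunk in text.split(";"):
        agent, rest = chunk.split("=", 1)
        dose_str, unit = rest.strip().split(" ", 1)
        parts.append(BackgroundDose(agent.strip(), float(dose_str), unit.strip()))
    return tuple(sorted(parts, key=lambda b: b.agent))


def _open_reader(path) -> tuple[csv.DictReader, object]:
    fh = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        fh.close()
        raise FormatError(f"{path}: empty file (header row required)")
    return reader, fh


def _check_columns(fieldnames, required, path):
    missing = [c for c in required if c not in fieldnames]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")


def read_plate_csv(path) -> ReadResult:
    """Read plate wells; one record per well-formed data row."""
    reader, fh = _open_reader(path)
    with fh:
        _check_columns(reader.fieldnames, PLATE_COLUMNS, path)
        records, errors = [], []
        for row in reader:
            line = reader.line_num
            try:
                records.append(
                    WellRecord(
                        experiment_id=row["experiment_id"],
                        varied_agent=row["varied_agent"],
                        dose=float(row["dose"]),
                        dose_unit=row["dose_unit"],
                        replicate=int(row["replicate"]),
                        viability=float(row["viability"]),
                        background=_parse_background(row["background"]),
                    )
                )
            except (ValueError, KeyError, CombindexError) as exc:
                errors.append((line, str(exc)))
    return ReadResult(records, errors)


def write_plate_csv(records: Sequence[WellRecord], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLATE_COLUMNS)
        for w in records:
            writer.writerow(
                [
                    w.experiment_id,
                    w.varied_agent,
                    repr(w.dose),
                    w.dose_unit,
                    _serialize_background(w.background),
                    w.replicate,
                    repr(w.viability),
                ]
            )


def read_animal_csv(path) -> ReadResult:
    """Read mouse/day caliper rows; diameters are canonicalized a <= b on
    construction, and the weight column is optional."""
    reader, fh = _open_reader(path)
    with fh:
        _check_columns(reader.fieldnames, _ANIMAL_REQUIRED, path)
        has_weight = "weight_g" in reader.fieldnames
        records, errors = [], []
        for row in reader:
            line = reader.line_num
            try:
                weight = None
                if has_weight and (row["weight_g"] or "").strip():
                    weight = float(row["weight_g"])
                records.append(
                    TumorObservation(
                        mouse_id=row["mouse_id"],
                        group=row["group"],
                        day=int(row["day"]),
                        diam_short=float(row["diam_a_mm"]),
                        diam_long=float(row["diam_b_mm"]),
                        body_weight=weight,
                    )
                )
            except (ValueError, KeyError, CombindexError) as exc:
                errors.append((line, str(exc)))
    return ReadResult(records, errors)


def write_animal_csv(records: Sequence[TumorObservation], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANIMAL_COLUMNS)
        for o in records:
            writer.writerow(
                [
                    o.mouse_id,
                    o.group,
                    o.day,
                    repr(o.diam_short),
                    repr(o.diam_long),
                    "" if o.body_weight is None else repr(o.body_weight),
                ]
            )
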