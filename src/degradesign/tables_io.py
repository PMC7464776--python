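"""Reading, validating and writing the tabular inputs and outputs.

Compound property tables and DOE run tables arrive as CSV/TSV with a header
row.  Transcribed tables often carry typographic minus signs (U+2212); the
readers normalize those before parsing, and report unparseable cells rather
than silently dropping rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

import numpy as np

from ._util import parse_number
from .errors import LevelMismatchError, SchemaError, ValidationError
from .taguchi import Factor, TaguchiDesign

__all__ = [
    "CompoundRecord",
    "DoeRunRecord",
    "DEFAULT_COMPOUND_SCHEMA",
    "read_compound_table",
    "write_compound_table",
    "read_doe_table",
    "doe_to_design",
]

#: Canonical column names → default file column names.
DEFAULT_COMPOUND_SCHEMA: dict[str, str] = {
    "compound_id": "compound_id",
    "binding_free_energy": "binding_free_energy_kj_mol",
    "transition_energy": "transition_energy_ev",
    "set_tag": "set_tag",
}

_SET_TAGS = {"training", "test", "none"}


@dataclass
class CompoundRecord:
    """One molecule's effect values.

    binding_free_energy is the enzyme-binding ΔG_bind in kJ/mol (negative =
    favorable binding); transition_energy is the first-excited-state UV
    transition energy in eV.
    """

    compound_id: str
    binding_free_energy: float | None = None
    transition_energy: float | None = None
    set_tag: str = "none"

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if self.set_tag not in _SET_TAGS:
            raise ValidationError(
                f"set_tag must be one of {sorted(_SET_TAGS)}, got {self.set_tag!r}"
            )
        if self.transition_energy is not None and self.transition_energy <= 0:
            raise ValidationError(
                f"{self.compound_id}: transition_energy must be > 0, "
                f"got {self.transition_energy}"
            )


@dataclass
class DoeRunRecord:
    """One row of a DOE run table: factor settings plus the measured response."""

    run_id: int
    factor_settings: list[tuple[str, float]] = field(default_factory=list)
    response: float = float("nan")

    def __post_init__(self) -> None:
        if self.run_id <= 0:
            raise ValidationError(f"run_id must be positive, got {self.run_id}")


def _read_raw(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such table file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_compound_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[CompoundRecord]:
    """Read a compound property table into records, preserving row order.

    ``schema`` maps canonical field names (keys of DEFAULT_COMPOUND_SCHEMA)
    to the file's column names; unmapped optional fields are skipped.
    Unparseable numeric cells are collected and reported in a single
    ValidationError naming every offending (row, column).
    """
    schema = dict(DEFAULT_COMPOUND_SCHEMA if schema is None else schema)
    frame = _read_raw(path)
    id_col = schema.get("compound_id")
    if id_col is None or id_col not in frame.columns:
        raise SchemaError(f"missing compound id column {id_col!r} in {path}")
    numeric_fields = [
        f
        for f in ("binding_free_energy", "transition_energy")
        if schema.get(f) is not None
    ]
    for f in numeric_fields:
        if schema[f] not in frame.columns:
            raise SchemaError(f"missing column {schema[f]!r} (field {f!r}) in {path}")

    records: list[CompoundRecord] = []
    bad_cells: list[str] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        cid = str(row[id_col]).strip()
        if cid in seen:
            raise ValidationError(f"duplicate compound_id {cid!r} in {path}")
        seen.add(cid)
        values: dict[str, float | None] = {}
        for f in numeric_fields:
            cell = row[schema[f]]
            try:
                values[f] = parse_number(cell)
            except ValueError:
                bad_cells.append(f"row {idx + 1} column {schema[f]!r}: {cell!r}")
                values[f] = None
        tag = "none"
        tag_col = schema.get("set_tag")
        if tag_col and tag_col in frame.columns:
            raw_tag = str(row[tag_col]).strip()
            if raw_tag:
                tag = raw_tag
        records.append(CompoundRecord(compound_id=cid, set_tag=tag, **values))
    if bad_cells:
        raise ValidationError(
            f"unparseable numeric cells in {path}: " + "; ".join(bad_cells)
        )
    return records


def write_compound_table(
    records: Sequence[CompoundRecord],
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> None:
    """Write records back to CSV/TSV under the (possibly remapped) schema."""
    schema = dict(DEFAULT_COMPOUND_SCHEMA if schema is None else schema)
    rows = []
    for r in records:
        row: dict[str, object] = {schema["compound_id"]: r.compound_id}
        if schema.get("binding_free_energy"):
            row[schema["binding_free_energy"]] = r.binding_free_energy
        if schema.get("transition_energy"):
            row[schema["transition_energy"]] = r.transition_energy
        if schema.get("set_tag"):
            row[schema["set_tag"]] = r.set_tag
        rows.append(row)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_doe_table(
    path: str | Path,
    factors: Sequence[Factor],
    response_column: str,
    factor_columns: Mapping[str, str] | None = None,
    run_column: str | None = None,
) -> list[DoeRunRecord]:
    """Read a DOE run table, checking every cell against its declared levels.

    ``factor_columns`` maps factor names to file column names (defaults to
    the factor names themselves).  A cell whose value is not among the
    factor's declared levels raises LevelMismatchError citing run and factor.
    """
    frame = _read_raw(path)
    colmap = {f.name: f.name for f in factors}
    if factor_columns:
        colmap.update(factor_columns)
    for f in factors:
        if colmap[f.name] not in frame.columns:
            raise SchemaError(f"missing column {colmap[f.name]!r} for factor {f.name!r}")
    if response_column not in frame.columns:
        raise SchemaError(f"missing response column {response_column!r}")

    records: list[DoeRunRecord] = []
    seen_runs: set[int] = set()
    for idx, row in frame.iterrows():
        run_id = (
            int(parse_number(row[run_column])) if run_column else idx + 1
        )
        if run_id in seen_runs:
            raise ValidationError(f"duplicate run_id {run_id} in {path}")
        seen_runs.add(run_id)
        settings: list[tuple[str, float]] = []
        for f in factors:
            value = parse_number(row[colmap[f.name]])
            try:
                f.level_index(value)
            except ValidationError as exc:
                raise LevelMismatchError(f"run {run_id}: {exc}") from exc
            settings.append((f.name, value))
        response = parse_number(row[response_column])
        records.append(
            DoeRunRecord(run_id=run_id, factor_settings=settings, response=response)
        )
    return records


def doe_to_design(
    records: Sequence[DoeRunRecord], factors: Sequence[Factor]
) -> tuple[TaguchiDesign, np.ndarray]:
    """Convert run records to a level-index design matrix plus responses.

    The analysis operations are agnostic to whether a design was generated
    or read from a run table; this bridges the two.  The resulting design is
    validated for balance and pairwise orthogonality.
    """
    factors = list(factors)
    by_name = {f.name: f for f in factors}
    matrix = np.empty((len(records), len(factors)), dtype=int)
    responses = np.empty(len(records))
    for i, rec in enumerate(records):
        if len(rec.factor_settings) != len(factors):
            raise ValidationError(
                f"run {rec.run_id}: {len(rec.factor_settings)} factor settings "
                f"for {len(factors)} declared factors"
            )
        for name, value in rec.factor_settings:
            f = by_name[name]
            matrix[i, factors.index(f)] = f.level_index(value)
        responses[i] = rec.response
    design = TaguchiDesign(level_matrix=matrix, factors=factors)
    design.validate()
    return design, responses
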