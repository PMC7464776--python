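"""Packaged reference datasets for the chlorinated-OPFR design study.

Four CSV fixtures transcribed from the published study of TCPP/TCEP/TCIPP
degradability design:

* ``opfr_effects.csv`` — 22 OPFRs with enzyme-binding free energies
  (kJ/mol), UV first-excited-state transition energies (eV) and the
  published efficacy coefficients / comprehensive evaluation values;
* ``derivative_predictions.csv`` — pharmacophore-predicted comprehensive
  (C), biodegradation (B, −log scale) and photodegradation (P, eV) values
  for the TCPP/TCEP derivatives, with the published improvement
  intensities and ratios;
* ``derivative_properties.csv`` — flame retardancy (P–O BDE, kcal/mol),
  HOMO–LUMO gap (eV), total energy (a.u.) and minimum frequency for the 14
  evaluated derivatives, with published change rates;
* ``taguchi_runs.csv`` — the 27-run L27(3^7) external-condition experiment
  with binding free-energy responses (kJ/mol).

Loaders return package domain objects; `reference` holds the published
derived statistics (level-mean table, rankings, text-quoted energetics)
used as expected values by the verification checks.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .. import reference  # noqa: F401  (re-exported for convenience)
from .._util import parse_number
from ..tables_io import CompoundRecord, DoeRunRecord, read_compound_table, read_doe_table


def fixture_path(name: str) -> Path:
    """Absolute path of a packaged CSV fixture."""
    return Path(resources.files(__package__) / name)


def load_opfr_effects(directory: str | Path | None = None) -> list[CompoundRecord]:
    """The 22-compound effects table as records (published columns ignored)."""
    path = Path(directory) / "opfr_effects.csv" if directory else fixture_path(
        "opfr_effects.csv"
    )
    return read_compound_table(path)


def load_opfr_effects_frame(directory: str | Path | None = None) -> pd.DataFrame:
    """The full effects table, including the published computed columns."""
    path = Path(directory) / "opfr_effects.csv" if directory else fixture_path(
        "opfr_effects.csv"
    )
    frame = pd.read_csv(path, dtype=str)
    for col in frame.columns:
        if col in ("compound_id", "set_tag"):
            continue
        frame[col] = frame[col].map(parse_number)
    return frame.set_index("compound_id")


def load_taguchi_runs(directory: str | Path | None = None) -> list[DoeRunRecord]:
    """The 27-run external-condition experiment with responses."""
    path = Path(directory) / "taguchi_runs.csv" if directory else fixture_path(
        "taguchi_runs.csv"
    )
    return read_doe_table(
        path,
        factors=reference.EXTERNAL_FACTORS,
        response_column="binding_free_energy_kj_mol",
        factor_columns=reference.EXTERNAL_FACTOR_COLUMNS,
        run_column="run",
    )


def _load_numeric_frame(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in frame.columns:
        if col in ("role", "parent_id", "compound_id"):
            continue
        frame[col] = frame[col].map(lambda v: parse_number(v) if v.strip() else None)
    return frame


def load_derivative_predictions(
    directory: str | Path | None = None,
) -> pd.DataFrame:
    """Predicted C/B/P values and published intensities for the derivatives."""
    path = (
        Path(directory) / "derivative_predictions.csv"
        if directory
        else fixture_path("derivative_predictions.csv")
    )
    return _load_numeric_frame(path)


def load_derivative_properties(
    directory: str | Path | None = None,
) -> pd.DataFrame:
    """Functional-property table (flame retardancy, gap, energy, frequency)."""
    path = (
        Path(directory) / "derivative_properties.csv"
        if directory
        else fixture_path("derivative_properties.csv")
    )
    return _load_numeric_frame(path)
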