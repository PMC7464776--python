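"""Reaction-energetics bookkeeping for degradation pathways.

All energies here are inputs (from quantum-chemistry calculations done
elsewhere); this module only combines them:

* reaction free energy   ΔG = ΣG(products) − ΣG(reactants)
* reaction barrier       ΔE = E(TS) − ΣE(reactants)
* standard enthalpy      H°(T) = E + ZPE + ΔH_trans + ΔH_rot + ΔH_vib + R·T
* bond dissociation enthalpy  BDE = H(frag1) + H(frag2) − H(parent)

kcal/mol is the canonical internal unit; Hartree (a.u.) and kJ/mol inputs
are converted explicitly.  Pathways are ordered step lists whose total
barrier is compared between a parent compound and its derivative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from ._util import round_half_up
from .errors import DomainError, ShapeError, UnitError

__all__ = [
    "HARTREE_TO_KCAL",
    "KCAL_TO_KJ",
    "GAS_CONSTANT_KCAL",
    "to_kcal",
    "SpeciesEnergetics",
    "ReactionStep",
    "Pathway",
    "PathwayComparison",
    "reaction_free_energy",
    "reaction_barrier",
    "standard_enthalpy",
    "bond_dissociation_enthalpy",
    "pathway_compare",
]

HARTREE_TO_KCAL = 627.5094740631  # kcal/mol per Hartree
KCAL_TO_KJ = 4.184  # kJ per kcal (thermochemical calorie)
GAS_CONSTANT_KCAL = 1.98720425e-3  # kcal mol^-1 K^-1

_UNIT_FACTORS = {"kcal/mol": 1.0, "kj/mol": 1.0 / KCAL_TO_KJ, "au": HARTREE_TO_KCAL,
                 "hartree": HARTREE_TO_KCAL}


def to_kcal(value: float, unit: str) -> float:
    """Convert an energy to kcal/mol from kcal/mol, kJ/mol or Hartree."""
    try:
        return value * _UNIT_FACTORS[unit.lower().replace(" ", "")]
    except KeyError:
        raise UnitError(f"unknown energy unit {unit!r}") from None


@dataclass
class SpeciesEnergetics:
    """Thermochemical components of one species, all in one unit."""

    species_id: str
    electronic_energy: float
    zpe: float = 0.0
    dh_trans: float = 0.0
    dh_rot: float = 0.0
    dh_vib: float = 0.0
    temperature: float = 298.15  # K
    unit: str = "kcal/mol"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")


@dataclass
class ReactionStep:
    """One elementary step with its activation barrier in kcal/mol."""

    label: str
    barrier: float
    reactant_ids: list[str] = field(default_factory=list)
    product_ids: list[str] = field(default_factory=list)
    ts_energy: float | None = None
    free_energy_change: float | None = None


@dataclass
class Pathway:
    """An ordered degradation route; the total barrier is the step sum."""

    pathway_id: str
    steps: list[ReactionStep]

    @property
    def total_barrier(self) -> float:
        return float(sum(s.barrier for s in self.steps))


def reaction_free_energy(
    product_g: Sequence[float], reactant_g: Sequence[float]
) -> float:
    """ΣG(products) − ΣG(reactants), kcal/mol."""
    if not product_g or not reactant_g:
        raise DomainError("product and reactant lists must be non-empty")
    return float(sum(product_g) - sum(reactant_g))


def reaction_barrier(ts_energy: float, reactant_e: Sequence[float]) -> float:
    """E(TS) − ΣE(reactants), kcal/mol.

    A negative barrier (TS below the reactants) is physically suspect for a
    true transition state; it is returned as-is but with a warning.
    """
    if not reactant_e:
        raise DomainError("reactant energy list must be non-empty")
    barrier = float(ts_energy - sum(reactant_e))
    if barrier < 0:
        warnings.warn(
            f"negative reaction barrier ({barrier:.4f} kcal/mol): transition "
            "state lies below the reactants",
            stacklevel=2,
        )
    return barrier


def standard_enthalpy(species: SpeciesEnergetics, include_rt: bool = True) -> float:
    """Standard enthalpy H°(T) of one species, in its declared unit.

    Sum of electronic energy, zero-point energy and the translational,
    rotational and vibrational thermal corrections, plus (by default) the
    ideal-gas R·T term converted into the species' unit.
    """
    total = (
        species.electronic_energy
        + species.zpe
        + species.dh_trans
        + species.dh_rot
        + species.dh_vib
    )
    if include_rt:
        rt_kcal = GAS_CONSTANT_KCAL * species.temperature
        total += rt_kcal / to_kcal(1.0, species.unit)
    return float(total)


def bond_dissociation_enthalpy(
    parent_h: float, fragment_h_1: float, fragment_h_2: float
) -> float:
    """Homolysis enthalpy H(frag1) + H(frag2) − H(parent), kcal/mol.

    Symmetric in the two fragments; a lower P–O BDE is read as better flame
    retardancy (easier release of the radical-scavenging PO• species).
    """
    return float(fragment_h_1 + fragment_h_2 - parent_h)


@dataclass
class PathwayComparison:
    """Step-aligned and total barrier differences between two pathways."""

    reference_id: str
    modified_id: str
    step_differences: list[float]  # reference − modified, per aligned step
    total_reference: float
    total_modified: float

    @property
    def total_reduction(self) -> float:
        """Absolute total-barrier reduction, kcal/mol."""
        return self.total_reference - self.total_modified

    @property
    def percent_reduction(self) -> float:
        """Total reduction as a percentage of the reference total."""
        return self.total_reduction / self.total_reference * 100.0

    def rounded_percent(self) -> float:
        return round_half_up(self.percent_reduction, 2)


def pathway_compare(reference: Pathway, modified: Pathway) -> PathwayComparison:
    """Compare a derivative's pathway barriers against the parent's.

    Steps are aligned by ordinal position.  If the step counts differ, only
    the totals are compared (with a warning); per-step differences are then
    empty.
    """
    if not reference.steps or not modified.steps:
        raise DomainError("both pathways must contain at least one step")
    if reference.total_barrier == 0:
        raise DomainError("reference pathway has zero total barrier")
    if len(reference.steps) != len(modified.steps):
        warnings.warn(
            f"pathways have {len(reference.steps)} vs {len(modified.steps)} "
            "steps; comparing totals only",
            stacklevel=2,
        )
        diffs: list[float] = []
    else:
        diffs = [
            r.barrier - m.barrier
            for r, m in zip(reference.steps, modified.steps)
        ]
    return PathwayComparison(
        reference_id=reference.pathway_id,
        modified_id=modified.pathway_id,
        step_differences=diffs,
        total_reference=reference.total_barrier,
        total_modified=modified.total_barrier,
    )
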