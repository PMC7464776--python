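"""Vacuum-vs-solvated UV transition-energy comparison.

A 2×2 grid of first-excited-state transition energies — {parent,
derivative} × {vacuum, solvated} — is reduced to four pairwise percent
reductions: derivative vs parent within each condition, and solvated vs
vacuum within each compound.  Lower transition energy means easier
photoexcitation, so a positive reduction is read as improved
photodegradability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

from .errors import DomainError, ValidationError

__all__ = [
    "Condition",
    "TransitionEnergyGrid",
    "SolvationReport",
    "transition_reduction",
    "solvation_report",
]

Condition = Literal["vacuum", "solvated"]
_CONDITIONS: tuple[Condition, ...] = ("vacuum", "solvated")


@dataclass
class TransitionEnergyGrid:
    """Mapping (compound_id, condition) → transition energy in eV."""

    entries: dict[tuple[str, Condition], float]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValidationError("grid needs at least two entries to compare")
        for (cid, cond), e in self.entries.items():
            if cond not in _CONDITIONS:
                raise ValidationError(f"unknown condition {cond!r} for {cid!r}")
            if e <= 0:
                raise ValidationError(
                    f"transition energy must be > 0 eV: ({cid}, {cond}) = {e}"
                )

    def energy(self, compound_id: str, condition: Condition) -> float:
        try:
            return self.entries[(compound_id, condition)]
        except KeyError:
            raise ValidationError(
                f"missing grid cell ({compound_id!r}, {condition!r})"
            ) from None


def transition_reduction(e_reference: float, e_other: float) -> float:
    """Percent by which e_other lies below e_reference."""
    if e_reference <= 0:
        raise DomainError("reference transition energy must be > 0")
    return (e_reference - e_other) / e_reference * 100.0


@dataclass
class SolvationReport:
    """The four pairwise reductions of a parent/derivative energy grid.

    All entries are percentages; positive = the second member of the pair
    has the lower (more photodegradable) transition energy.
    """

    parent_id: str
    derivative_id: str
    derivative_vs_parent_vacuum: float
    derivative_vs_parent_solvated: float
    solvation_effect_parent: float
    solvation_effect_derivative: float
    derivative_solvated_vs_parent_vacuum: float


def solvation_report(
    grid: TransitionEnergyGrid, parent: str, derivative: str
) -> SolvationReport:
    """Compare parent and derivative transition energies across conditions.

    Requires all four grid cells; raises ValidationError naming any missing
    (compound, condition) cell.  The extra cross comparison — solvated
    derivative vs vacuum parent — quantifies the combined gain from
    modification plus solvent environment.
    """
    pv = grid.energy(parent, "vacuum")
    ps = grid.energy(parent, "solvated")
    dv = grid.energy(derivative, "vacuum")
    ds = grid.energy(derivative, "solvated")
    return SolvationReport(
        parent_id=parent,
        derivative_id=derivative,
        derivative_vs_parent_vacuum=transition_reduction(pv, dv),
        derivative_vs_parent_solvated=transition_reduction(ps, ds),
        solvation_effect_parent=transition_reduction(pv, ps),
        solvation_effect_derivative=transition_reduction(dv, ds),
        derivative_solvated_vs_parent_vacuum=transition_reduction(pv, ds),
    )
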