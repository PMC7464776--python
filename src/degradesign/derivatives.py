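"""Derivative evaluation: improvement intensities and the practicality screen.

A candidate derivative is compared against its parent compound on the
predicted degradability channels (comprehensive score C, biodegradation
activity B on a −log scale, photodegradation transition energy P) and on
the functional properties (P–O bond dissociation enthalpy for flame
retardancy, HOMO–LUMO gap for insulation, total energy and minimum
vibrational frequency for stability).

Three named rate conventions are exposed because published tables mix them:

* reduction_intensity: (old − new)/|old| × 100 — positive when the value drops
* increase_intensity:  (new − old)/|old| × 100 — positive when it rises
* change_rate is increase_intensity under another name (signed as the
  raw change); enhanced_rate is reduction_intensity (positive = enhanced)

Denominators use |old| so that signed quantities (total energies in a.u.
are negative) keep the sign of the physical change.

The environment-friendly screen passes a derivative only if every one of
six criteria holds: lower C, higher B, lower P, enhanced flame retardancy,
all-positive vibrational frequencies, and an insulation (gap) loss no worse
than the configured tolerance (default 5%).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

from .errors import DomainError, ValidationError

__all__ = [
    "DerivativeComparison",
    "ScreenVerdict",
    "reduction_intensity",
    "increase_intensity",
    "change_rate",
    "enhanced_rate",
    "effect_ratio",
    "screen_environment_friendly",
]


@dataclass
class DerivativeComparison:
    """Parent-vs-derivative values needed by the practicality screen."""

    parent_id: str
    derivative_id: str
    c_pred_parent: float | None = None
    c_pred_derivative: float | None = None
    b_pred_parent: float | None = None
    b_pred_derivative: float | None = None
    p_pred_parent: float | None = None
    p_pred_derivative: float | None = None
    flame_retardancy_parent: float | None = None
    flame_retardancy_derivative: float | None = None
    gap_parent: float | None = None
    gap_derivative: float | None = None
    energy_parent: float | None = None
    energy_derivative: float | None = None
    min_frequency_derivative: float | None = None

    def __post_init__(self) -> None:
        if self.parent_id == self.derivative_id:
            raise ValidationError("parent and derivative ids must differ")


def reduction_intensity(old: float, new: float) -> float:
    """Percent drop from old to new; negative output means an increase."""
    if old == 0:
        raise DomainError("reduction intensity undefined for old == 0")
    return (old - new) / abs(old) * 100.0


def increase_intensity(old: float, new: float) -> float:
    """Percent rise from old to new; negative output means a decrease."""
    if old == 0:
        raise DomainError("increase intensity undefined for old == 0")
    return (new - old) / abs(old) * 100.0


def change_rate(old: float, new: float) -> float:
    """Signed relative change (new − old)/|old| × 100, as property tables print it."""
    return increase_intensity(old, new)


def enhanced_rate(old: float, new: float) -> float:
    """Flame-retardancy enhancement: positive when the P–O BDE decreased."""
    return reduction_intensity(old, new)


def effect_ratio(biodeg_increase: float, photodeg_reduction: float) -> float:
    """Ratio of the biodegradation gain to the photodegradation gain (both %)."""
    if photodeg_reduction == 0:
        raise DomainError("effect ratio undefined for zero photodegradation change")
    return biodeg_increase / photodeg_reduction


#: Screen criterion name → DerivativeComparison fields it needs.
_CRITERION_FIELDS: dict[str, tuple[str, ...]] = {
    "comprehensive_reduced": ("c_pred_parent", "c_pred_derivative"),
    "biodegradation_increased": ("b_pred_parent", "b_pred_derivative"),
    "photodegradation_reduced": ("p_pred_parent", "p_pred_derivative"),
    "flame_retardancy_enhanced": (
        "flame_retardancy_parent",
        "flame_retardancy_derivative",
    ),
    "structure_stable": ("min_frequency_derivative",),
    "insulation_maintained": ("gap_parent", "gap_derivative"),
}


@dataclass
class ScreenVerdict:
    """Per-criterion booleans plus the overall conjunction."""

    derivative_id: str
    criteria: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.criteria.values())


def screen_environment_friendly(
    cmp: DerivativeComparison, gap_tolerance: float = 5.0
) -> ScreenVerdict:
    """Apply the six-way environment-friendly screen to one derivative.

    gap_tolerance is the maximum tolerated insulation loss: the HOMO–LUMO
    gap change rate must be ≥ −gap_tolerance percent.
    """
    known = {f.name for f in fields(DerivativeComparison)}
    missing = [
        fname
        for crit, needed in _CRITERION_FIELDS.items()
        for fname in needed
        if fname in known and getattr(cmp, fname) is None
    ]
    if missing:
        raise ValidationError(
            f"{cmp.derivative_id}: missing fields for screening: "
            + ", ".join(sorted(set(missing)))
        )

    criteria: dict[str, bool] = {
        "comprehensive_reduced": cmp.c_pred_derivative < cmp.c_pred_parent,
        "biodegradation_increased": cmp.b_pred_derivative > cmp.b_pred_parent,
        "photodegradation_reduced": cmp.p_pred_derivative < cmp.p_pred_parent,
        "flame_retardancy_enhanced": enhanced_rate(
            cmp.flame_retardancy_parent, cmp.flame_retardancy_derivative
        )
        > 0,
        "structure_stable": cmp.min_frequency_derivative > 0,
        "insulation_maintained": change_rate(cmp.gap_parent, cmp.gap_derivative)
        >= -gap_tolerance,
    }
    return ScreenVerdict(derivative_id=cmp.derivative_id, criteria=criteria)
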