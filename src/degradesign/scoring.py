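"""Normalization-based composite degradability scoring.

Each effect channel (biodegradation proxied by enzyme-binding free energy,
photodegradation proxied by the first-excited-state UV transition energy)
is converted to a dimensionless efficacy coefficient by comparing the
compound's value against a target value T drawn from the same table:

    ratio_le1:  R = min(x, T) / max(x, T)   ∈ (0, 1]
    ratio_ge1:  R = max(x, T) / min(x, T)   ∈ [1, ∞)

Both equal 1 exactly when x = T.  Binding free energies enter as absolute
values (magnitudes), since the ratio is only meaningful on a positive scale.
The comprehensive evaluation value C is the weighted sum of a compound's
coefficients; with the default equal weights, C = (R_bio + R_photo) / 2.
Lower C is read as better composite degradability.

The default configuration — target = the reference compound TCIPP for both
channels, ratio_ge1 on |ΔG_bind| and ratio_le1 on transition energy — is the
one that reproduces the published 22-compound evaluation table cell for
cell.  TCIPP's values coincide with the lower/upper median of the respective
columns, so an order-statistic target policy is provided for tables without
a designated reference compound.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from ._util import round_half_up
from .errors import DomainError, ShapeError, ValidationError
from .tables_io import CompoundRecord

__all__ = [
    "Orientation",
    "TargetMode",
    "TargetPolicy",
    "EffectSpec",
    "WeightVector",
    "ScoreTable",
    "select_target",
    "efficacy_coefficient",
    "comprehensive_score",
    "score_table",
    "DEFAULT_EFFECTS",
    "DEFAULT_POLICIES",
    "DEFAULT_WEIGHTS",
]


class Orientation(str, Enum):
    """Which of min/max forms the numerator of the efficacy ratio."""

    RATIO_LE1 = "ratio_le1"  # min/max: rewards small values, capped at 1
    RATIO_GE1 = "ratio_ge1"  # max/min: penalizes deviation, floored at 1


class TargetMode(str, Enum):
    REFERENCE_COMPOUND = "reference_compound"
    ORDER_STATISTIC = "order_statistic"


@dataclass(frozen=True)
class TargetPolicy:
    """How the target value T is chosen from a column of effect values.

    reference_compound: T is the designated compound's own value.
    order_statistic: T is the ``order_index``-th (1-based) of the values
    sorted ascending — index (n+1)//2 gives the lower median.
    """

    mode: TargetMode
    reference_id: str | None = None
    order_index: int | None = None

    def __post_init__(self) -> None:
        if self.mode is TargetMode.REFERENCE_COMPOUND:
            if not self.reference_id or self.order_index is not None:
                raise ValidationError(
                    "reference_compound mode requires reference_id only"
                )
        elif self.mode is TargetMode.ORDER_STATISTIC:
            if self.order_index is None or self.reference_id is not None:
                raise ValidationError("order_statistic mode requires order_index only")
            if self.order_index < 1:
                raise ValidationError("order_index is 1-based and must be >= 1")


@dataclass(frozen=True)
class EffectSpec:
    """One effect channel: which record field it reads and how it is scored."""

    name: str
    value_accessor: str  # CompoundRecord attribute name
    use_magnitude: bool
    orientation: Orientation


@dataclass(frozen=True)
class WeightVector:
    """Per-effect weights; fractions in [0, 1] summing to 1."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not 0 <= w <= 1 for w in self.weights):
            raise ValidationError(f"weights must lie in [0, 1]: {self.weights}")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValidationError(f"weights must sum to 1: {self.weights}")


@dataclass
class ScoreTable:
    """Efficacy coefficients and comprehensive scores, one row per compound.

    ``frame`` is indexed by compound_id with one ``R_<effect>`` column per
    effect plus a ``comprehensive`` column; ``targets`` records the T used
    per effect (on the magnitude scale where applicable).
    """

    frame: pd.DataFrame
    targets: dict[str, float]
    weights: WeightVector

    def rounded(self) -> pd.DataFrame:
        """Report view: coefficients at 3 d.p., comprehensive score at 2 d.p."""
        out = self.frame.copy()
        for col in out.columns:
            nd = 2 if col == "comprehensive" else 3
            out[col] = out[col].map(lambda v: round_half_up(v, nd))
        return out


def select_target(
    values: Sequence[float],
    policy: TargetPolicy,
    *,
    ids: Sequence[str] | None = None,
    use_magnitude: bool = False,
) -> float:
    """Pick the target value T from a column under the given policy.

    With ``use_magnitude`` the target is returned on the magnitude scale,
    and order statistics are taken over magnitudes.
    """
    if len(values) == 0:
        raise DomainError("cannot select a target from an empty value list")
    scaled = [abs(v) for v in values] if use_magnitude else list(values)
    if policy.mode is TargetMode.REFERENCE_COMPOUND:
        if ids is None:
            raise ValidationError("reference_compound mode requires compound ids")
        try:
            pos = list(ids).index(policy.reference_id)
        except ValueError:
            raise DomainError(
                f"reference compound {policy.reference_id!r} not found"
            ) from None
        return scaled[pos]
    if policy.order_index > len(scaled):
        raise DomainError(
            f"order_index {policy.order_index} exceeds table size {len(scaled)}"
        )
    return sorted(scaled)[policy.order_index - 1]


def efficacy_coefficient(x: float, target: float, orientation: Orientation) -> float:
    """Dimensionless efficacy ratio of a value against the target.

    Inputs must be positive (take magnitudes first for signed quantities).
    """
    if x <= 0 or target <= 0:
        raise DomainError(
            f"efficacy ratio needs positive inputs, got x={x}, T={target}"
        )
    lo, hi = min(x, target), max(x, target)
    if orientation is Orientation.RATIO_LE1:
        return lo / hi
    return hi / lo


def comprehensive_score(coefficients: Sequence[float], w: WeightVector) -> float:
    """Weighted sum of a compound's efficacy coefficients."""
    if len(coefficients) != len(w.weights):
        raise ShapeError(
            f"{len(coefficients)} coefficients vs {len(w.weights)} weights"
        )
    return float(sum(c * wi for c, wi in zip(coefficients, w.weights)))


def score_table(
    records: Sequence[CompoundRecord],
    effects: Sequence[EffectSpec] | None = None,
    policies: Sequence[TargetPolicy] | None = None,
    w: WeightVector | None = None,
) -> ScoreTable:
    """Score every compound on every effect channel.

    Defaults reproduce the published evaluation table: TCIPP-referenced
    targets, ratio_ge1 on |ΔG_bind|, ratio_le1 on transition energy, equal
    weights.  Arithmetic is done unrounded; use ScoreTable.rounded() for the
    report view.
    """
    effects = list(DEFAULT_EFFECTS if effects is None else effects)
    policies = list(DEFAULT_POLICIES if policies is None else policies)
    w = DEFAULT_WEIGHTS if w is None else w
    if not (len(effects) == len(policies) == len(w.weights)):
        raise ShapeError("effects, policies and weights must align one-to-one")

    ids = [r.compound_id for r in records]
    columns: dict[str, list[float]] = {}
    targets: dict[str, float] = {}
    for eff, policy in zip(effects, policies):
        raw = []
        for r in records:
            v = getattr(r, eff.value_accessor)
            if v is None:
                raise ValidationError(
                    f"{r.compound_id} lacks a value for effect {eff.name!r}"
                )
            raw.append(v)
        target = select_target(
            raw, policy, ids=ids, use_magnitude=eff.use_magnitude
        )
        targets[eff.name] = target
        xs = [abs(v) for v in raw] if eff.use_magnitude else raw
        columns[f"R_{eff.name}"] = [
            efficacy_coefficient(x, target, eff.orientation) for x in xs
        ]

    frame = pd.DataFrame(columns, index=pd.Index(ids, name="compound_id"))
    coeff_cols = list(frame.columns)
    frame["comprehensive"] = [
        comprehensive_score(row, w) for row in frame[coeff_cols].to_numpy()
    ]
    return ScoreTable(frame=frame, targets=targets, weights=w)


DEFAULT_EFFECTS: tuple[EffectSpec, ...] = (
    EffectSpec(
        name="biodegradation",
        value_accessor="binding_free_energy",
        use_magnitude=True,
        orientation=Orientation.RATIO_GE1,
    ),
    EffectSpec(
        name="photodegradation",
        value_accessor="transition_energy",
        use_magnitude=False,
        orientation=Orientation.RATIO_LE1,
    ),
)

DEFAULT_POLICIES: tuple[TargetPolicy, ...] = (
    TargetPolicy(mode=TargetMode.REFERENCE_COMPOUND, reference_id="TCIPP"),
    TargetPolicy(mode=TargetMode.REFERENCE_COMPOUND, reference_id="TCIPP"),
)

DEFAULT_WEIGHTS = WeightVector(weights=(0.5, 0.5))
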