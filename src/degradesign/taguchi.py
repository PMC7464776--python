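"""Three-level orthogonal-array (Taguchi) design and main-effects analysis.

The L27(3^7) design assigns seven three-level factors to columns of the
27-run orthogonal array L27(3^13).  Each column is balanced (every level
appears 9 times) and every column pair is orthogonal (each of the 9 ordered
level pairs co-occurs exactly 3 times), so per-factor level means — the main
effects — are estimated independently of one another.

Analysis here follows the classical range ("delta") method: factor
importance is the spread max−min of its three level means, and the optimal
level is the one whose mean response best meets the objective.  For enzyme
binding free energies the objective is minimization: a more negative mean
ΔG_bind means stronger affinity between the degrading enzyme and the
compound, hence easier biodegradation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Literal, Sequence

import numpy as np

from .errors import DomainError, ShapeError, ValidationError

__all__ = [
    "Factor",
    "TaguchiDesign",
    "MainEffects",
    "FactorRanking",
    "build_l27_design",
    "validate_orthogonal_array",
    "level_means",
    "rank_factors",
    "affinity_improvement",
]


@dataclass(frozen=True)
class Factor:
    """One controllable external condition with exactly three levels.

    Levels are physical values in ascending declaration order; the design
    matrix stores 1-based indices into this list.
    """

    name: str
    unit: str
    levels: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.levels) != 3 or len(set(self.levels)) != 3:
            raise ValidationError(
                f"factor {self.name!r} must declare exactly 3 distinct levels, "
                f"got {self.levels!r}"
            )

    def level_index(self, value: float) -> int:
        """Map a physical value to its 1-based level index."""
        for i, lv in enumerate(self.levels, start=1):
            if math.isclose(value, lv, rel_tol=1e-9, abs_tol=1e-12):
                return i
        raise ValidationError(
            f"value {value!r} is not a declared level of factor {self.name!r} "
            f"(levels: {self.levels!r})"
        )


@dataclass
class TaguchiDesign:
    """An orthogonal array: runs × factors matrix of level indices in {1,2,3}."""

    level_matrix: np.ndarray
    factors: list[Factor]

    def __post_init__(self) -> None:
        self.level_matrix = np.asarray(self.level_matrix, dtype=int)
        if self.level_matrix.ndim != 2:
            raise ShapeError("level_matrix must be 2-dimensional")
        if self.level_matrix.shape[1] != len(self.factors):
            raise ShapeError(
                f"level_matrix has {self.level_matrix.shape[1]} columns but "
                f"{len(self.factors)} factors are declared"
            )

    @property
    def runs(self) -> int:
        return self.level_matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return self.level_matrix.shape[1]

    def validate(self) -> None:
        """Check balance and pairwise orthogonality; raise ValidationError if violated."""
        validate_orthogonal_array(self.level_matrix)


def validate_orthogonal_array(matrix: np.ndarray, n_levels: int = 3) -> None:
    """Brute-force strength-2 orthogonality check.

    Balance: each level appears runs/n_levels times in every column.
    Orthogonality: every ordered level pair appears runs/n_levels**2 times
    in every column pair.
    """
    matrix = np.asarray(matrix, dtype=int)
    runs, n_cols = matrix.shape
    if runs % (n_levels**2):
        raise ValidationError(
            f"{runs} runs cannot form a strength-2 array on {n_levels} levels"
        )
    per_level = runs // n_levels
    per_pair = runs // n_levels**2
    levels = range(1, n_levels + 1)
    for c in range(n_cols):
        counts = {lv: int(np.sum(matrix[:, c] == lv)) for lv in levels}
        if any(counts[lv] != per_level for lv in levels):
            raise ValidationError(f"column {c} is unbalanced: {counts}")
    for c1, c2 in combinations(range(n_cols), 2):
        for l1, l2 in product(levels, repeat=2):
            n = int(np.sum((matrix[:, c1] == l1) & (matrix[:, c2] == l2)))
            if n != per_pair:
                raise ValidationError(
                    f"columns ({c1},{c2}) not orthogonal: level pair "
                    f"({l1},{l2}) occurs {n} times, expected {per_pair}"
                )


def _l27_columns() -> np.ndarray:
    """The 27×13 array from the 13 nonzero ternary linear functionals.

    Runs are the 27 points (a, b, c) of GF(3)^3, a varying slowest.  Columns
    are the functionals w1·a + w2·b + w3·c (mod 3) with coefficient vectors
    normalized so the first nonzero coefficient is 1 — one representative per
    projective direction — taken in lexicographic coefficient order.
    """
    coeffs = [
        w
        for w in product(range(3), repeat=3)
        if any(w) and next(x for x in w if x) == 1
    ]
    points = np.array(list(product(range(3), repeat=3)))  # a slowest
    cols = [(points @ np.array(w)) % 3 for w in coeffs]
    return np.stack(cols, axis=1) + 1


def build_l27_design(
    n_factors: int, factors: Sequence[Factor] | None = None
) -> TaguchiDesign:
    """Construct an L27(3^n) design for up to 13 three-level factors.

    If ``factors`` is omitted, generic placeholder factors with levels
    (1, 2, 3) are attached.
    """
    if not 1 <= n_factors <= 13:
        raise DomainError(f"n_factors must be in [1, 13], got {n_factors}")
    matrix = _l27_columns()[:, :n_factors]
    if factors is None:
        factors = [
            Factor(name=f"F{i + 1}", unit="", levels=(1.0, 2.0, 3.0))
            for i in range(n_factors)
        ]
    elif len(factors) != n_factors:
        raise ShapeError("len(factors) must equal n_factors")
    design = TaguchiDesign(level_matrix=matrix, factors=list(factors))
    design.validate()
    return design


@dataclass
class MainEffects:
    """Per-factor level means of the response, plus the grand mean."""

    level_means: np.ndarray  # factors × 3
    grand_mean: float
    factors: list[Factor] = field(default_factory=list)


@dataclass
class FactorRanking:
    """Range-based factor importance and per-factor optimal levels."""

    ranges: np.ndarray  # per-factor max − min of level means
    ranks: np.ndarray  # permutation of 1..n_factors, 1 = largest range
    optimal_level: np.ndarray  # 1-based level index meeting the objective
    objective: Literal["min", "max"] = "min"


def level_means(design: TaguchiDesign, response: Sequence[float]) -> MainEffects:
    """Mean response at each (factor, level) cell of a balanced design.

    Entry (f, l) is the arithmetic mean of the response over all runs in
    which factor f sits at level l+1.
    """
    y = np.asarray(response, dtype=float)
    if y.shape != (design.runs,):
        raise ShapeError(
            f"response has length {y.size}, design has {design.runs} runs"
        )
    means = np.empty((design.n_factors, 3))
    for f in range(design.n_factors):
        for lv in range(3):
            means[f, lv] = y[design.level_matrix[:, f] == lv + 1].mean()
    return MainEffects(
        level_means=means, grand_mean=float(y.mean()), factors=list(design.factors)
    )


def rank_factors(
    effects: MainEffects, objective: Literal["min", "max"] = "min"
) -> FactorRanking:
    """Rank factors by the range of their level means; pick optimal levels.

    Ranks are assigned in descending range order; ties are broken by factor
    declaration order (stable sort).  The optimal level is the argmin of the
    level means under the default minimization objective (most negative
    binding free energy = strongest affinity), argmax under "max".
    """
    means = np.asarray(effects.level_means, dtype=float)
    ranges = means.max(axis=1) - means.min(axis=1)
    order = np.argsort(-ranges, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(order) + 1)
    if objective == "min":
        optimal = means.argmin(axis=1) + 1
    elif objective == "max":
        optimal = means.argmax(axis=1) + 1
    else:
        raise DomainError(f"objective must be 'min' or 'max', got {objective!r}")
    return FactorRanking(
        ranges=ranges, ranks=ranks, optimal_level=optimal, objective=objective
    )


def affinity_improvement(g_reference: float, g_new: float) -> float:
    """Percent gain in binding-affinity magnitude relative to a reference.

    Computed on magnitudes, (|g_new| − |g_reference|) / |g_reference| × 100,
    so the sign convention of the inputs (binding energies are reported both
    signed and unsigned) does not matter.  Positive output = stronger binding.
    """
    if g_reference == 0:
        raise DomainError("reference binding free energy must be nonzero")
    return (abs(g_new) - abs(g_reference)) / abs(g_reference) * 100.0
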