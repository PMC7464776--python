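"""Synthetic data generators mirroring the statistical shape of real inputs.

Three generators cover the three input kinds the pipeline consumes:

* compound property tables — binding free-energy magnitudes drawn
  log-normally (the real 22-compound table spans |ΔG_bind| ≈ 9–269 kJ/mol,
  a ratio of ~29, far wider than any normal spread), transition energies
  drawn from a normal truncated at zero (real range ≈ 4.3–8.3 eV);
* balanced three-level factorial responses — an additive main-effects model
  y = μ + Σ_f δ_f(level) + ε with Gaussian noise, the model under which
  range-based factor ranking is consistent;
* two-pathway barrier profiles with an exactly known total-barrier
  reduction, for round-trip testing of the comparison report.

Every generator is a pure function of its configuration: the same seed
reproduces the same output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .energetics import Pathway, ReactionStep
from .errors import ValidationError
from .tables_io import CompoundRecord
from .taguchi import TaguchiDesign

__all__ = [
    "SimulationConfig",
    "gen_compound_table",
    "gen_doe_response",
    "gen_pathway_pair",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic generators, with defaults sized like the
    real study inputs (22 compounds; 27-run DOE around −77 kJ/mol; hundred-
    kcal/mol-scale step barriers)."""

    seed: int = 0
    n_compounds: int = 22
    binding_mean: float = 130.0  # kJ/mol, median |ΔG_bind| magnitude
    binding_spread: float = 0.7  # log-scale SD of the magnitude
    energy_mean: float = 6.9  # eV
    energy_spread: float = 1.3  # eV
    doe_grand_mean: float = -77.0  # kJ/mol
    planted_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=dict
    )  # factor name -> level offsets, each triple summing to 0
    noise_sd: float = 5.0  # kJ/mol
    pathway_step_count: int = 3
    barrier_range: tuple[float, float] = (150.0, 400.0)  # kcal/mol
    pathway_reduction_pct: float = 15.73  # planted total-barrier reduction

    def __post_init__(self) -> None:
        if self.binding_spread < 0 or self.energy_spread < 0 or self.noise_sd < 0:
            raise ValidationError("spreads and noise_sd must be >= 0")
        if self.n_compounds < 2:
            raise ValidationError("n_compounds must be >= 2")
        if self.pathway_step_count < 1:
            raise ValidationError("pathway_step_count must be >= 1")
        lo, hi = self.barrier_range
        if not 0 < lo <= hi:
            raise ValidationError(f"invalid barrier_range {self.barrier_range}")
        for name, deltas in self.planted_effects.items():
            if len(deltas) != 3:
                raise ValidationError(f"factor {name!r}: need 3 level offsets")
            if abs(sum(deltas)) > 1e-9:
                raise ValidationError(
                    f"factor {name!r}: planted offsets must sum to 0, got {deltas}"
                )


def gen_compound_table(cfg: SimulationConfig) -> list[CompoundRecord]:
    """Draw a synthetic compound property table.

    Binding free energies are negative with log-normal magnitude
    ``binding_mean · exp(binding_spread · Z)``; transition energies are
    normal(energy_mean, energy_spread) redrawn until positive.  With zero
    spreads every compound carries the channel mean, so downstream scoring
    degenerates to all-ones coefficients.
    """
    rng = np.random.default_rng(cfg.seed)
    magnitudes = cfg.binding_mean * np.exp(
        cfg.binding_spread * rng.standard_normal(cfg.n_compounds)
    )
    energies = np.empty(cfg.n_compounds)
    for i in range(cfg.n_compounds):
        e = rng.normal(cfg.energy_mean, cfg.energy_spread)
        while e <= 0:  # truncate at zero; rare for realistic configs
            e = rng.normal(cfg.energy_mean, cfg.energy_spread)
        energies[i] = e
    width = len(str(cfg.n_compounds))
    return [
        CompoundRecord(
            compound_id=f"CPD-{i + 1:0{width}d}",
            binding_free_energy=-float(m),
            transition_energy=float(e),
        )
        for i, (m, e) in enumerate(zip(magnitudes, energies))
    ]


def gen_doe_response(design: TaguchiDesign, cfg: SimulationConfig) -> np.ndarray:
    """Simulate responses y = μ + Σ_f δ_f(level of run) + N(0, noise_sd²).

    planted_effects must be keyed by the design's factor names (factors
    without an entry get zero offsets).  With noise_sd = 0 the level means
    recover the planted offsets exactly.
    """
    names = [f.name for f in design.factors]
    unknown = set(cfg.planted_effects) - set(names)
    if unknown:
        raise ValidationError(
            f"planted_effects reference unknown factors: {sorted(unknown)}"
        )
    rng = np.random.default_rng(cfg.seed)
    y = np.full(design.runs, cfg.doe_grand_mean)
    for f, name in enumerate(names):
        deltas = cfg.planted_effects.get(name, (0.0, 0.0, 0.0))
        y += np.take(deltas, design.level_matrix[:, f] - 1)
    y += rng.normal(0.0, cfg.noise_sd, size=design.runs)
    return y


def gen_pathway_pair(cfg: SimulationConfig) -> tuple[Pathway, Pathway, float]:
    """Generate a (reference, modified, true_reduction_percent) triple.

    Reference step barriers are uniform in ``barrier_range``; the modified
    pathway scales every step by (1 − pathway_reduction_pct/100), so the
    planted total reduction is exact by construction and the comparison
    report must recover it to round-off.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.barrier_range
    barriers = rng.uniform(lo, hi, size=cfg.pathway_step_count)
    scale = 1.0 - cfg.pathway_reduction_pct / 100.0
    reference = Pathway(
        pathway_id="reference",
        steps=[
            ReactionStep(label=f"step-{i + 1}", barrier=float(b))
            for i, b in enumerate(barriers)
        ],
    )
    modified = Pathway(
        pathway_id="modified",
        steps=[
            ReactionStep(label=f"step-{i + 1}", barrier=float(b * scale))
            for i, b in enumerate(barriers)
        ],
    )
    return reference, modified, cfg.pathway_reduction_pct
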