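# degradesign

Design-support analytics for **degradable organophosphorus flame retardants
(OPFRs)**. Chlorinated OPFRs such as TCPP, TCEP and TCIPP are widespread
aquatic pollutants that resist both activated-sludge biodegradation and
UV photodegradation. One design strategy attacks the problem at the source:
score each compound's composite degradability, modify the worst offenders
with hydrophilic substituents, screen the candidates for retained flame
retardancy and stability, and tune the external degradation conditions.
`degradesign` implements that computational chain as a tested, reusable
library and CLI for anyone re-analyzing such datasets or applying the same
workflow to new compound families.

## What it computes

**Composite degradability score.** Each effect channel is normalized
against a target value *T* taken from the same table (a designated
reference compound, or an order statistic such as the median):

```
R = min(x, T) / max(x, T)        (ratio_le1, in (0, 1])
R = max(x, T) / min(x, T)        (ratio_ge1, in [1, ∞))
```

Biodegradation uses the enzyme-binding free energy |ΔG_bind| (kJ/mol,
against the *Sphingobium* sp. TCM1 phosphotriesterase) with the `ratio_ge1`
orientation; photodegradation uses the first-excited-state UV transition
energy (eV) with `ratio_le1`. The comprehensive evaluation value is the
weighted sum `C = w₁·R_bio + w₂·R_photo` (default weights 0.5/0.5); lower
C is read as better composite degradability.

**Taguchi main-effects analysis.** An L27(3⁷) orthogonal array (27 runs,
seven three-level factors: pH, temperature, methanol, acetic acid, H₂O₂,
voltage gradient, surfactant) is constructed from the 13 ternary linear
functionals over GF(3)³, or accepted from a run table and validated by
brute-force balance/orthogonality counting. Factor importance is the range
`max − min` of the three per-level mean responses; the optimal level
minimizes the mean binding free energy. The affinity-improvement metric is
`(|ΔG_new| − |ΔG_ref|)/|ΔG_ref| × 100`.

**Energetics bookkeeping.** Reaction free energies
`ΔG = ΣG(products) − ΣG(reactants)`, barriers `ΔE = E(TS) − ΣE(reactants)`,
standard enthalpies `H°(T) = E + ZPE + ΔH_trans + ΔH_rot + ΔH_vib + RT`,
P–O bond dissociation enthalpies `BDE = H(frag₁) + H(frag₂) − H(parent)`,
and parent-vs-derivative pathway comparisons with per-step and total
percent barrier reductions.

**Derivative screening.** Improvement intensities
(`(old−new)/|old| × 100` and its increase counterpart), the
biodegradation/photodegradation gain ratio, and a six-criterion
environment-friendly screen: lower C, higher predicted biodegradation
activity, lower transition energy, enhanced flame retardancy (lower P–O
BDE), all-positive vibrational frequencies, and a HOMO–LUMO gap loss within
tolerance (default 5%).

**Solvation comparison.** Percent reductions of UV transition energies
across a {parent, derivative} × {vacuum, solvated} grid.

Reference datasets for the chlorinated-OPFR study (22 compounds, 27-run
external-condition experiment, 18 predicted derivatives, 14 evaluated
derivatives) ship with the package in `degradesign.data`.

## Worked example

Score the packaged 22-compound table (targets default to the reference
compound TCIPP):

```
$ degradesign score src/degradesign/data/opfr_effects.csv
             R_biodegradation  R_photodegradation  comprehensive
compound_id
TCEP                    1.168               0.992           1.08
TCIPP                   1.000               1.000           1.00
TCPP                    3.454               0.991           2.22
...
```

TCPP's binding free energy (−41.842 kJ/mol) is far weaker than the target
magnitude (|−144.537|), giving R_bio = 144.537/41.842 = 3.454 and C = 2.22
— the compound binds its degrading enzyme poorly and is flagged as a
modification target. Analyze the external-condition experiment:

```
$ degradesign doe-analyze src/degradesign/data/taguchi_runs.csv
                  pH temperature methanol acetic_acid   h2o2 voltage surfactant
1             -82.31      -76.75   -74.49      -78.06 -84.66  -71.28     -77.44
2             -75.11      -81.28   -75.19      -75.48 -71.56  -81.27     -74.85
3             -73.46      -72.85   -81.19      -77.34 -74.66  -78.32     -78.59
range           8.86        8.44     6.69        2.57   13.1    10.0       3.73
rank               3           4        5           7      1       2          6
optimal_level      1           2        3           1      1       2          3
```

H₂O₂ concentration has the largest level-mean range (13.10 kJ/mol, rank 1):
oxygen supply dominates the biodegradation response, followed by voltage
gradient and pH. The optimal combination (pH 6.5, 303 K, methanol 500 mg/L,
acetic acid 200 mg/L, H₂O₂ 300 mg/L, voltage 1 V/m, surfactant 750 mg/L) is
printed to stderr. Compare degradation pathway barriers:

```
$ degradesign pathway-compare ref.csv mod.csv
total barrier ref: 249.4895 kcal/mol
total barrier mod: 210.2360 kcal/mol
reduction: 39.2535 kcal/mol (15.73%)
```

`degradesign reproduce` re-runs every published derived statistic of the
reference datasets (66 score cells, 21 level means plus ranking, barrier
reductions, 42 property change rates, the 14-way screen, and the
percentage families computed from unrounded internals) and exits non-zero
on any mismatch. Other subcommands: `validate`, `evaluate`,
`solvation-report`, `simulate` (see `degradesign --help`).

## Layout

```
src/degradesign/      library (tables_io, scoring, taguchi, energetics,
                      derivatives, solvation, simulate, verify, cli)
src/degradesign/data/ packaged reference CSVs + loaders
docs/methods.md       models, conventions, numerical choices, limitations
tests/                pytest suite (unit, property-based, acceptance)
```
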