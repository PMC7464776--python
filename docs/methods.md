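# Methods

This note records the models implemented by `degradesign`, the conventions
chosen where the source material was ambiguous, and what the test suite
does and does not demonstrate.

## Composite degradability scoring

Two effect channels proxy degradability: the binding free energy ΔG_bind
(kJ/mol) between a compound and its degrading enzyme (biodegradation; more
negative = stronger binding = more favorable hydrolysis), and the
first-excited-state UV transition energy (eV) (photodegradation; lower =
easier photoexcitation). Each channel is reduced to a dimensionless
efficacy coefficient by comparison with a target value T, and the
comprehensive value C is the weighted coefficient sum.

**Orientation.** The normalization ratio can be taken either way around:

* `ratio_le1` = min(x,T)/max(x,T) ∈ (0,1] — rewards values near or below
  the target scale symmetrically;
* `ratio_ge1` = max(x,T)/min(x,T) ∈ [1,∞) — its exact reciprocal.

The published evaluation table is reproducible only with `ratio_ge1` on
binding-energy magnitudes and `ratio_le1` on transition energies (e.g.
144.537/41.842 = 3.454 for TCPP's biodegradation coefficient but
7.2211/7.2874 = 0.991 for its photodegradation coefficient). Orientation
is therefore an explicit per-effect setting, with that reconciled pair as
the default. Note the semantic tension this implies: under `ratio_ge1`
the strongest binder in the table (TEHP, −268.708 kJ/mol) still scores
1.859 because the ratio penalizes deviation from the target in *both*
directions. The package computes the score as defined and takes no
position on whether a lower C truly means faster real-world degradation.

**Target policy.** The default target is a designated reference compound
(TCIPP), whose values equal the lower median of the 22 binding-energy
magnitudes and the upper median of the 22 transition energies — a single
rule consistent with both channels. For tables without a designated
reference, an order-statistic policy (k-th ascending value, e.g.
(n+1)//2 for the lower median) is provided.

**Magnitudes and signs.** Binding free energies are negative; they enter
the ratios as absolute values, which is the only way the all-positive
published coefficients can arise.

**Weights.** Default 0.5/0.5, treating biodegradability and
photodegradability as equally important; any simplex weight vector is
accepted.

**Rounding.** All arithmetic is double precision and unrounded;
coefficients are *reported* at 3 decimals and C at 2, using half-up
rounding (`decimal`-based) because printed report tables round ties away
from zero while Python's built-in `round` is banker's.

## Taguchi L27(3^7) design and analysis

**Construction.** Runs are the 27 points of GF(3)³; the 13 columns of the
full L27(3¹³) array are the nonzero ternary linear functionals with first
nonzero coefficient normalized to 1 (one per projective direction), taken
in lexicographic coefficient order; a design on n ≤ 13 factors takes the
first n columns. Balance (each level 9×/column) and strength-2
orthogonality (each ordered level pair 3×/column pair) follow from
linear-algebraic independence and are additionally verified by brute-force
counting — the same validator applied to run tables read from files. The
27-run external-condition experiment shipped in `degradesign.data` passes
this validator, so its published analysis is reproducible without assuming
any particular column assignment.

**Analysis.** Main effects are per-(factor, level) arithmetic means of the
response over the 9 runs at that level. Factor importance is the range
(max − min) of the three level means — the classical "delta" statistic.
Signal-to-noise transforms and ANOVA F-tests are deliberately not
implemented: the range statistic alone reproduces the published ranking,
and the source reports no variance decomposition to compare against. The
objective defaults to minimization (more negative binding free energy =
stronger enzyme affinity); ranks are unaffected by the objective. Ties in
the range are broken by factor declaration order (stable sort) —
deterministic and documented.

Note one source inconsistency carried as-is: the narrative quotes an
optimal H₂O₂ concentration of 200 mg/L, but 200 is not among that factor's
declared levels {300, 350, 400}; the argmin of the published level means
is 300 mg/L, which is what the analysis reports. The voltage unit is
stored as the run-table header's "V/m" (the narrative says "V/cm"); it is
a label, never converted.

## Energetics

All energies are inputs from external quantum-chemistry calculations.
kcal/mol is canonical; Hartree (× 627.5094740631) and kJ/mol (÷ 4.184)
are converted explicitly, never guessed. The standard enthalpy assembles
H°(T) = E + ZPE + ΔH_trans + ΔH_rot + ΔH_vib + R·T with the ideal-gas R·T
term optional but on by default at 298.15 K (R = 1.98720425×10⁻³
kcal·mol⁻¹·K⁻¹). The bond dissociation enthalpy is the standard homolysis
form H(frag₁) + H(frag₂) − H(parent), symmetric in the fragments. The
barrier ΔE = E(TS) − ΣE(reactants) may be negative for ill-posed inputs;
it is returned with a warning rather than rejected. Pathway comparison
aligns steps by ordinal position; on length mismatch it compares totals
only and warns. Percent reduction is (total_ref − total_mod)/total_ref ×
100, so reduction% + (total_mod/total_ref)×100 ≡ 100 is an exact identity
the tests exploit.

## Derivative evaluation and the practicality screen

Three rate conventions are exposed as separately named operations because
mixed sign conventions are the main source of confusion in this kind of
table: `reduction_intensity` (old−new)/|old|·100, `increase_intensity`
(new−old)/|old|·100, and their aliases `enhanced_rate` (flame retardancy:
positive = BDE dropped) and `change_rate` (signed raw change). The
denominator uses |old| so that quantities with negative values (total
energies in a.u.) keep the sign of the physical change — with a plain
`old` denominator the published energy change rates would come out with
inverted signs.

The environment-friendly screen is a conjunction of six criteria (lower C,
higher predicted biodegradation activity, lower predicted transition
energy, enhanced flame retardancy, positive minimum frequency, gap change
rate ≥ −5% by default). It is monotone: worsening any single input can
only flip pass→fail, never fail→pass.

**Reproduction bands.** The published change rates of the
functional-property table reproduce exactly after rounding from the
printed values for the gap and energy columns (28/28 cells). Three of the
14 flame-retardancy rates differ from printed-input recomputation by
exactly one unit in the last printed digit (e.g. −13.73 published vs
−13.72 recomputed), the signature of rates computed from unrounded
enthalpies; the verification check therefore allows ±0.01 pp on that
column only. The prediction-table intensities were likewise computed from
unrounded predictions; recomputing them from the printed 2-d.p. inputs
(magnitudes ≈ 1–7) carries input-rounding leverage up to ≈ 0.8 pp, so each
cell is checked against its half-ulp propagation bound
100·0.005·(|old|+|new|)/old². Two cells — the comprehensive-score
reductions of TCEP–NH₂ and TCEP–CHO — are inconsistent with their own
printed inputs beyond any rounding argument (26.55 and 26.40 published vs
34.26 and 43.52 recomputed; both would require C_pred ≈ 0.79 rather than
the printed 0.71 and 0.61). They are enumerated in
`degradesign.reference.KNOWN_INCONSISTENT_INTENSITIES`, reported by the
verification run, and excluded from pass/fail. These are also the only two
predicted derivatives absent from the functional-property evaluation. The
four solvation reductions recompute from the printed eV energies within
±0.2 pp.

## Synthetic data

The generators emulate the *statistical shape* of the real inputs, not
their physics:

* compound tables: binding magnitudes log-normal around a median of
  130 kJ/mol with log-SD 0.7 (the real table spans 9.2–268.7 kJ/mol, a
  29-fold range that a normal cannot produce without sign violations);
  transition energies normal(6.9, 1.3) eV truncated at zero (real range
  4.3–8.3 eV);
* DOE responses: additive main-effects model y = μ + Σ_f δ_f(level) + ε
  with μ = −77 kJ/mol (the real 27-run grand mean ≈ −76.96) and
  ε ~ N(0, 5²) kJ/mol, matching the scale of the real level-mean ranges
  (2.6–13.1 kJ/mol); planted per-factor offsets must sum to zero so the
  grand mean stays interpretable;
* pathway pairs: reference barriers uniform in 150–400 kcal/mol (the
  scale of the published steps), with every modified step scaled by
  1 − r/100 so the planted total reduction r is exact by construction.

Everything is a pure function of (config, seed) via
`numpy.random.default_rng`. Because the DOE generator is exactly the
additive model the range analysis assumes, passing recovery tests show
correctness of the analysis pipeline, not robustness to interaction
effects, heteroscedastic noise, or model misspecification — real responses
offer no such guarantee. Likewise the compound generator draws channels
independently, whereas real binding energies and transition energies are
correlated through molecular size and class.

Test problem sizes: planted-effect recovery uses 200 replicates of the
27-run design (≥ 95% rank-1 recovery at 5σ separation), the null-ranking
check 2000 replicates; both complete in seconds.

## Degenerate inputs and numerical edges

Efficacy ratios require strictly positive inputs after magnitude handling;
zero or negative values raise domain errors rather than propagating
infinities. An empty compound table is a valid read result but an invalid
scoring input. A constant score table yields all-ones coefficients, C = 1.
The DOE analysis requires the response length to equal the run count and
is defined for any balanced design, not only 27 runs. Transcribed tables
may use typographic minus signs (U+2212, en/em dashes); all readers
normalize them, and unparseable cells are collected and reported together
rather than dropped.

## Limitations

* No quantum chemistry, docking, molecular dynamics or pharmacophore
  modeling is performed; every energy and predicted activity is an input.
* The scoring model is reproduced as defined, including its
  both-directions penalty on the biodegradation channel (see above); users
  wanting "stronger binding is strictly better" semantics should select
  `ratio_le1` on magnitudes explicitly.
* The screen thresholds (gap tolerance 5%) and weights (0.5/0.5) are
  conventions of the reference analysis, not fitted quantities.
* Candidate derivative lists are inputs; substituent-site selection from
  pharmacophore force-field maps is out of scope.
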