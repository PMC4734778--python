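# Methods

## Model and assumptions

`ilfkit` treats a multicellular logic circuit as a set of physically
isolated chambers that all receive the same stimulus mixture. Inside a
chamber, input-layer (IL) sensor cells secrete a single wiring molecule ω
into the shared medium; the pooled ω represses the chamber's output-layer
(OL) cell. Because any secreting cell suffices to shut the OL off, a chamber
computes NOR over its sensors' activities, and the whole circuit computes
the OR of its chambers. The compiler exploits this: a minimal
sum-of-products is double-negated (De Morgan) so that each product term maps
onto one NOR chamber, with each literal inverted into a sensor-cell choice
(positive literal → NOT cell, negated literal → ID cell).

Modelling assumptions, all deliberate simplifications:

- **Steady state only.** All readouts are endpoint measurements; incubation
  kinetics, growth and dilution are not simulated.
- **Linear ω pooling.** A sensor's contribution is
  `fraction × max_wire_output × response/100`; contributions add. There is
  no degradation term (its effect can be folded into `max_wire_output`).
- **Well-mixed chambers.** No spatial gradients within a chamber; space
  enters the model only as the isolation *between* chambers.
- **Crosstalk is linear.** A cell's effective stimulus is its own input plus
  a weighted sum of the others (weights default to 0).
- **Secreted outputs add across chambers** in buffer mode. How multiple
  chamber effluents combine volumetrically is not otherwise specified, so
  linear summation is the assumption.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| Hill floor `y_low` | 5 | % positive cells | basal leakage of every cell type |
| Hill ceiling `y_high` | 85 | % positive cells | saturated response |
| sensor half-max `K` | 10 | concentration (abstract) | input sensitivity |
| Hill coefficient `n` | 8 (`ideal_step`) / 2 (`graded`) | – | stage steepness |
| working concentration | 10·K | concentration | the stimulus level encoding logic 1 |
| wire ceiling `max_wire_output` | 100 | ω units per unit cell fraction | scales pooled ω |
| OL half-max | 7 | ω units | sits between basal pool and one active sensor |
| buffer half-max | 35 | β units | below one firing chamber's output |
| chamber composition | equal IL fractions, 20% OL | – | configurable per chamber |
| logic thresholds | 20 / 60 | % positive cells | 0-state / 1-state boundaries |

All Hill parameters are **synthetic stand-ins**: they were constructed to
satisfy the digital-abstraction geometry (floor below the 20% threshold,
ceiling above 60%, steep transition), not fitted to measurements. The OL
half-max of 7 ω units was chosen between the worst-case basal pool of a
fully silent chamber (0.8 × 100 × 0.05 = 4) and the smallest single-active-
sensor signal at six sensors per chamber (0.8/6 × 100 × 0.85 ≈ 11.3), which
is what makes the step-profile library verify every function up to six
inputs. The buffer half-max of 35 sits above the summed basal β of up to
~4 silent chambers and below one firing chamber's ~84; buffer-mode designs
with many more chambers would accumulate enough basal β to mis-fire — a
known limitation (transducer mode has no such coupling).

## Minimization and tie-breaking

Prime implicants come from the classic Quine–McCluskey tabulation; cover
selection is exact branch-and-bound (essential primes first, then search
with an admissible bound), minimizing lexicographically: (1) term count,
(2) total literal count, with a deterministic canonical ordering of the
resulting terms. A circuit-wide "fewest distinct sensor types" objective was
considered as a third criterion and deliberately omitted: it is a global,
cross-output optimization that would couple otherwise independent outputs,
and for every design whose inventory this package reports (majority,
comparator, multiplexer) the minimal cover is already uniquely determined
by the first two criteria (all their covering primes are essential).
Multi-output functions are compiled fully independently per output — no
product-term sharing — each output receiving its own OL reporter type.

Degenerate inputs: a constant-0 output compiles to zero chambers (no
chamber ever fires); constant-1 to a single sensor-less chamber whose OL is
constitutively on (the NOR of nothing). Exact minimization is limited to
N ≤ 12; beyond that the search space makes the exact method inappropriate
and heuristic minimizers are out of scope.

## The readout

Integrated values map to ternary states: strictly above 60% positive cells
is 1, strictly below 20% is 0, the band between is *indeterminate* and is
counted as a verification failure rather than coerced — the architecture's
noise margins are supposed to keep signals out of that band, so entering it
is diagnostic. Transducer mode integrates an output's chambers by taking
the **highest** reporter value; buffer mode feeds the summed secreted β
through the buffer cell's steep activation curve, which saturates so the
readout is nearly independent of how many chambers fire. Because
verification compares states, any strictly increasing rescaling of the
readout (e.g. arbitrary fluorescence units instead of percent positive)
with correspondingly rescaled thresholds classifies identically; a property
test asserts this.

## Synthetic data generators

`fixtures` produces every input the test surface needs: random truth tables
(each minterm on independently with density 0.5 by default), dose–response
tables with **binomial counting noise** (10,000 cells per concentration,
matching flow-cytometry practice of percent-positive gating; no instrument
noise model), and parameter-jittered libraries (log-normal on K and n,
additive clamped noise on floors/ceilings) for robustness probing. All are
bit-reproducible from (seed, config). What passing tests on these fixtures
do *not* show: real transfer functions have asymmetric noise, day-to-day
drift, and growth-rate coupling between co-cultured strains; the generators
model none of that, so simulated verification is a necessary but not
sufficient indicator for wet-lab success.

## Problem sizes in the test suite

The exhaustive sweeps run at the sizes the properties demand: all 256
3-input functions are compiled and simulation-verified; all 65,536 4-input
functions are minimized to confirm the 2^(N−1) module bound (the bound is
attained, by parity); 200 random functions at N = 4–6 are verified under
the step-profile library; Hill recovery statistics use 100 seeds at 10,000
cells per point. The whole suite completes in well under a minute on one
core.

## Known limitations

- Buffer-mode basal accumulation for designs with ≳5 chambers (above).
- The crosstalk sweep reports a pass-rate curve; monotonicity in the
  crosstalk weight holds for the shipped libraries and circuits (and is
  tested there) but is not a theorem for arbitrary parameter sets.
- No don't-care minimization, multi-level synthesis, or heuristic covers
  for N > 12; no mechanistic pathway modelling behind the Hill curves.
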