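# Methods

## The model

`amoebacsp` simulates a constraint-satisfaction search inspired by the
spatiotemporal dynamics of a plasmodial amoeba. An `N`-variable problem
is represented by `2N` units, two per variable: unit `(i, 0)` asserts
`x_i = 0`, unit `(i, 1)` asserts `x_i = 1`. Each unit carries a
saturating accumulator `X ∈ {-1, 0, 1}` — an abstraction of the volume
displacement of one pseudopod-like branch. Per discrete step, each unit
independently receives a unit of resource (`R = 1`) with probability

```
p(s) = (1 - s) · p_free + s · p_blocked
```

where `s ∈ [0, 1]` is the unit's combined *bounceback signal*. The
accumulator rises by one on supply and falls by one otherwise, clamped
to `[-1, 1]`.

All constraint knowledge enters through **bounceback rules**
`condition ⇒ target`: when every condition unit is fully activated
(`X = 1`), the rule applies a blocking signal of per-rule-type intensity
to the target. Rules firing on the same target combine as a noisy-OR,
`s = 1 - Π(1 - intensity)`, which reduces to plain OR for binary
intensities. An empty condition is permitted and means unconditional
suppression; it arises for width-1 clauses and for bonds that the atom
arithmetic forces (see below).

The decoded assignment is sticky: `x_i` switches to `v` only when unit
`(i, v)` is fully activated while its opponent is at or below zero;
otherwise the previous value is kept. Update order within a step is
fully synchronous: signals from `X(t)`, then supply, then `X(t+1)`, then
decode.

### Stability

A state is *stable* when (a) every unit satisfies
`(X = 1 ∧ s = 0) ∨ (X ≤ 0 ∧ s > 0)`, and (b) every variable keeps at
least one fully activated unit. Condition (b) is deliberate: without
it, a variable whose two branches are both retracted-and-blocked would
count as stable even though the system asserts no value for it and the
decoder merely remembers a stale one — and such frustrated states do
occur dynamically (~5% of steps on the demo instance). With the
intra-variable exclusion rules in force, (a) + (b) jointly force exactly
one activated unit per variable, and a short argument shows stable
states decode exactly to constraint-satisfying assignments: if a clause
were fully violated, its violating units would all be activated, so its
rules would fire on activated units, contradicting (a). Under
fractional intensities, "blocked" in (a) means any positive signal; an
exactly-1 combined signal is a measure-zero event there.

### Metastable visits

A *visit* is logged when the decoded assignment satisfies the target
predicate and is unchanged for `stability_window` consecutive steps
(default 3). Dwell time is the full run of unchanged steps; transitions
are counted between consecutive visits of one chain. The window value
is a bookkeeping choice, not a dynamical parameter: 3 steps is long
enough to exclude single-step flickers and short enough not to censor
genuine short stays.

## SAT frontend

Each clause of width `k` compiles to `k` CLAUSE rules: for literal `ℓ`,
the condition is the set of units asserting all *other* literals
violated, the target is the unit asserting `ℓ` violated. Blocking the
last possible violation steers the search toward clause satisfaction
without global evaluation. Per variable, two CONTRA rules
`{(i, v)} ⇒ (i, 1-v)` make the branches mutually exclusive; without
them the system parks with both branches activated and the decoder
never commits (they are on by default, flag-disableable). A width-1
clause yields an unconditional block of its violating unit.

WalkSAT is implemented exactly as the pure random walk: pick a random
unsatisfied clause, flip a random variable in it. No greedy move, no
noise parameter, no restarts (a greedy-mix flag exists, off by
default). Iteration counting matches the comparison convention: one
WalkSAT flip, or one synchronous whole-system step of the amoeba
dynamics, is one iteration.

## Supply probabilities (calibration)

`p_free` and `p_blocked` are free parameters of the model — the
formulation only requires unblocked supply to be likely and blocked
supply unlikely. They are the noise calibration of the search, and
they matter: with `p_free = 0.99, p_blocked = 0.01` the
dynamics freeze in frustrated plateaus on 50-variable uniform random
3-SAT (a pilot run solved 0 of 30 trials in 10⁴ steps while the WalkSAT
baseline solved most), because fully activated branches almost never
release and contested variables stay locked down. A scan over
`(p_free, p_blocked)` on pilot instances shows a broad optimum around
`0.85–0.9 / 0.002–0.005`; the shipped defaults are `0.88 / 0.005`. The
`1 - p_free` dropout is the fluctuation that lets decisive branches
spontaneously release; the nonzero `p_blocked` lets blocked branches
occasionally defy suppression, which is what produces hops between
solutions. Both are configurable per run.

The chemistry frontend pins its own supply defaults at
`0.99 / 0.01` (`chem.chem_config`): there, exploration noise is meant
to enter through the continuous rule intensities — the frontend's
temperature knob — and near-deterministic supply keeps the intensity
regimes from being washed out by supply dropout. The SAT-calibrated
global defaults apply to the binary-intensity solver, where the rules
carry no tunable slack and supply noise is the only fluctuation
available.

At this desk scale (N = 50, m = 213, satisfiable instances) the
reconstruction and pure-walk WalkSAT are of comparable speed on typical
instances; the amoeba dynamics' advantage concentrates in the hard
tail, where its censoring rate is consistently lower, so its *mean*
iterations-to-solution is lower while pooled *medians* are close (and
can fall on either side on a given instance set). The dramatic
separation this family of algorithms is known for belongs to larger
instances, where a pure random walk degrades exponentially; reproducing
it is outside this package's desk-scale benchmark.

## Chemistry frontend

An atom multiset (H, O, N, C supported; valences 1, 2, 3, 4) compiles
to *bond slots*: every unordered atom pair gets
`min(valence_a, valence_b, 3)` slots, one per unit of bond order.
Each slot is one Boolean variable of the generic engine; molecules are
read off a slot assignment as connected components of the bond graph
(networkx), with formulas in Hill order and common display aliases
(NH3 for H3N).

Constraints compile to typed rules per atom `a` with valence `v` and
incident slot set `I(a)`:

- **OCTET_EXCESS** — for every `(v+1)`-subset `T ⊆ I(a)` and each
  `i ∈ T`: if the other slots of `T` are all bonded, block bonding
  `i` (caps bonds at `v`);
- **OCTET_DEFICIT** — for every `(|I(a)| - v + 1)`-subset `U` and each
  `i ∈ U`: if the other slots of `U` are all decisively open, block the
  open branch of `i` (forces bonds up to `v`); when `|I(a)| = v` this
  degenerates to an unconditional force on every incident slot;
- **SLOT_ORDER** — higher bond order only on top of lower (symmetry
  breaking between equivalent slots of one pair; flag-disableable);
- **CONTRA** — per-slot branch exclusion, as in SAT.

The octet rule is rendered as exact valence completion (bond count =
valence, lone pairs implicit); no charges, radicals, energies or 3-D
geometry. Composition identity is by formula multiset, so isomers with
identical component formulas merge.

`enumerate_valid_compositions` is an independent backtracking oracle
over slot assignments with remaining-valence and capacity pruning
(guarded at 12 atoms); it defines the support against which simulation
outputs are checked.

### First-found semantics

A chemistry trial starts from the neutral volume state (`X = 0`
everywhere) with the decoded assignment seeded by the initial
composition (realized canonically on the lowest slots) or drawn at
random. The trial's first-found state is the composition decoded at
the first step where the stability criterion holds and every atom's
valence is complete. Detection deliberately uses the stability
criterion rather than mere persistence of the decoded assignment: the
seeded assignment trivially persists from step 0 (both branches of
every slot saturate and the sticky decoder keeps it), so a
persistence-only rule would always report the seeding as its own
first-found state and the first-found distribution would degenerate.
A corollary: a trial seeded at a valence-complete composition still
has to stabilize dynamically before that composition can be its
first-found state.

### Intensity regimes

Chemistry rule intensities are continuous in `[0, 1]`; lowering them
injects fluctuation — the temperature analogy. Two named sets ship:
`tight` (all types 0.95) and `loose` (all types 0.60). The pair was
chosen because a uniform lowering measurably reshapes the first-found
distribution on the 2 N + 4 H system, whereas lowering only the
OCTET_DEFICIT intensity (an alternative considered) changes how fast
trials complete but not the composition mix. The sets are this
package's own choice and demonstrate the qualitative effect of the
temperature knob, not any specific target frequencies.

## Problem sizes and numerical choices

- Benchmark: 20 satisfiable uniform random 3-SAT instances at `N = 50`,
  `m = 213` (the SATLIB phase-transition ratio 4.26), 100 trials per
  instance per algorithm, step budget 5 × 10⁴; censored trials enter
  means at the budget value and are flagged. Satisfiability screening
  uses an internal DPLL check (generation is rejection sampling, ~2×).
- Long-run statistics on the demo instance: 500 chains × 10⁴ steps
  (5 × 10⁶ aggregated steps) for stable-state purity, solution
  reachability and transition ordering.
- Chemistry contrast: 500 trials per intensity set, 3 × 10³ step budget
  (typical first-find is at a few hundred steps).
- Rule evaluation is dense float32 matrix algebra over the condition
  and target incidence matrices; the binary-intensity case takes an
  exact boolean path, so `s = 0` and `s = 1` are exact there. In the
  fractional case the noisy-OR is computed in log space with exact-1
  intensities split out, so `s = 1` remains exact.
- Octet-rule compilation is guarded at 16 incident slots per atom
  (subset growth); brute-force SAT enumeration at 24 variables.

## Known limitations

- Bounceback conditions are evaluated on the accumulators `X`, the
  formulation this package implements. Width-1 clauses aside, a formula whose
  satisfaction hinges on unit clauses has stable states only at
  solutions of the remaining clauses conditioned on those forces.
- The bundled demonstration experiments use two related but distinct
  stoichiometries (2 N + 4 H for the first-found distribution, 2 N + 6 H
  for the worked molecule tables); a 2 NH3 state is unreachable from
  2 N + 4 H, so the two experiments are not interchangeable.
- The generator emulates the uniform random 3-SAT class only; real
  SATLIB files can be benchmarked via `--dimacs-dir` but are not
  bundled.
- Passing the chemistry tests shows the constraint compiler and
  dynamics are consistent with the valence oracle on small inorganic
  systems; it says nothing about real reaction thermodynamics or rates.
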