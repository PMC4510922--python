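# amoebacsp

Amoeba-inspired, bounceback-controlled stochastic search for constraint
satisfaction, with two frontends:

- **SAT** — a concurrent stochastic local-search solver for Boolean
  satisfiability (DIMACS CNF in), with a pure random-walk WalkSAT
  baseline and a uniform random 3-SAT benchmark harness;
- **Chemistry** — exploration of metastable molecules for a small atom
  multiset under valence (octet-rule) constraints, with first-found
  distributions and composition-to-composition transition statistics.

The package is for people studying heuristic search dynamics and
chemical reaction-path exploration at the level of toy models: it
treats a molecule as a constraint-satisfying fixed point and reaction
paths as stochastic hops between metastable states.

## The model in brief

An `N`-variable problem is searched by `2N` units, two per variable
(`(i, v)` asserts `x_i = v`), each with a saturating accumulator
`X_{i,v} ∈ {-1, 0, 1}`. Per step, unit `(i, v)` receives a resource
(`R_{i,v} = 1`) with probability

  p(s) = (1 − s) · p_free + s · p_blocked,

where `s ∈ [0, 1]` is the unit's combined **bounceback signal**:
constraints compile to rules *condition ⇒ target* that block the target
unit with a per-rule-type intensity whenever every condition unit has
`X = 1`; simultaneous rules combine as a noisy-OR. `X` rises on supply
and falls otherwise; the assignment decodes as `x_i = v` when `(i, v)`
is fully activated and its opponent is at or below zero, keeping the
previous value otherwise. A clause like `(¬x₁ ∨ x₃ ∨ ¬x₄)` yields
rules such as `X_{1,1}=1 ∧ X_{3,0}=1 ⇒ block (4,1)`: if the other two
literals are violated, the last possible violation is suppressed. A
state in which every activated unit is unblocked and every retracted
unit is blocked is *stable* — and stable states decode exactly to
constraint-satisfying assignments. Because the blocking is
probabilistic, the system does not halt at the first solution: it dwells
there and occasionally hops to other solutions, preferring
single-bit-flip hops.

## Worked example

The bundled 4-variable, 9-clause demo instance has exactly three
solutions. Solve it, list them, and watch the metastable hopping:

```
$ amoeba sat-solve demo.cnf --seed 1
s SATISFIABLE after 67 steps (seed 1)
v -1 2 3 -4

$ amoeba sat-solve demo.cnf --list-solutions
s 3 solutions
v -1 2 3 -4
v 1 2 3 -4
v 1 2 3 4

$ amoeba transitions demo.cnf --steps 10000 --chains 20 --seed 1
dwell totals over 200020 aggregated steps:
  0110: 58020
  1110: 57193
  1111: 56898
empirical transition probabilities:
       0110   1110   1111
0110  0.057  0.852  0.091
1110  0.463  0.044  0.493
1111  0.084  0.808  0.108
counts -> transitions.csv
```

(`demo.cnf` is `write_dimacs(example_formula())`; any DIMACS file
works.) The solve run reports the first verified solution and the step
at which it was found. The dwell/transition table shows the dynamics
holding each of the three solutions for long stretches and hopping
between them: from solution `1111` the hop to `1110` (one bit flip,
probability 0.808) is about ten times likelier than to `0110` (two
simultaneous flips, 0.084).

Chemistry: feed two nitrogens and six hydrogens and ask what molecules
form; the valence oracle for this multiset contains exactly four
compositions (N₂ + 3 H₂, N₂H₂ + 2 H₂, N₂H₄ + H₂, 2 NH₃):

```
$ amoeba chem-run --atoms "N:2,H:6" --trials 200 --seed 0 --out dist.csv
first-found distribution over 200 trials -> dist.csv
  N2H4 + H2                 106  (53.0%)
  N2H2 + 2 H2                62  (31.0%)
  2 NH3                      29  (14.5%)
  N2 + 3 H2                   3  (1.5%)
```

Every reported composition satisfies the valence of all eight atoms;
the frequencies say which metastable molecule the dynamics stabilizes
in first, starting from free atoms with random initial bonding bias.

Two intensity parameter sets ship (`tight`, all rule types 0.95, and
`loose`, all 0.60 — lowering intensities raises the effective
temperature); their first-found distributions differ measurably —
the distribution of metastable molecules the search stabilizes in
first is itself a function of the blocking intensities.

## Benchmarking against WalkSAT

```
amoeba benchmark --n 50 --instances 20 --trials 100 --budget 50000 --seed 1 --out bench.csv
```

generates satisfiable uniform random 3-SAT instances at the
phase-transition ratio (m = 4.26 n), runs the amoeba dynamics and pure
random-walk WalkSAT 100 times each per instance, and reports
mean/median iterations-to-solution (one WalkSAT flip or one synchronous
whole-system amoeba step = one iteration; censored trials count at the
budget). See `docs/methods.md` for what to expect at this scale.

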