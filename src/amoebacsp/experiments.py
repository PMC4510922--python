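"""Monte Carlo harnesses: solver benchmarking and solution-transition statistics.

Two experiment shapes, both deterministic given their seed:

* iterations-to-solution comparison between the bounceback dynamics and
  the pure-walk WalkSAT baseline on uniform random 3-SAT instances;
* long-run segmentation of a multi-solution instance's trajectory into
  metastable solution visits, with dwell totals and an empirical
  transition-probability matrix between solutions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import SolverConfig, bits_label, simulate
from .sat import (
    CNFFormula,
    brute_force_solutions,
    compile_bounceback_rules,
    generate_uniform_3sat,
    verify,
)
from .walksat import walksat_run_batch

__all__ = [
    "BINARY_INTENSITIES",
    "run_amoebasat_batch",
    "make_benchmark_instances",
    "run_benchmark",
    "summarize_benchmark",
    "TransitionSummary",
    "transition_analysis",
]

#: SAT frontend default: fully binary blocking, as in the original
#: Boolean formulation.
BINARY_INTENSITIES = {"CLAUSE": 1.0, "CONTRA": 1.0}

DEFAULT_BUDGET = 50_000


def run_amoebasat_batch(
    formula: CNFFormula,
    max_steps: int,
    n_chains: int,
    seed: int | np.random.Generator = 0,
    config: SolverConfig | None = None,
    intensities: Mapping[str, float] | None = None,
):
    """Batched bounceback-dynamics solver runs on one instance.

    Returns ``(solved, iterations, assignments)`` shaped like
    :func:`amoebacsp.walksat.walksat_run_batch`, with censored chains
    reporting ``iterations = max_steps``.
    """
    if config is None:
        config = SolverConfig()
    if intensities is None:
        intensities = BINARY_INTENSITIES
    rules = compile_bounceback_rules(formula)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rec = simulate(
        rules,
        intensities,
        config,
        formula.n_vars,
        n_chains=n_chains,
        rng=rng,
        target=formula.satisfies,
        stop_on_target=True,
        max_steps=max_steps,
    )
    solved = rec.first_hit_step >= 0
    iterations = rec.first_hit_step.copy()
    iterations[~solved] = max_steps
    for b in np.nonzero(solved)[0]:
        assert verify(formula, rec.first_hit_assignment[b])
    return solved, iterations, rec.first_hit_assignment


def make_benchmark_instances(
    n_instances: int,
    n_vars: int,
    n_clauses: int | None = None,
    seed: int = 0,
) -> list[CNFFormula]:
    """Generate satisfiability-screened uniform random 3-SAT instances."""
    rng = np.random.default_rng(seed)
    return [
        generate_uniform_3sat(n_vars, n_clauses, seed=rng, require_satisfiable=True)
        for _ in range(n_instances)
    ]


def run_benchmark(
    instances: Sequence[CNFFormula],
    algorithms: Sequence[str] = ("amoebasat", "walksat"),
    trials: int = 100,
    budget: int = DEFAULT_BUDGET,
    seed: int = 0,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Full-factorial instances x algorithms x trials iteration counts.

    One row per trial with the instance id, algorithm, trial index,
    derived seed, solved flag and iterations-to-solution (censored
    trials report the budget and ``solved = False``).  Reproducible from
    ``seed``: per-(instance, algorithm) streams come from spawned
    children of one seed sequence.
    """
    known = {"amoebasat", "walksat"}
    bad = set(algorithms) - known
    if bad:
        raise ValueError(f"unknown algorithm(s): {sorted(bad)}; known: {sorted(known)}")
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(instances) * len(algorithms))
    k = 0
    for inst_id, formula in enumerate(instances):
        for algo in algorithms:
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            if algo == "amoebasat":
                solved, iters, _ = run_amoebasat_batch(
                    formula, budget, trials, seed=rng, config=config
                )
            else:
                solved, iters, _ = walksat_run_batch(formula, budget, trials, seed=rng)
            for trial in range(trials):
                rows.append(
                    {
                        "instance": inst_id,
                        "algorithm": algo,
                        "trial": trial,
                        "seed": seed,
                        "stream": k - 1,
                        "solved": bool(solved[trial]),
                        "iterations": int(iters[trial]),
                        "budget": budget,
                    }
                )
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Per-algorithm mean/median iterations (censored trials at budget)."""
    return (
        results.groupby("algorithm")
        .agg(
            mean_iterations=("iterations", "mean"),
            median_iterations=("iterations", "median"),
            solved_rate=("solved", "mean"),
            censored=("solved", lambda s: int((~s).sum())),
            trials=("solved", "size"),
        )
        .reset_index()
    )


@dataclass
class TransitionSummary:
    """Empirical metastable-solution statistics from long trajectories."""

    solutions: list            # bit-string labels
    dwell: dict                # label -> total dwell steps
    counts: pd.DataFrame       # transition counts, rows = from, cols = to
    probabilities: pd.DataFrame  # row-normalised counts
    total_steps: int
    n_chains: int
    visits: int


def transition_analysis(
    formula: CNFFormula,
    config: SolverConfig | None = None,
    run_length: int = 20_000,
    n_chains: int = 50,
    seed: int = 0,
    intensities: Mapping[str, float] | None = None,
) -> TransitionSummary:
    """Segment long runs into solution visits and estimate transitions.

    Requires an instance with at least two solutions (oracle-checked for
    up to 24 variables).  The visit rule: a satisfying decoded
    assignment unchanged for ``config.stability_window`` consecutive
    steps is a visit; transitions are counted between consecutive visits
    of each chain.
    """
    if config is None:
        config = SolverConfig(seed=seed)
    if intensities is None:
        intensities = BINARY_INTENSITIES
    if formula.n_vars <= 24:
        sols = brute_force_solutions(formula)
        if len(sols) < 2:
            raise ValueError(
                f"transition analysis needs >= 2 solutions, instance has {len(sols)}"
            )
        labels = sorted(bits_label(s) for s in sols)
    else:
        labels = None
    rules = compile_bounceback_rules(formula)
    rng = np.random.default_rng(seed)
    rec = simulate(
        rules,
        intensities,
        config,
        formula.n_vars,
        n_chains=n_chains,
        rng=rng,
        target=formula.satisfies,
        track_visits=True,
        stop_on_target=False,
        max_steps=run_length,
    )
    dwell: Counter = Counter()
    for v in rec.visits:
        dwell[bits_label(v.state)] += v.dwell
    seen = sorted(dwell)
    if labels is None:
        labels = seen
    else:
        labels = sorted(set(labels) | set(seen))
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=np.int64)
    for (a, b), n in rec.transitions.items():
        counts.loc[bits_label(a), bits_label(b)] += n
    departures = counts.sum(axis=1)
    probs = counts.div(departures.replace(0, np.nan), axis=0).fillna(0.0)
    return TransitionSummary(
        solutions=labels,
        dwell=dict(dwell),
        counts=counts,
        probabilities=probs,
        total_steps=rec.total_steps,
        n_chains=n_chains,
        visits=len(rec.visits),
    )
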