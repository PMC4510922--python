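"""Pure random-walk WalkSAT baseline.

Each iteration picks one unsatisfied clause uniformly at random and flips
one variable of that clause, again uniformly at random.  This is the
pure-walk variant with no greedy break-count move and no noise
parameter; an optional greedy mix exists behind a flag but is off by
default, since the benchmark comparison is against the plain walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sat import CNFFormula, verify

__all__ = ["WalkSATState", "WalkSATResult", "walksat_step", "walksat_run", "walksat_run_batch"]


@dataclass
class WalkSATState:
    assignment: np.ndarray  # (N,) uint8
    flips: int = 0


@dataclass
class WalkSATResult:
    solved: bool
    flips: int
    assignment: np.ndarray


def _unsatisfied_clauses(formula: CNFFormula, assignment: np.ndarray) -> np.ndarray:
    return np.nonzero(~formula.clause_satisfaction(assignment))[0]


def walksat_step(
    formula: CNFFormula,
    state: WalkSATState,
    rng: np.random.Generator,
    greedy_prob: float = 0.0,
) -> tuple[WalkSATState, int | None]:
    """One flip; returns (new state, flipped variable index).

    Called on a satisfying assignment it is a no-op, signalled by a
    ``None`` flipped variable and an unchanged flip counter.

    ``greedy_prob`` mixes in a classic greedy move (flip the variable of
    the chosen clause that breaks the fewest clauses) with the given
    probability; the default 0.0 is the pure random walk.
    """
    unsat = _unsatisfied_clauses(formula, state.assignment)
    if unsat.size == 0:
        return state, None
    clause = formula.clauses[int(rng.choice(unsat))]
    if greedy_prob > 0.0 and rng.random() < greedy_prob:
        best_var, best_broken = None, None
        for lit in clause:
            cand = state.assignment.copy()
            cand[lit.variable_index - 1] ^= 1
            broken = int((~formula.clause_satisfaction(cand)).sum())
            if best_broken is None or broken < best_broken:
                best_var, best_broken = lit.variable_index, broken
        var = best_var
    else:
        var = clause[int(rng.integers(len(clause)))].variable_index
    new_assignment = state.assignment.copy()
    new_assignment[var - 1] ^= 1
    return WalkSATState(new_assignment, state.flips + 1), var


def walksat_run(
    formula: CNFFormula,
    max_flips: int,
    seed: int | np.random.Generator = 0,
    greedy_prob: float = 0.0,
) -> WalkSATResult:
    """Random init, then iterate flips until satisfied or budget."""
    if max_flips < 1:
        raise ValueError("max_flips must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = WalkSATState(rng.integers(0, 2, size=formula.n_vars).astype(np.uint8))
    while state.flips < max_flips:
        state, var = walksat_step(formula, state, rng, greedy_prob)
        if var is None:
            break
    solved = bool(formula.satisfies(state.assignment))
    if solved:
        assert verify(formula, state.assignment)
    return WalkSATResult(solved, state.flips, state.assignment)


def walksat_run_batch(
    formula: CNFFormula,
    max_flips: int,
    n_chains: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run many independent pure-walk chains in lock-step.

    Returns ``(solved, flips, assignments)`` with shapes (B,), (B,) and
    (B, N); censored chains report ``flips = max_flips``.  Equivalent in
    distribution to ``n_chains`` calls of :func:`walksat_run` but orders
    of magnitude faster.
    """
    if max_flips < 1:
        raise ValueError("max_flips must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B, N, M = n_chains, formula.n_vars, formula.n_clauses
    assign = rng.integers(0, 2, size=(B, N), dtype=np.int64).astype(np.uint8)
    vars0, _ = formula._eval_arrays()
    widths = np.array([len(cl) for cl in formula.clauses], dtype=np.int64)
    solved = np.zeros(B, dtype=bool)
    flips = np.zeros(B, dtype=np.int64)

    if M == 0:
        return np.ones(B, dtype=bool), flips, assign

    for _ in range(max_flips):
        unsat = ~formula.clause_satisfaction(assign)  # (B, M)
        counts = unsat.sum(axis=1)
        solved |= counts == 0
        active = ~solved
        if not active.any():
            break
        # pick the (idx+1)-th unsatisfied clause per chain
        r = rng.random(B)
        idx = np.floor(r * np.maximum(counts, 1)).astype(np.int64)
        cs = unsat.cumsum(axis=1)
        clause_idx = (cs <= idx[:, None]).sum(axis=1)
        clause_idx = np.minimum(clause_idx, M - 1)
        k = np.floor(rng.random(B) * widths[clause_idx]).astype(np.int64)
        var0 = vars0[clause_idx, k]
        rows = np.nonzero(active)[0]
        assign[rows, var0[rows]] ^= 1
        flips[rows] += 1

    solved |= formula.satisfies(assign)
    flips[~solved] = max_flips
    return solved, flips, assign
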