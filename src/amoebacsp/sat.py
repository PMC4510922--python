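"""SAT frontend: CNF handling, clause-to-bounceback compilation, oracles.

A clause is violated only when every one of its literals is violated, so
each literal yields one bounceback rule: *if the units asserting all the
other literals violated are fully activated, suppress the unit that would
violate this literal too*.  Blocking the last possible violation steers
the concurrent dynamics toward clause satisfaction without ever
evaluating the formula globally.

Besides the compiler this module carries the plumbing a SAT frontend
needs: a DIMACS reader/writer, a brute-force solution oracle for small
instances, a uniform random 3-SAT generator for benchmarking, and a
minimal DPLL satisfiability check used only to screen generated
instances (it is not a solving frontend).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    RULE_CLAUSE,
    RULE_CONTRA,
    BouncebackRule,
    UnitId,
    pack_bits,
)

__all__ = [
    "Literal",
    "Clause",
    "CNFFormula",
    "DimacsError",
    "parse_dimacs",
    "write_dimacs",
    "compile_bounceback_rules",
    "verify",
    "brute_force_solutions",
    "generate_uniform_3sat",
    "example_formula",
    "EXAMPLE_SOLUTIONS",
]

#: SATLIB phase-transition clause/variable ratio for uniform random 3-SAT.
PHASE_TRANSITION_RATIO = 4.26

BRUTE_FORCE_MAX_VARS = 24


@dataclass(frozen=True, order=True)
class Literal:
    variable_index: int
    negated: bool

    def __post_init__(self) -> None:
        if self.variable_index < 1:
            raise ValueError("variable_index must be >= 1")

    @property
    def satisfying_value(self) -> int:
        """The variable value that makes this literal true."""
        return 0 if self.negated else 1

    @property
    def violating_unit(self) -> UnitId:
        """The unit asserting the value that falsifies this literal."""
        return UnitId(self.variable_index, 1 - self.satisfying_value)

    @staticmethod
    def from_dimacs(code: int) -> "Literal":
        if code == 0:
            raise ValueError("0 is the DIMACS clause terminator, not a literal")
        return Literal(abs(code), code < 0)

    def to_dimacs(self) -> int:
        return -self.variable_index if self.negated else self.variable_index


Clause = tuple  # tuple[Literal, ...]


def _clause(*codes: int) -> Clause:
    return tuple(Literal.from_dimacs(c) for c in codes)


@dataclass(frozen=True)
class CNFFormula:
    """A CNF formula over variables 1..n_vars."""

    n_vars: int
    clauses: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "clauses", tuple(tuple(cl) for cl in self.clauses))
        for cl in self.clauses:
            if len(cl) == 0:
                raise ValueError("empty clause is unsatisfiable and not representable")
            for lit in cl:
                if lit.variable_index > self.n_vars:
                    raise ValueError(
                        f"literal on x{lit.variable_index} exceeds n_vars={self.n_vars}"
                    )

    @property
    def n_clauses(self) -> int:
        return len(self.clauses)

    def _eval_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Padded (M, K) arrays of 0-based variable ids and satisfying values.

        Padding entries use satisfying value 2, which never matches.
        """
        if not hasattr(self, "_arrays"):
            K = max((len(cl) for cl in self.clauses), default=1)
            M = len(self.clauses)
            vars0 = np.zeros((M, K), dtype=np.int64)
            vals = np.full((M, K), 2, dtype=np.int64)
            for m, cl in enumerate(self.clauses):
                for k, lit in enumerate(cl):
                    vars0[m, k] = lit.variable_index - 1
                    vals[m, k] = lit.satisfying_value
            object.__setattr__(self, "_arrays", (vars0, vals))
        return self._arrays

    def clause_satisfaction(self, assignment: np.ndarray) -> np.ndarray:
        """Boolean clause-satisfaction matrix for (..., N) assignments."""
        a = np.asarray(assignment)
        vars0, vals = self._eval_arrays()
        if self.n_clauses == 0:
            return np.ones(a.shape[:-1] + (0,), dtype=bool)
        return (a[..., vars0] == vals).any(axis=-1)

    def satisfies(self, assignment: np.ndarray) -> np.ndarray:
        """Vectorised formula evaluation for (..., N) assignments."""
        return self.clause_satisfaction(assignment).all(axis=-1)

    def to_dimacs_codes(self) -> list[list[int]]:
        return [[lit.to_dimacs() for lit in cl] for cl in self.clauses]


class DimacsError(ValueError):
    """Malformed DIMACS CNF input."""


def parse_dimacs(text: str) -> CNFFormula:
    """Parse DIMACS CNF text.

    Accepts ``c`` comment lines, a single ``p cnf N M`` header, clauses
    terminated by ``0`` (possibly spanning lines), and the SATLIB
    convention of a trailing ``%`` end-of-file marker.  Duplicate
    literals in a clause are deduplicated; a tautological clause
    (``x`` and ``not x``) is dropped with a warning.
    """
    n_vars = None
    n_clauses_declared = None
    clauses: list[Clause] = []
    pending: list[int] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("c"):
            continue
        if line.startswith("%"):
            break
        if line.startswith("p"):
            if n_vars is not None:
                raise DimacsError(f"line {lineno}: duplicate problem header")
            parts = line.split()
            if len(parts) != 4 or parts[1] != "cnf":
                raise DimacsError(f"line {lineno}: malformed header {line!r}")
            try:
                n_vars, n_clauses_declared = int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise DimacsError(f"line {lineno}: malformed header {line!r}") from exc
            if n_vars < 1:
                raise DimacsError(f"line {lineno}: header declares {n_vars} variables")
            continue
        if n_vars is None:
            raise DimacsError(f"line {lineno}: clause before 'p cnf' header")
        for tok in line.split():
            try:
                code = int(tok)
            except ValueError as exc:
                raise DimacsError(f"line {lineno}: bad token {tok!r}") from exc
            if code == 0:
                if not pending:
                    raise DimacsError(f"line {lineno}: empty clause")
                codes = list(dict.fromkeys(pending))  # dedupe, keep order
                variables = [abs(c) for c in codes]
                if len(set(variables)) < len(variables):
                    warnings.warn(
                        f"line {lineno}: tautological clause dropped: {pending}",
                        stacklevel=2,
                    )
                else:
                    clauses.append(_clause(*codes))
                pending = []
            else:
                if abs(code) > n_vars:
                    raise DimacsError(
                        f"line {lineno}: literal {code} exceeds declared {n_vars} variables"
                    )
                pending.append(code)
    if pending:
        raise DimacsError("unterminated clause at end of input (missing trailing 0)")
    if n_vars is None:
        raise DimacsError("missing 'p cnf' header")
    if n_clauses_declared is not None and n_clauses_declared != len(clauses):
        warnings.warn(
            f"header declares {n_clauses_declared} clauses, parsed {len(clauses)}",
            stacklevel=2,
        )
    return CNFFormula(n_vars, tuple(clauses))


def write_dimacs(formula: CNFFormula, comment: str | None = None) -> str:
    lines = []
    if comment:
        lines.extend(f"c {ln}" for ln in comment.splitlines())
    lines.append(f"p cnf {formula.n_vars} {formula.n_clauses}")
    for codes in formula.to_dimacs_codes():
        lines.append(" ".join(str(c) for c in codes) + " 0")
    return "\n".join(lines) + "\n"


def compile_bounceback_rules(
    formula: CNFFormula, include_contra: bool = True
) -> list[BouncebackRule]:
    """Compile a CNF formula into bounceback rules.

    For each clause and each literal in it: condition = the violating
    units of all *other* literals, target = the violating unit of this
    literal (type CLAUSE).  A width-1 clause degenerates to an
    unconditional (empty-condition) suppression of its violating unit.

    With ``include_contra``, each variable also gets the two
    intra-variable exclusion rules ``{(i,v)} => (i,1-v)`` (type CONTRA)
    so the opposing branches suppress each other; without them the
    system can park with both branches of a variable fully activated and
    never commit to a value.
    """
    rules: list[BouncebackRule] = []
    for cl in formula.clauses:
        units = [lit.violating_unit for lit in cl]
        for k in range(len(cl)):
            condition = frozenset(units[:k] + units[k + 1:])
            rules.append(BouncebackRule(condition, units[k], RULE_CLAUSE))
    if include_contra:
        for i in range(1, formula.n_vars + 1):
            for v in (0, 1):
                rules.append(
                    BouncebackRule(frozenset({UnitId(i, v)}), UnitId(i, 1 - v), RULE_CONTRA)
                )
    return rules


def _coerce_assignment(formula: CNFFormula, assignment) -> np.ndarray:
    if isinstance(assignment, Mapping):
        missing = [i for i in range(1, formula.n_vars + 1) if i not in assignment]
        if missing:
            raise ValueError(f"assignment missing variables {missing}")
        return np.array([assignment[i] for i in range(1, formula.n_vars + 1)], dtype=np.uint8)
    a = np.asarray(assignment, dtype=np.uint8)
    if a.shape != (formula.n_vars,):
        raise ValueError(f"assignment must cover all {formula.n_vars} variables")
    return a


def verify(formula: CNFFormula, assignment) -> bool:
    """True iff every clause has at least one satisfied literal."""
    return bool(formula.satisfies(_coerce_assignment(formula, assignment)))


def brute_force_solutions(formula: CNFFormula) -> set:
    """All satisfying assignments, as tuples of bits, by exhaustive search.

    Guarded at 24 variables; the space doubles with every variable.
    """
    N = formula.n_vars
    if N > BRUTE_FORCE_MAX_VARS:
        raise ValueError(
            f"brute force refused for n_vars={N} > {BRUTE_FORCE_MAX_VARS}"
        )
    sols: set = set()
    total = 1 << N
    chunk = 1 << 16
    shifts = np.arange(N, dtype=np.int64)
    for start in range(0, total, chunk):
        ints = np.arange(start, min(start + chunk, total), dtype=np.int64)
        bits = ((ints[:, None] >> shifts) & 1).astype(np.uint8)
        mask = formula.satisfies(bits)
        for row in bits[mask]:
            sols.add(tuple(int(b) for b in row))
    return sols


# ---------------------------------------------------------------------------
# DPLL satisfiability screen (internal; instance generation only)

def _dpll_satisfiable(formula: CNFFormula) -> bool:
    clauses = [frozenset(l.to_dimacs() for l in cl) for cl in formula.clauses]

    def solve(clauses: list, assignment: dict) -> bool:
        # unit propagation
        while True:
            unit = next((next(iter(c)) for c in clauses if len(c) == 1), None)
            if unit is None:
                break
            clauses = _assign(clauses, unit)
            if clauses is None:
                return False
        if not clauses:
            return True
        # branch on the most frequent literal
        counts: dict[int, int] = {}
        for c in clauses:
            for lit in c:
                counts[lit] = counts.get(lit, 0) + 1
        lit = max(counts, key=counts.get)
        for choice in (lit, -lit):
            reduced = _assign(clauses, choice)
            if reduced is not None and solve(reduced, assignment):
                return True
        return False

    def _assign(clauses: list, lit: int):
        out = []
        for c in clauses:
            if lit in c:
                continue
            if -lit in c:
                c = c - {-lit}
                if not c:
                    return None
            out.append(c)
        return out

    return solve(clauses, {})


def generate_uniform_3sat(
    n_vars: int,
    n_clauses: int | None = None,
    seed: int | np.random.Generator = 0,
    require_satisfiable: bool = False,
    max_attempts: int = 1000,
) -> CNFFormula:
    """Draw a uniform random 3-SAT instance.

    Every clause takes three distinct variables uniformly at random,
    each with uniform polarity.  ``n_clauses`` defaults to
    ``round(4.26 * n_vars)``, the phase-transition ratio of the SATLIB
    uniform random 3-SAT benchmark class.  With ``require_satisfiable``
    instances are rejection-sampled until a complete check (brute force
    at small N, DPLL otherwise) confirms satisfiability.
    """
    if n_vars < 3:
        raise ValueError("uniform 3-SAT needs at least 3 variables")
    M = int(round(PHASE_TRANSITION_RATIO * n_vars)) if n_clauses is None else int(n_clauses)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_attempts):
        clauses = []
        for _ in range(M):
            variables = rng.choice(n_vars, size=3, replace=False) + 1
            signs = rng.integers(0, 2, size=3)
            clauses.append(
                tuple(Literal(int(v), bool(s)) for v, s in zip(variables, signs))
            )
        formula = CNFFormula(n_vars, tuple(clauses))
        if not require_satisfiable:
            return formula
        if n_vars <= BRUTE_FORCE_MAX_VARS:
            if brute_force_solutions(formula):
                return formula
        elif _dpll_satisfiable(formula):
            return formula
    raise RuntimeError(
        f"no satisfiable instance found in {max_attempts} attempts "
        f"(n_vars={n_vars}, n_clauses={M})"
    )


# ---------------------------------------------------------------------------
# The worked 4-variable example instance

#: Its three satisfying assignments (x1, x2, x3, x4).
EXAMPLE_SOLUTIONS = {(1, 1, 1, 1), (1, 1, 1, 0), (0, 1, 1, 0)}


def example_formula() -> CNFFormula:
    """The 9-clause, 4-variable demo instance with exactly three solutions.

    (1,1,1,1), (1,1,1,0) and (0,1,1,0) satisfy it; it is small enough to
    enumerate yet has several solutions at Hamming distances 1 and 2 of
    each other, which makes it the standard instance for watching the
    dynamics hop between metastable solutions.
    """
    return CNFFormula(
        4,
        (
            _clause(-1, 3, -4),
            _clause(1, -2, 3),
            _clause(1, 2, 3),
            _clause(1, 2, 4),
            _clause(1, -3, -4),
            _clause(-2, 3, 4),
            _clause(2, -3, -4),
            _clause(2, -3, 4),
            _clause(2, 3, 4),
        ),
    )
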