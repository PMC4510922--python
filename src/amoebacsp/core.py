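"""Bounceback-controlled concurrent stochastic search dynamics.

An ``N``-variable constraint problem is searched by a coupled system of
``2N`` units, two per variable: unit ``(i, 0)`` asserts ``x_i = 0`` and
unit ``(i, 1)`` asserts ``x_i = 1``.  Each unit carries a saturating
accumulator ``X in {-1, 0, 1}`` (an abstraction of the volume displacement
of a pseudopod-like branch of an amoeboid cell).  At every discrete step
each unit independently receives a unit of resource with high probability
``p_free`` — unless one or more *bounceback rules* fire against it, in
which case the supply probability is pulled down toward ``p_blocked``.

A bounceback rule is a conditional suppression: when every unit in its
condition set is fully activated (``X = 1``), the rule applies a blocking
signal of a per-rule-type intensity in ``[0, 1]`` to its target unit.
Constraint knowledge enters the dynamics *only* through these rules; the
rest of the machinery is problem-agnostic, which is what lets the same
engine run Boolean satisfiability and valence-rule chemistry unchanged.

Multiple rules firing on one target combine as a noisy-OR:
``s = 1 - prod(1 - intensity_r)``.  With all intensities at 1.0 this
reduces to a plain OR and the dynamics are the binary ones of the original
SAT formulation; fractional intensities leave a residual supply
probability on blocked units, which acts like a temperature.

All randomness flows through a single :class:`numpy.random.Generator`;
fixing the seed fixes every trajectory bit for bit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "UnitId",
    "BouncebackRule",
    "SolverConfig",
    "UnitState",
    "RuleSet",
    "ConfigurationError",
    "compute_signals",
    "supply_resources",
    "update_X",
    "decode_assignment",
    "is_stable",
    "step",
    "run",
    "simulate",
    "Visit",
    "TrajectoryRecord",
    "pack_bits",
    "unpack_bits",
]


class ConfigurationError(ValueError):
    """Raised when rules, intensities and state do not fit together."""


@dataclass(frozen=True, order=True)
class UnitId:
    """One of the 2N units: ``(variable_index, value_tag)``.

    ``variable_index`` is 1-based; ``value_tag`` is the Boolean value the
    unit asserts for that variable.
    """

    variable_index: int
    value_tag: int

    def __post_init__(self) -> None:
        if self.variable_index < 1:
            raise ValueError(f"variable_index must be >= 1, got {self.variable_index}")
        if self.value_tag not in (0, 1):
            raise ValueError(f"value_tag must be 0 or 1, got {self.value_tag}")

    @property
    def index(self) -> int:
        """Flat position in unit-vector order: (1,0), (1,1), (2,0), ..."""
        return 2 * (self.variable_index - 1) + self.value_tag

    @staticmethod
    def from_index(k: int) -> "UnitId":
        return UnitId(k // 2 + 1, k & 1)

    def opposite(self) -> "UnitId":
        return UnitId(self.variable_index, 1 - self.value_tag)


@dataclass(frozen=True)
class BouncebackRule:
    """Conditional suppression: if all condition units have X=1, block target.

    An *empty* condition means the rule always fires (unconditional
    suppression); this encodes width-1 clauses and forced bonds.
    """

    condition: frozenset
    target: UnitId
    rule_type: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", frozenset(self.condition))
        if self.target in self.condition:
            raise ValueError("rule target may not appear in its own condition")

    def fires(self, X: Mapping[UnitId, int] | np.ndarray) -> bool:
        if isinstance(X, np.ndarray):
            return all(X[u.index] == 1 for u in self.condition)
        return all(X[u] == 1 for u in self.condition)


# Rule-type labels used by the two frontends.
RULE_CLAUSE = "CLAUSE"
RULE_CONTRA = "CONTRA"
RULE_OCTET_EXCESS = "OCTET_EXCESS"
RULE_OCTET_DEFICIT = "OCTET_DEFICIT"
RULE_SLOT_ORDER = "SLOT_ORDER"


@dataclass(frozen=True)
class SolverConfig:
    """Global dynamics parameters.

    p_free
        Resource-supply probability for an unblocked unit.  High, so
        unblocked branches elongate on most steps — but deliberately
        short of certainty: the 1 - p_free dropout is the fluctuation
        that lets fully activated branches spontaneously release, which
        is what keeps the concurrent search from freezing in frustrated
        configurations.
    p_blocked
        Supply probability for a fully blocked unit (signal 1.0).  Small
        but nonzero, so blocked branches occasionally defy the
        suppression and the system can hop between solutions.
    stability_window
        Number of consecutive steps a constraint-satisfying decoded
        assignment must persist to be logged as a metastable-state visit.
    """

    p_free: float = 0.88
    p_blocked: float = 0.005
    max_steps: int = 10_000
    seed: int = 0
    stability_window: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_blocked < self.p_free <= 1.0):
            raise ValueError(
                f"need 0 <= p_blocked < p_free <= 1, got {self.p_blocked}, {self.p_free}"
            )
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.stability_window < 1:
            raise ValueError("stability_window must be >= 1")


class UnitState:
    """The 2N-unit system state at one step.

    Vectors are indexed in :attr:`UnitId.index` order.  ``X`` holds the
    saturating accumulators, ``R`` the last resource-supply draws, ``S``
    the blocking signals computed from ``X``.
    """

    __slots__ = ("n_vars", "X", "R", "S", "t")

    def __init__(
        self,
        n_vars: int,
        X: np.ndarray | None = None,
        R: np.ndarray | None = None,
        S: np.ndarray | None = None,
        t: int = 0,
    ) -> None:
        n_units = 2 * n_vars
        self.n_vars = int(n_vars)
        self.X = np.zeros(n_units, dtype=np.int8) if X is None else np.asarray(X, dtype=np.int8)
        self.R = np.zeros(n_units, dtype=np.int8) if R is None else np.asarray(R, dtype=np.int8)
        self.S = np.zeros(n_units, dtype=float) if S is None else np.asarray(S, dtype=float)
        self.t = int(t)
        for name, arr in (("X", self.X), ("R", self.R), ("S", self.S)):
            if arr.shape != (n_units,):
                raise ValueError(f"{name} must have shape ({n_units},), got {arr.shape}")
        if not np.isin(self.X, (-1, 0, 1)).all():
            raise ValueError("X values must lie in {-1, 0, 1}")
        if not np.isin(self.R, (0, 1)).all():
            raise ValueError("R values must lie in {0, 1}")
        if self.S.min(initial=0.0) < 0.0 or self.S.max(initial=0.0) > 1.0:
            raise ValueError("S values must lie in [0, 1]")
        if t < 0:
            raise ValueError("t must be non-negative")

    @classmethod
    def zeros(cls, n_vars: int) -> "UnitState":
        return cls(n_vars)

    @property
    def n_units(self) -> int:
        return 2 * self.n_vars

    def unit_ids(self) -> list[UnitId]:
        return [UnitId.from_index(k) for k in range(self.n_units)]

    def x_of(self, unit: UnitId) -> int:
        return int(self.X[unit.index])

    def set_x(self, unit: UnitId, value: int) -> None:
        if value not in (-1, 0, 1):
            raise ValueError("X values must lie in {-1, 0, 1}")
        self.X[unit.index] = value

    def copy(self) -> "UnitState":
        return UnitState(self.n_vars, self.X.copy(), self.R.copy(), self.S.copy(), self.t)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"UnitState(n_vars={self.n_vars}, t={self.t}, X={self.X.tolist()})"


class RuleSet:
    """A rule list compiled to dense matrices for batched evaluation.

    ``C`` is the (n_rules, n_units) condition incidence matrix and ``T``
    the (n_rules, n_units) one-hot target matrix; a rule fires when the
    count of activated condition units reaches the condition size, and
    signals per target combine as a noisy-OR in log space.
    """

    def __init__(self, rules: Sequence[BouncebackRule], n_vars: int) -> None:
        self.rules = list(rules)
        self.n_vars = int(n_vars)
        n_units = 2 * n_vars
        n_rules = len(self.rules)
        self._C = np.zeros((n_rules, n_units), dtype=np.float32)
        self._T = np.zeros((n_rules, n_units), dtype=np.float32)
        self._cond_sizes = np.zeros(n_rules, dtype=np.float32)
        self.rule_types: list[str] = sorted({r.rule_type for r in self.rules})
        type_code = {name: i for i, name in enumerate(self.rule_types)}
        self._type_codes = np.zeros(n_rules, dtype=np.int64)
        for k, rule in enumerate(self.rules):
            for u in rule.condition:
                if u.index >= n_units:
                    raise ConfigurationError(f"rule condition unit {u} outside an {n_vars}-variable system")
                self._C[k, u.index] = 1.0
            if rule.target.index >= n_units:
                raise ConfigurationError(f"rule target {rule.target} outside an {n_vars}-variable system")
            self._T[k, rule.target.index] = 1.0
            self._cond_sizes[k] = len(rule.condition)
            self._type_codes[k] = type_code[rule.rule_type]

    def __len__(self) -> int:
        return len(self.rules)

    def intensity_vector(self, intensities: Mapping[str, float]) -> np.ndarray:
        """Per-rule intensity array; every rule type must have an entry."""
        missing = [t for t in self.rule_types if t not in intensities]
        if missing:
            raise ConfigurationError(f"no intensity given for rule type(s): {missing}")
        per_type = np.array([float(intensities[t]) for t in self.rule_types])
        if per_type.size and (per_type.min() < 0.0 or per_type.max() > 1.0):
            raise ConfigurationError("intensities must lie in [0.0, 1.0]")
        if len(self.rules) == 0:
            return np.zeros(0)
        return per_type[self._type_codes]

    def blocking(
        self, intensities: Mapping[str, float]
    ) -> tuple[np.ndarray, np.ndarray, bool]:
        """Precompute per-rule blocking terms for :meth:`signals`.

        Returns ``(log(1 - intensity)`` with a 0 placeholder for
        intensity 1, the exact-1 mask, and a flag marking the all-binary
        case (every intensity 0 or 1), which takes a cheaper path.
        """
        vec = self.intensity_vector(intensities)
        full = vec >= 1.0
        q = 1.0 - vec
        log_q = np.where(full, 0.0, np.log(np.where(full, 1.0, np.maximum(q, 1e-300))))
        binary = bool(np.isin(vec, (0.0, 1.0)).all())
        return log_q.astype(np.float32), full.astype(np.float32), binary

    def signals(self, active: np.ndarray, blocking: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
        """Combined blocking signal per unit from an activation mask.

        ``active`` is a boolean/0-1 array of shape (..., n_units) marking
        units with X = 1; returns signals of the same leading shape.
        """
        log_q, full, binary = blocking
        a = np.asarray(active, dtype=np.float32)
        if len(self.rules) == 0:
            return np.zeros(a.shape)
        counts = a @ self._C.T
        fires = (counts >= self._cond_sizes - 0.5).astype(np.float32)
        # any firing intensity-1.0 rule forces the signal to exactly 1
        hard = (fires * full) @ self._T > 0.5
        if binary:
            return hard.astype(np.float64)
        # product over firing fractional-intensity rules, in log space
        tot = (fires * log_q) @ self._T
        s = -np.expm1(tot.astype(np.float64))
        s = np.where(hard, 1.0, s)
        return np.clip(s, 0.0, 1.0)


def _as_ruleset(rules: Sequence[BouncebackRule] | RuleSet, n_vars: int) -> RuleSet:
    return rules if isinstance(rules, RuleSet) else RuleSet(rules, n_vars)


def compute_signals(
    state: UnitState,
    rules: Sequence[BouncebackRule] | RuleSet,
    intensities: Mapping[str, float],
) -> np.ndarray:
    """Noisy-OR combined bounceback signal for every unit.

    A rule fires iff all its condition units have ``X = 1`` (an empty
    condition always fires); the signal on a unit is
    ``1 - prod(1 - intensity)`` over the rules firing at it.
    """
    rs = _as_ruleset(rules, state.n_vars)
    return rs.signals(state.X == 1, rs.blocking(intensities))


def supply_resources(
    signals: np.ndarray, config: SolverConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sample resource supply: R=1 with prob (1-s)*p_free + s*p_blocked."""
    s = np.asarray(signals, dtype=float)
    p = config.p_free + s * (config.p_blocked - config.p_free)
    return (rng.random(s.shape) < p).astype(np.int8)


def update_X(X: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Saturating accumulation of supplied resource onto X in {-1,0,1}."""
    X = np.asarray(X)
    up = np.minimum(X + 1, 1)
    down = np.maximum(X - 1, -1)
    return np.where(np.asarray(R) == 1, up, down).astype(np.int8)


def decode_assignment(X: np.ndarray, previous: np.ndarray) -> np.ndarray:
    """Decode unit accumulators into a variable assignment.

    ``x_i = v`` when unit (i,v) is fully activated while its opponent is
    at or below zero; ambiguous variables keep their previous value.
    Accepts leading batch dimensions on both arguments.
    """
    X = np.asarray(X)
    x0 = X[..., 0::2]
    x1 = X[..., 1::2]
    take0 = (x0 == 1) & (x1 <= 0)
    take1 = (x1 == 1) & (x0 <= 0)
    prev = np.asarray(previous, dtype=np.uint8)
    return np.where(take0, 0, np.where(take1, 1, prev)).astype(np.uint8)


def is_stable(X: np.ndarray, signals: np.ndarray) -> bool | np.ndarray:
    """Stability criterion: activated units unblocked, inactive units blocked.

    Every unit must satisfy ``(X = 1 and s = 0)`` or ``(X <= 0 and s > 0)``,
    and every variable must keep at least one of its two units fully
    activated.  The second condition rejects states in which both
    branches of a variable are retracted yet blocked: such a state
    asserts no value for the variable (the decoder merely remembers a
    stale one), so it does not count as stably holding an assignment.
    With intra-variable exclusion rules in force the two conditions
    jointly force exactly one activated unit per variable, which is what
    makes stable states decode to constraint-satisfying assignments.

    With binary intensities "blocked" means s = 1 exactly; under
    fractional intensities any positive combined signal counts, since an
    exact-1 combination is a measure-zero event there.
    """
    X = np.asarray(X)
    s = np.asarray(signals)
    ok = ((X == 1) & (s <= 0.0)) | ((X <= 0) & (s > 0.0))
    asserted = (X[..., 0::2] == 1) | (X[..., 1::2] == 1)
    out = ok.all(axis=-1) & asserted.all(axis=-1)
    return bool(out) if out.ndim == 0 else out


def step(
    state: UnitState,
    rules: Sequence[BouncebackRule] | RuleSet,
    intensities: Mapping[str, float],
    config: SolverConfig,
    rng: np.random.Generator,
    previous: np.ndarray | None = None,
) -> tuple[UnitState, np.ndarray, bool]:
    """One synchronous update of the whole unit system.

    Order: signals from X(t); resource supply sampled under those
    signals; X(t+1) accumulated; assignment decoded from X(t+1) with
    ``previous`` breaking ambiguous variables.  Returns the new state,
    the decoded assignment and whether the new state meets the stability
    criterion (under its own freshly computed signals).
    """
    rs = _as_ruleset(rules, state.n_vars)
    blocking = rs.blocking(intensities)
    s_now = rs.signals(state.X == 1, blocking)
    R = supply_resources(s_now, config, rng)
    new_X = update_X(state.X, R)
    prev = np.zeros(state.n_vars, dtype=np.uint8) if previous is None else previous
    x = decode_assignment(new_X, prev)
    s_next = rs.signals(new_X == 1, blocking)
    new_state = UnitState(state.n_vars, new_X, R, s_next, state.t + 1)
    return new_state, x, bool(is_stable(new_X, s_next))


def pack_bits(x: np.ndarray) -> np.ndarray:
    """Pack assignments (..., N) with N <= 62 into integer keys."""
    x = np.asarray(x, dtype=np.int64)
    n = x.shape[-1]
    if n > 62:
        raise ValueError("bit packing supports at most 62 variables")
    weights = (np.int64(1) << np.arange(n, dtype=np.int64))
    return x @ weights


def unpack_bits(key: int, n: int) -> tuple[int, ...]:
    return tuple((int(key) >> k) & 1 for k in range(n))


def bits_label(bits: Iterable[int]) -> str:
    return "".join(str(int(b)) for b in bits)


@dataclass(frozen=True)
class Visit:
    """One logged stay in a constraint-satisfying decoded state."""

    chain: int
    state: tuple
    start: int
    dwell: int
    censored: bool = False


@dataclass
class TrajectoryRecord:
    """Outcome of :func:`simulate` over one or more chains."""

    n_vars: int
    n_chains: int
    steps_run: int
    seed: int | None
    first_hit_step: np.ndarray      # (n_chains,), -1 where censored
    first_hit_assignment: np.ndarray  # (n_chains, n_vars)
    visits: list = field(default_factory=list)
    transitions: Counter = field(default_factory=Counter)
    stable_steps: int = 0
    total_steps: int = 0
    stable_decoded: Counter = field(default_factory=Counter)
    assignments: np.ndarray | None = None   # (n_chains, steps+1, n_vars) if recorded
    stable_flags: np.ndarray | None = None

    @property
    def solved(self) -> np.ndarray:
        return self.first_hit_step >= 0

    @property
    def censored(self) -> np.ndarray:
        return ~self.solved

    def iterations(self, budget_value: int | None = None) -> np.ndarray:
        """Per-chain iterations-to-target, censored entries at the budget."""
        out = self.first_hit_step.astype(float)
        if budget_value is not None:
            out[out < 0] = budget_value
        return out


def simulate(
    rules: Sequence[BouncebackRule] | RuleSet,
    intensities: Mapping[str, float],
    config: SolverConfig,
    n_vars: int,
    *,
    n_chains: int = 1,
    rng: np.random.Generator | None = None,
    target: Callable[[np.ndarray], np.ndarray] | None = None,
    require_stable_target: bool = False,
    stop_on_target: bool = True,
    track_visits: bool = False,
    track_stable_decodes: bool = False,
    initial_X: np.ndarray | None = None,
    initial_assignment: np.ndarray | None = None,
    max_steps: int | None = None,
    record: bool = False,
) -> TrajectoryRecord:
    """Run the dynamics over ``n_chains`` independent chains in lock-step.

    Parameters
    ----------
    target
        Vectorised predicate mapping an assignment batch (B, N) to a
        boolean vector; a chain's first-hit step is the first step at
        which its decoded assignment satisfies the predicate (and, when
        ``require_stable_target`` is set, the unit state simultaneously
        meets the stability criterion).
    stop_on_target
        Drop chains from the batch once they hit the target (forced off
        while visit tracking is on, so transition logs cover full runs).
    track_visits
        Log metastable-state visits: a target-satisfying decoded
        assignment unchanged for ``config.stability_window`` consecutive
        steps opens a visit; dwell times and visit-to-visit transitions
        are recorded per chain.
    track_stable_decodes
        Count the decoded assignment at every step whose unit state meets
        the stability criterion.
    """
    rs = _as_ruleset(rules, n_vars)
    blocking = rs.blocking(intensities)
    n_units = 2 * n_vars
    B = int(n_chains)
    steps = config.max_steps if max_steps is None else int(max_steps)
    if steps < 1:
        raise ValueError("max_steps must be >= 1")
    seed_used = config.seed if rng is None else None
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if track_visits:
        stop_on_target = False

    if initial_X is None:
        X = np.zeros((B, n_units), dtype=np.int8)
    else:
        X = np.broadcast_to(np.asarray(initial_X, dtype=np.int8), (B, n_units)).copy()
    if initial_assignment is None:
        x = rng.integers(0, 2, size=(B, n_vars), dtype=np.int64).astype(np.uint8)
    else:
        x = np.broadcast_to(np.asarray(initial_assignment, dtype=np.uint8), (B, n_vars)).copy()

    first_hit = np.full(B, -1, dtype=np.int64)
    first_assign = np.zeros((B, n_vars), dtype=np.uint8)
    visits: list[Visit] = []
    transitions: Counter = Counter()
    stable_steps = 0
    total_steps = 0
    stable_decoded: Counter = Counter()

    rec_assign = np.zeros((B, steps + 1, n_vars), dtype=np.uint8) if record else None
    rec_stable = np.zeros((B, steps + 1), dtype=bool) if record else None

    # visit bookkeeping (per live chain, aligned with the batch arrays)
    window = config.stability_window
    if track_visits:
        cur_key = pack_bits(x)
        run_len = np.ones(B, dtype=np.int64)
        open_mask = np.zeros(B, dtype=bool)
        open_start = np.zeros(B, dtype=np.int64)
        last_closed = np.full(B, -1, dtype=np.int64)

    chain_ids = np.arange(B)
    need_stable = require_stable_target or track_stable_decodes or record

    t = 0
    while True:
        alive = chain_ids.size
        sig = rs.signals(X == 1, blocking)
        if need_stable:
            st = is_stable(X, sig)
            st = np.atleast_1d(st)
        if target is not None:
            hit = np.asarray(target(x), dtype=bool)
            eff = hit & st if require_stable_target else hit
        else:
            eff = np.zeros(alive, dtype=bool)

        if track_stable_decodes and st.any():
            keys, counts = np.unique(pack_bits(x[st]), return_counts=True)
            for k, c in zip(keys.tolist(), counts.tolist()):
                stable_decoded[unpack_bits(k, n_vars)] += int(c)
        if need_stable:
            stable_steps += int(st.sum())
        total_steps += alive

        new_hits = eff & (first_hit[chain_ids] < 0)
        if new_hits.any():
            ids = chain_ids[new_hits]
            first_hit[ids] = t
            first_assign[ids] = x[new_hits]

        if record:
            rec_assign[chain_ids, t] = x
            rec_stable[chain_ids, t] = st

        if track_visits and t > 0:
            key = pack_bits(x)
            changed = key != cur_key
            closing = changed & open_mask
            for b in np.nonzero(closing)[0]:
                visits.append(
                    Visit(int(chain_ids[b]), unpack_bits(int(cur_key[b]), n_vars),
                          int(open_start[b]), int(run_len[b]))
                )
                last_closed[b] = cur_key[b]
            open_mask &= ~changed
            run_len = np.where(changed, 1, run_len + 1)
            cur_key = np.where(changed, key, cur_key)
            sat_now = np.asarray(target(x), dtype=bool) if target is not None else np.zeros(alive, bool)
            opening = sat_now & (run_len == window) & ~open_mask
            for b in np.nonzero(opening)[0]:
                open_start[b] = t - window + 1
                if last_closed[b] != -1:
                    transitions[
                        (unpack_bits(int(last_closed[b]), n_vars),
                         unpack_bits(int(key[b]), n_vars))
                    ] += 1
            open_mask |= opening

        if stop_on_target and new_hits.any():
            keep = ~new_hits
            if not keep.all():
                chain_ids = chain_ids[keep]
                X = X[keep]
                x = x[keep]
                sig = sig[keep]
        if t >= steps or chain_ids.size == 0:
            break

        # advance one synchronous step
        p = config.p_free + sig * (config.p_blocked - config.p_free)
        R = rng.random(sig.shape) < p
        X = update_X(X, R.astype(np.int8))
        x = decode_assignment(X, x)
        t += 1

    if track_visits:
        for b in np.nonzero(open_mask)[0]:
            visits.append(
                Visit(int(chain_ids[b]), unpack_bits(int(cur_key[b]), n_vars),
                      int(open_start[b]), int(run_len[b]), censored=True)
            )

    return TrajectoryRecord(
        n_vars=n_vars,
        n_chains=B,
        steps_run=t,
        seed=seed_used,
        first_hit_step=first_hit,
        first_hit_assignment=first_assign,
        visits=visits,
        transitions=transitions,
        stable_steps=stable_steps,
        total_steps=total_steps,
        stable_decoded=stable_decoded,
        assignments=rec_assign,
        stable_flags=rec_stable,
    )


def run(
    rules: Sequence[BouncebackRule] | RuleSet,
    intensities: Mapping[str, float],
    config: SolverConfig,
    n_vars: int,
    *,
    initial_state: UnitState | None = None,
    initial_assignment: np.ndarray | None = None,
    target: Callable[[np.ndarray], np.ndarray] | None = None,
    record: bool = True,
    track_visits: bool = True,
) -> TrajectoryRecord:
    """Single-chain convenience wrapper around :func:`simulate`.

    Runs for ``config.max_steps`` steps, recording the decoded assignment
    and stability flag at every step plus metastable-state visits; a
    chain that never reaches the target is reported as censored
    (``first_hit_step = -1``), never as an error.
    """
    return simulate(
        rules,
        intensities,
        config,
        n_vars,
        n_chains=1,
        target=target,
        stop_on_target=False,
        track_visits=track_visits,
        track_stable_decodes=True,
        initial_X=None if initial_state is None else initial_state.X,
        initial_assignment=initial_assignment,
        record=record,
    )
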