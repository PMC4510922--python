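"""Valence-constrained chemistry frontend.

An input atom multiset (e.g. 2 N + 6 H) is compiled into *bond slots*:
every unordered atom pair gets ``min(valence_a, valence_b, 3)`` slots,
one per unit of bond order, so a triple bond is three activated slots of
the same pair.  Each slot is one Boolean variable of the generic
dynamics (its two units are the bonded/unbonded branches), which lets
the SAT machinery run completely unchanged.

Chemical knowledge enters as typed bounceback rules:

OCTET_EXCESS
    An atom with valence v may carry at most v bonds: for every
    (v+1)-subset of its incident slots, each member slot is suppressed
    when all the others are on.
OCTET_DEFICIT
    The atom must reach v bonds (the valence-shell completion reading of
    the octet rule, with lone pairs implicit): once so many slots are
    off that only v remain open, the off-branch of each remaining slot
    is suppressed.  When the atom has exactly v incident slots this
    degenerates to an unconditional force on every slot.
SLOT_ORDER
    Symmetry breaking between equivalent slots of one pair: order k+1
    may only switch on on top of order k.
CONTRA
    Per-slot intra-variable exclusion, as in the SAT frontend.

Each rule type has its own continuous blocking intensity in [0, 1];
lowering intensities adds probabilistic fluctuation, the analogue of
raising temperature.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .core import (
    RULE_CONTRA,
    RULE_OCTET_DEFICIT,
    RULE_OCTET_EXCESS,
    RULE_SLOT_ORDER,
    BouncebackRule,
    SolverConfig,
    UnitId,
    simulate,
)

__all__ = [
    "VALENCE",
    "AtomSpec",
    "BondSlot",
    "BondSystem",
    "MolecularComposition",
    "parse_atom_multiset",
    "build_bond_system",
    "compile_chem_rules",
    "decode_molecules",
    "enumerate_valid_compositions",
    "realize_composition",
    "run_chem",
    "ChemRunResult",
    "INTENSITY_SETS",
    "DEFAULT_INTENSITIES",
    "chem_config",
]

#: Bonding capacity per supported element (lone pairs implicit).
VALENCE = {"H": 1, "O": 2, "N": 3, "C": 4}

#: Triple bonds are the highest order considered.
MAX_BOND_ORDER = 3

#: Subset-enumeration guard: octet rules grow combinatorially in the
#: number of slots incident to one atom.
MAX_INCIDENT_SLOTS = 16

ENUMERATION_MAX_ATOMS = 12

#: Common display names for Hill-order formulas.
_DISPLAY = {"H3N": "NH3", "H2N2": "N2H2", "H4N2": "N2H4", "H2O2": "H2O2"}
_DISPLAY_REVERSE = {v: k for k, v in _DISPLAY.items()}


@dataclass(frozen=True)
class AtomSpec:
    atom_id: int
    element: str
    valence: int

    def __post_init__(self) -> None:
        if self.element not in VALENCE:
            raise ValueError(f"unsupported element: {self.element!r}")
        if self.valence != VALENCE[self.element]:
            raise ValueError(
                f"valence {self.valence} does not match element {self.element} "
                f"(expected {VALENCE[self.element]})"
            )


@dataclass(frozen=True)
class BondSlot:
    """One potential unit of bond order between a fixed atom pair."""

    atom_a: int
    atom_b: int
    slot_index: int  # 1-based, up to min(valences, MAX_BOND_ORDER)

    def __post_init__(self) -> None:
        if self.atom_a >= self.atom_b:
            raise ValueError("BondSlot atoms must satisfy atom_a < atom_b")
        if self.slot_index < 1:
            raise ValueError("slot_index is 1-based")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.atom_a, self.atom_b)


@dataclass(frozen=True)
class BondSystem:
    """Atoms plus the full slot enumeration, mapped onto SAT-style variables.

    Slot at position ``k`` (0-based) is variable ``k+1`` of the generic
    dynamics; its two units are (k+1, 1) = bonded and (k+1, 0) = open.
    """

    atoms: tuple
    slots: tuple

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    @property
    def n_vars(self) -> int:
        return self.n_slots

    def slot_variable(self, slot: BondSlot) -> int:
        return self.slots.index(slot) + 1

    def incident(self, atom_id: int) -> list[int]:
        """0-based positions of the slots touching the given atom."""
        return [k for k, s in enumerate(self.slots) if atom_id in s.pair]

    def incidence_matrix(self) -> np.ndarray:
        """(n_slots, n_atoms) 0/1 matrix: slot k touches atom column."""
        inc = np.zeros((self.n_slots, self.n_atoms), dtype=np.int64)
        for k, s in enumerate(self.slots):
            inc[k, s.atom_a - 1] = 1
            inc[k, s.atom_b - 1] = 1
        return inc

    def valences(self) -> np.ndarray:
        return np.array([a.valence for a in self.atoms], dtype=np.int64)

    def valence_complete(self, assignment: np.ndarray) -> np.ndarray:
        """Vectorised check: every atom's bond count equals its valence."""
        a = np.asarray(assignment, dtype=np.int64)
        counts = a @ self.incidence_matrix()
        return (counts == self.valences()).all(axis=-1)

    def atom_multiset(self) -> Counter:
        return Counter(a.element for a in self.atoms)


def parse_atom_multiset(spec: str | Mapping[str, int] | Sequence[str]) -> list[str]:
    """Expand an atom multiset spec like ``"N:2,H:6"`` into element symbols."""
    if isinstance(spec, str):
        counts: list[tuple[str, int]] = []
        for part in spec.split(","):
            part = part.strip()
            if not part:
                continue
            if ":" in part:
                elem, _, num = part.partition(":")
                counts.append((elem.strip(), int(num)))
            else:
                counts.append((part, 1))
    elif isinstance(spec, Mapping):
        counts = list(spec.items())
    else:
        counts = [(e, 1) for e in spec]
    out: list[str] = []
    for elem, num in counts:
        if elem not in VALENCE:
            raise ValueError(f"unsupported element: {elem!r}")
        if num < 1:
            raise ValueError(f"count for {elem} must be positive")
        out.extend([elem] * num)
    return out


def build_bond_system(atoms: str | Mapping[str, int] | Sequence[str]) -> BondSystem:
    """Enumerate all bond slots for an atom multiset.

    Deterministic ordering: atoms keep input order (ids 1..n), pairs are
    lexicographic, slot indices ascend.
    """
    elements = parse_atom_multiset(atoms)
    if len(elements) < 2:
        raise ValueError("a bond system needs at least 2 atoms")
    specs = tuple(
        AtomSpec(i + 1, e, VALENCE[e]) for i, e in enumerate(elements)
    )
    slots: list[BondSlot] = []
    for a, b in itertools.combinations(range(1, len(specs) + 1), 2):
        max_order = min(specs[a - 1].valence, specs[b - 1].valence, MAX_BOND_ORDER)
        for k in range(1, max_order + 1):
            slots.append(BondSlot(a, b, k))
    return BondSystem(specs, tuple(slots))


def compile_chem_rules(
    system: BondSystem,
    include_contra: bool = True,
    include_slot_order: bool = True,
) -> list[BouncebackRule]:
    """Compile the valence/octet constraint set of a bond system."""
    rules: list[BouncebackRule] = []
    for atom in system.atoms:
        incident = system.incident(atom.atom_id)
        if len(incident) > MAX_INCIDENT_SLOTS:
            raise ValueError(
                f"atom {atom.atom_id} ({atom.element}) has {len(incident)} incident "
                f"slots; octet-rule enumeration is guarded at {MAX_INCIDENT_SLOTS}"
            )
        v = atom.valence
        # at most v bonds
        if len(incident) >= v + 1:
            for T in itertools.combinations(incident, v + 1):
                for i in T:
                    cond = frozenset(UnitId(j + 1, 1) for j in T if j != i)
                    rules.append(BouncebackRule(cond, UnitId(i + 1, 1), RULE_OCTET_EXCESS))
        # at least v bonds (empty condition when len(incident) == v)
        deficit_size = len(incident) - v + 1
        if deficit_size >= 1:
            for U in itertools.combinations(incident, deficit_size):
                for i in U:
                    cond = frozenset(UnitId(j + 1, 0) for j in U if j != i)
                    rules.append(BouncebackRule(cond, UnitId(i + 1, 0), RULE_OCTET_DEFICIT))
    if include_slot_order:
        by_pair: dict[tuple[int, int], list[int]] = {}
        for k, slot in enumerate(system.slots):
            by_pair.setdefault(slot.pair, []).append(k)
        for positions in by_pair.values():
            for lo, hi in itertools.combinations(sorted(positions), 2):
                rules.append(
                    BouncebackRule(
                        frozenset({UnitId(lo + 1, 0)}), UnitId(hi + 1, 1), RULE_SLOT_ORDER
                    )
                )
    if include_contra:
        for k in range(system.n_slots):
            for vtag in (0, 1):
                rules.append(
                    BouncebackRule(
                        frozenset({UnitId(k + 1, vtag)}), UnitId(k + 1, 1 - vtag), RULE_CONTRA
                    )
                )
    return rules


def hill_formula(counts: Mapping[str, int]) -> str:
    """Hill-order molecular formula (C, H, then alphabetical; no-C case
    fully alphabetical)."""
    items = {e: c for e, c in counts.items() if c > 0}
    order: list[str] = []
    if "C" in items:
        order.append("C")
        if "H" in items:
            order.append("H")
        order.extend(sorted(e for e in items if e not in ("C", "H")))
    else:
        order = sorted(items)
    return "".join(f"{e}{items[e] if items[e] > 1 else ''}" for e in order)


def display_formula(hill: str) -> str:
    """Conventional display name for a Hill formula (NH3, N2H4, ...)."""
    return _DISPLAY.get(hill, hill)


@dataclass(frozen=True, order=True)
class MolecularComposition:
    """A multiset of molecular formulas, e.g. one N2 plus three H2."""

    formulas: tuple  # sorted tuple of (hill_formula, count)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "MolecularComposition":
        return cls(tuple(sorted((f, int(c)) for f, c in counts.items() if c > 0)))

    @classmethod
    def from_formulas(cls, formulas: Iterable[str]) -> "MolecularComposition":
        return cls.from_counts(Counter(formulas))

    def as_dict(self) -> dict:
        return dict(self.formulas)

    def label(self) -> str:
        # heaviest molecules first; reverse-alphabetical on ties so that
        # e.g. N2 precedes H2
        ordered = sorted(self.formulas, key=lambda fc: fc[0], reverse=True)
        ordered.sort(key=lambda fc: -_formula_weight(fc[0]))
        parts = []
        for f, c in ordered:
            name = display_formula(f)
            parts.append(name if c == 1 else f"{c} {name}")
        return " + ".join(parts) if parts else "(no molecules)"

    def atom_counts(self) -> Counter:
        total: Counter = Counter()
        for f, c in self.formulas:
            for e, n in _parse_formula(f).items():
                total[e] += n * c
        return total

    def __str__(self) -> str:
        return self.label()


def _parse_formula(f: str) -> Counter:
    counts: Counter = Counter()
    i = 0
    while i < len(f):
        elem = f[i]
        i += 1
        num = ""
        while i < len(f) and f[i].isdigit():
            num += f[i]
            i += 1
        counts[elem] += int(num) if num else 1
    return counts


def _formula_weight(f: str) -> int:
    return sum(_parse_formula(f).values())


def parse_composition(spec: str) -> MolecularComposition:
    """Parse e.g. ``"N2 + 2 H2"`` or ``"N2+2H2"`` or ``"NH3:2"``."""
    counts: Counter = Counter()
    for part in spec.replace(",", "+").split("+"):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            formula, _, num = part.partition(":")
            count = int(num)
            formula = formula.strip()
        else:
            m = part.split()
            if len(m) == 2 and m[0].isdigit():
                count, formula = int(m[0]), m[1]
            else:
                # leading digits are a count only if followed by space-free
                # formula starting with a letter after them, e.g. "2NH3"
                j = 0
                while j < len(part) and part[j].isdigit():
                    j += 1
                if j > 0 and j < len(part):
                    maybe = part[j:]
                    # "2NH3" -> 2 x NH3 ; but "N2" has digits after letters
                    count, formula = int(part[:j]), maybe
                else:
                    count, formula = 1, part
        formula = _DISPLAY_REVERSE.get(formula, formula)
        # normalise through parse/emit so "NH3" and "H3N" collide
        counts[hill_formula(_parse_formula(formula))] += count
    return MolecularComposition.from_counts(counts)


def decode_molecules(system: BondSystem, assignment: np.ndarray) -> MolecularComposition:
    """Read molecules off a slot assignment.

    Atoms are graph nodes; any activated slot of a pair contributes an
    edge (bond order = number of activated slots).  Connected components
    become molecular formulas.
    """
    a = np.asarray(assignment).astype(np.int64)
    if a.shape != (system.n_slots,):
        raise ValueError(f"assignment must cover all {system.n_slots} slots")
    G = nx.Graph()
    G.add_nodes_from(atom.atom_id for atom in system.atoms)
    for k, slot in enumerate(system.slots):
        if a[k]:
            G.add_edge(slot.atom_a, slot.atom_b)
    formulas = []
    for comp in nx.connected_components(G):
        counts = Counter(system.atoms[i - 1].element for i in comp)
        formulas.append(hill_formula(counts))
    return MolecularComposition.from_formulas(formulas)


def _search_assignments(system: BondSystem, stop_at=None, want_composition=None):
    """Backtracking over slots with valence-exactness pruning.

    Yields every assignment in which each atom's bond count equals its
    valence.  Slots of one pair are filled in ascending order (lower
    orders first), which collapses permutations of equivalent slots.
    """
    n = system.n_slots
    slots = system.slots
    valences = system.valences()
    remaining = valences.astype(np.int64).copy()
    # future capacity per atom: how many undecided slots touch it
    future = np.zeros(system.n_atoms, dtype=np.int64)
    for s in slots:
        future[s.atom_a - 1] += 1
        future[s.atom_b - 1] += 1
    assign = np.zeros(n, dtype=np.uint8)
    prev_slot_on = {}  # pair -> was the previous slot of this pair on?

    results = []

    def rec(k: int):
        if stop_at is not None and len(results) >= stop_at:
            return
        if k == n:
            if (remaining == 0).all():
                if want_composition is None or decode_molecules(system, assign) == want_composition:
                    results.append(assign.copy())
            return
        s = slots[k]
        ia, ib = s.atom_a - 1, s.atom_b - 1
        future[ia] -= 1
        future[ib] -= 1
        # try ON first (prefers low-slot filling, canonical realizations)
        lower_ok = s.slot_index == 1 or prev_slot_on.get((s.pair, s.slot_index - 1), False)
        if remaining[ia] > 0 and remaining[ib] > 0 and lower_ok:
            assign[k] = 1
            remaining[ia] -= 1
            remaining[ib] -= 1
            prev_slot_on[(s.pair, s.slot_index)] = True
            if (remaining <= future).all():
                rec(k + 1)
            remaining[ia] += 1
            remaining[ib] += 1
        # try OFF
        assign[k] = 0
        prev_slot_on[(s.pair, s.slot_index)] = False
        if remaining[ia] <= future[ia] and remaining[ib] <= future[ib]:
            rec(k + 1)
        future[ia] += 1
        future[ib] += 1

    rec(0)
    return results


def enumerate_valid_compositions(system: BondSystem) -> set:
    """All molecular compositions in which every atom completes its valence.

    Backtracking oracle over slot assignments; guarded at
    ``ENUMERATION_MAX_ATOMS`` atoms.
    """
    if system.n_atoms > ENUMERATION_MAX_ATOMS:
        raise ValueError(
            f"enumeration refused for {system.n_atoms} atoms "
            f"(> {ENUMERATION_MAX_ATOMS})"
        )
    return {
        decode_molecules(system, a) for a in _search_assignments(system)
    }


def realize_composition(
    system: BondSystem, composition: MolecularComposition
) -> np.ndarray:
    """A concrete slot assignment decoding to the given composition.

    Lower-order slots are preferred, so the realization is canonical
    with respect to SLOT_ORDER symmetry breaking.  Raises if the
    composition cannot be realized on this system.
    """
    if composition.atom_counts() != system.atom_multiset():
        raise ValueError(
            f"composition {composition.label()!r} does not match the "
            f"system's atom multiset {dict(system.atom_multiset())}"
        )
    found = _search_assignments(system, stop_at=1, want_composition=composition)
    if not found:
        raise ValueError(f"composition {composition.label()!r} is not realizable")
    return found[0]


#: Named intensity parameter sets for the chemistry dynamics.  "tight"
#: blocks every rule type almost fully (a cold, strongly guided regime);
#: "loose" lowers every intensity uniformly, injecting aggressive
#: probabilistic fluctuation — the analogue of raising temperature —
#: which reshapes both the kinetics and the distribution of first-found
#: metastable molecules.
INTENSITY_SETS = {
    "tight": {
        RULE_OCTET_EXCESS: 0.95,
        RULE_OCTET_DEFICIT: 0.95,
        RULE_SLOT_ORDER: 0.95,
        RULE_CONTRA: 0.95,
    },
    "loose": {
        RULE_OCTET_EXCESS: 0.60,
        RULE_OCTET_DEFICIT: 0.60,
        RULE_SLOT_ORDER: 0.60,
        RULE_CONTRA: 0.60,
    },
}

DEFAULT_INTENSITIES = INTENSITY_SETS["tight"]

#: Chemistry-regime supply probabilities: near-deterministic, so that
#: exploration noise is governed by the continuous rule intensities
#: (the temperature knob of this frontend) rather than supply dropout.
CHEM_P_FREE = 0.99
CHEM_P_BLOCKED = 0.01


def chem_config(seed: int = 0, max_steps: int = 5000, stability_window: int = 3) -> SolverConfig:
    """Default dynamics configuration for chemistry runs."""
    return SolverConfig(
        p_free=CHEM_P_FREE,
        p_blocked=CHEM_P_BLOCKED,
        max_steps=max_steps,
        seed=seed,
        stability_window=stability_window,
    )


@dataclass
class ChemRunResult:
    """First-found distribution and optional transition statistics."""

    system: BondSystem
    first_found: Counter          # MolecularComposition -> count of trials
    first_steps: np.ndarray       # (trials,) step of first find, -1 censored
    censored: int
    dwell: Counter | None = None        # composition -> total dwell steps
    transitions: Counter | None = None  # (composition, composition) -> count

    def frequencies(self) -> dict:
        total = sum(self.first_found.values())
        return {c: n / total for c, n in self.first_found.items()} if total else {}


def run_chem(
    system: BondSystem,
    intensities: Mapping[str, float] | str = "tight",
    config: SolverConfig | None = None,
    *,
    initial: MolecularComposition | str | np.ndarray | None = None,
    trials: int = 500,
    track_transitions: bool = False,
    rules: Sequence[BouncebackRule] | None = None,
    rng: np.random.Generator | None = None,
) -> ChemRunResult:
    """Monte Carlo exploration of metastable molecules.

    Each trial starts from the neutral volume state (all accumulators at
    zero) with the decoded assignment seeded by ``initial`` (a
    composition, realized canonically on the slots) or drawn uniformly
    at random.  A trial's *first-found* state is the composition decoded
    at the first step where the stability criterion holds and every
    atom's valence is complete; trials that never get there within the
    step budget are counted as censored.

    With ``track_transitions`` every trial runs its full step budget and
    metastable-composition visits (dwell times, visit-to-visit
    transition counts) are aggregated across trials.
    """
    if config is None:
        config = chem_config()
    if isinstance(intensities, str):
        intensities = INTENSITY_SETS[intensities]
    if rules is None:
        rules = compile_chem_rules(system)

    if initial is None:
        x0 = None
    elif isinstance(initial, (MolecularComposition, str)):
        comp = parse_composition(initial) if isinstance(initial, str) else initial
        x0 = realize_composition(system, comp)
    else:
        x0 = np.asarray(initial, dtype=np.uint8)
        if x0.shape != (system.n_slots,):
            raise ValueError(f"initial assignment must cover {system.n_slots} slots")

    record = simulate(
        rules,
        intensities,
        config,
        system.n_vars,
        n_chains=trials,
        rng=rng,
        target=system.valence_complete,
        require_stable_target=True,
        stop_on_target=not track_transitions,
        track_visits=track_transitions,
        initial_assignment=x0,
    )

    first_found: Counter = Counter()
    for b in range(trials):
        if record.first_hit_step[b] >= 0:
            comp = decode_molecules(system, record.first_hit_assignment[b])
            first_found[comp] += 1
    censored = int((record.first_hit_step < 0).sum())

    dwell = transitions = None
    if track_transitions:
        dwell = Counter()
        for v in record.visits:
            comp = decode_molecules(system, np.array(v.state, dtype=np.uint8))
            if bool(system.valence_complete(np.array(v.state, dtype=np.uint8))):
                dwell[comp] += v.dwell
        transitions = Counter()
        for (a, b), n in record.transitions.items():
            ca = decode_molecules(system, np.array(a, dtype=np.uint8))
            cb = decode_molecules(system, np.array(b, dtype=np.uint8))
            transitions[(ca, cb)] += n

    return ChemRunResult(
        system=system,
        first_found=first_found,
        first_steps=record.first_hit_step.copy(),
        censored=censored,
        dwell=dwell,
        transitions=transitions,
    )
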