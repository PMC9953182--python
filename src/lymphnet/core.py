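"""Place/transition net kernel.

A P/T net is the quintuple ``N = (P, T, F, W, m0)``: a bipartite directed
graph whose two node kinds are *places* (token holders) and *transitions*
(events), arcs ``F ⊆ (P×T) ∪ (T×P)`` with positive integer weights ``W``,
and an initial marking ``m0``.  This module provides net construction and
validation, the incidence matrix, the classical firing rule, and the
standard structural predicates (pure, ordinary, connected, conserved).

All arithmetic is exact integer arithmetic; markings are immutable maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "PetriNetError",
    "PlaceDecl",
    "TransitionDecl",
    "Arc",
    "Marking",
    "PetriNet",
    "StructuralReport",
    "build_net",
    "incidence_matrix",
    "enabled",
    "fire",
    "structural_report",
]


class PetriNetError(ValueError):
    """Raised for structurally invalid nets, arcs, markings or firings."""


@dataclass(frozen=True)
class PlaceDecl:
    """A place declaration.

    ``compartment`` and ``species`` are optional annotation codes (lymph-node
    vocabulary); the kernel does not interpret them.
    """

    id: str
    label: str = ""
    compartment: str | None = None
    species: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PetriNetError("place id must be nonempty")


@dataclass(frozen=True)
class TransitionDecl:
    id: str
    label: str = ""
    process: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PetriNetError("transition id must be nonempty")


@dataclass(frozen=True)
class Arc:
    """A weighted arc between a place and a transition (either direction)."""

    source: str
    target: str
    weight: int = 1

    def __post_init__(self) -> None:
        if not isinstance(self.weight, (int, np.integer)) or isinstance(self.weight, bool):
            raise PetriNetError(f"arc {self.source}->{self.target}: weight must be an integer")
        if self.weight < 1:
            raise PetriNetError(
                f"arc {self.source}->{self.target}: weight {self.weight} < 1"
            )


class Marking(Mapping[str, int]):
    """A total map place id -> token count (>= 0).

    Totality is enforced at construction against the owning net's place set,
    which makes conservation checks unambiguous: an absent place is an error,
    never an implicit zero.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int]):
        for p, c in counts.items():
            if not isinstance(c, (int, np.integer)) or isinstance(c, bool):
                raise PetriNetError(f"marking of {p!r} must be an integer, got {c!r}")
            if c < 0:
                raise PetriNetError(f"marking of {p!r} is negative: {c}")
        self._counts = {p: int(c) for p, c in counts.items()}

    def __getitem__(self, place: str) -> int:
        return self._counts[place]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __repr__(self) -> str:
        nonzero = {p: c for p, c in self._counts.items() if c}
        return f"Marking({nonzero!r}, |P|={len(self)})"

    def __eq__(self, other) -> bool:
        if isinstance(other, Marking):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self):
        return hash(frozenset(self._counts.items()))

    def total(self) -> int:
        """Total number of tokens on all places."""
        return sum(self._counts.values())


@dataclass(frozen=True)
class StructuralReport:
    is_pure: bool
    is_ordinary: bool
    is_connected: bool
    is_strongly_connected: bool
    is_conserved: bool
    input_transitions: tuple[str, ...]
    output_transitions: tuple[str, ...]
    nonunit_arcs: tuple[Arc, ...]


class PetriNet:
    """An immutable, validated P/T net.

    Node order is declaration order; the incidence matrix and every invariant
    vector report in this fixed order, which makes all downstream analyses
    reproducible.
    """

    def __init__(
        self,
        places: Sequence[PlaceDecl],
        transitions: Sequence[TransitionDecl],
        arcs: Iterable[Arc],
        initial_marking: Mapping[str, int] | None = None,
    ):
        self.places: tuple[PlaceDecl, ...] = tuple(places)
        self.transitions: tuple[TransitionDecl, ...] = tuple(transitions)
        self.arcs: tuple[Arc, ...] = tuple(arcs)

        self._place_ids = [p.id for p in self.places]
        self._transition_ids = [t.id for t in self.transitions]
        pset = set(self._place_ids)
        tset = set(self._transition_ids)
        if len(pset) != len(self._place_ids):
            raise PetriNetError("duplicate place ids")
        if len(tset) != len(self._transition_ids):
            raise PetriNetError("duplicate transition ids")
        if pset & tset:
            raise PetriNetError(f"place/transition id overlap: {sorted(pset & tset)}")

        seen_pairs: set[tuple[str, str]] = set()
        # pre/post maps: transition -> {place: weight} and place -> {transition: weight}
        self._pre_t: dict[str, dict[str, int]] = {t: {} for t in self._transition_ids}
        self._post_t: dict[str, dict[str, int]] = {t: {} for t in self._transition_ids}
        self._pre_p: dict[str, dict[str, int]] = {p: {} for p in self._place_ids}
        self._post_p: dict[str, dict[str, int]] = {p: {} for p in self._place_ids}
        for a in self.arcs:
            if (a.source, a.target) in seen_pairs:
                raise PetriNetError(f"parallel arc {a.source}->{a.target}")
            seen_pairs.add((a.source, a.target))
            if a.source in pset and a.target in tset:
                self._pre_t[a.target][a.source] = a.weight
                self._post_p[a.source][a.target] = a.weight
            elif a.source in tset and a.target in pset:
                self._post_t[a.source][a.target] = a.weight
                self._pre_p[a.target][a.source] = a.weight
            elif a.source in pset and a.target in pset:
                raise PetriNetError(f"place-to-place arc {a.source}->{a.target}")
            elif a.source in tset and a.target in tset:
                raise PetriNetError(f"transition-to-transition arc {a.source}->{a.target}")
            else:
                raise PetriNetError(f"arc endpoint not in net: {a.source}->{a.target}")

        if initial_marking is None:
            initial_marking = {p: 0 for p in self._place_ids}
        if set(initial_marking) != pset:
            missing = pset - set(initial_marking)
            extra = set(initial_marking) - pset
            raise PetriNetError(
                f"initial marking must cover exactly the places; missing={sorted(missing)}, "
                f"unknown={sorted(extra)}"
            )
        self.initial_marking = Marking(initial_marking)

    # -- identity & lookup ---------------------------------------------------

    @property
    def place_ids(self) -> list[str]:
        return list(self._place_ids)

    @property
    def transition_ids(self) -> list[str]:
        return list(self._transition_ids)

    def is_place(self, node: str) -> bool:
        return node in self._pre_p

    def is_transition(self, node: str) -> bool:
        return node in self._pre_t

    def pre(self, node: str) -> dict[str, int]:
        """Pre-set of a node with arc weights (•t or •p)."""
        if node in self._pre_t:
            return dict(self._pre_t[node])
        if node in self._pre_p:
            return dict(self._pre_p[node])
        raise PetriNetError(f"unknown node {node!r}")

    def post(self, node: str) -> dict[str, int]:
        """Post-set of a node with arc weights (t• or p•)."""
        if node in self._post_t:
            return dict(self._post_t[node])
        if node in self._post_p:
            return dict(self._post_p[node])
        raise PetriNetError(f"unknown node {node!r}")

    def empty_marking(self) -> Marking:
        return Marking({p: 0 for p in self._place_ids})

    def marking(self, nonzero: Mapping[str, int] | None = None) -> Marking:
        """Build a total marking from a sparse ``{place: count}`` map."""
        counts = {p: 0 for p in self._place_ids}
        for p, c in (nonzero or {}).items():
            if p not in counts:
                raise PetriNetError(f"unknown place {p!r} in marking")
            counts[p] = c
        return Marking(counts)

    def __repr__(self) -> str:
        return (
            f"PetriNet(|P|={len(self.places)}, |T|={len(self.transitions)}, "
            f"|F|={len(self.arcs)})"
        )

    def to_nx(self) -> nx.DiGraph:
        """The net as a networkx digraph (weights on edges, kind on nodes)."""
        g = nx.DiGraph()
        for p in self.places:
            g.add_node(p.id, kind="place")
        for t in self.transitions:
            g.add_node(t.id, kind="transition")
        for a in self.arcs:
            g.add_edge(a.source, a.target, weight=a.weight)
        return g


def build_net(
    places: Sequence[PlaceDecl | str],
    transitions: Sequence[TransitionDecl | str],
    arcs: Iterable[Arc | tuple],
    initial_marking: Mapping[str, int] | None = None,
) -> PetriNet:
    """Construct a validated :class:`PetriNet`.

    Strings are accepted as bare place/transition declarations and tuples
    ``(source, target[, weight])`` as arcs, for concise test and generator
    code.
    """
    pdecls = [p if isinstance(p, PlaceDecl) else PlaceDecl(p) for p in places]
    tdecls = [t if isinstance(t, TransitionDecl) else TransitionDecl(t) for t in transitions]
    adecls = [a if isinstance(a, Arc) else Arc(*a) for a in arcs]
    return PetriNet(pdecls, tdecls, adecls, initial_marking)


def incidence_matrix(net: PetriNet) -> np.ndarray:
    """The |P| x |T| incidence matrix C.

    ``C[i, j] = w(t_j -> p_i) - w(p_i -> t_j)``: the token change on place i
    when transition j fires.  Rows follow net place order, columns net
    transition order; dtype is int64 (exact for all nets of interest).
    """
    p_index = {p: i for i, p in enumerate(net.place_ids)}
    t_index = {t: j for j, t in enumerate(net.transition_ids)}
    c = np.zeros((len(p_index), len(t_index)), dtype=np.int64)
    for a in net.arcs:
        if net.is_place(a.source):
            c[p_index[a.source], t_index[a.target]] -= a.weight
        else:
            c[p_index[a.target], t_index[a.source]] += a.weight
    return c


def enabled(net: PetriNet, marking: Marking, transition: str) -> bool:
    """True iff ``m(p) >= w(p, t)`` for every pre-place p of t.

    Transitions with an empty pre-set (input transitions) are always enabled.
    """
    if not net.is_transition(transition):
        raise PetriNetError(f"unknown transition {transition!r}")
    return all(marking[p] >= w for p, w in net.pre(transition).items())


def fire(net: PetriNet, marking: Marking, transition: str) -> Marking:
    """Fire an enabled transition, returning the successor marking.

    The input marking is not mutated.  Firing a disabled transition raises.
    """
    if not enabled(net, marking, transition):
        raise PetriNetError(f"transition {transition!r} is not enabled")
    counts = dict(marking)
    for p, w in net.pre(transition).items():
        counts[p] -= w
    for p, w in net.post(transition).items():
        counts[p] += w
    return Marking(counts)


def structural_report(net: PetriNet) -> StructuralReport:
    """Compute the standard structural predicates of a P/T net.

    pure: no transition shares a pre- and post-place (no self-loop).
    ordinary: all arc weights are one.
    connected / strongly connected: on the underlying (un)directed graph.
    conserved: every firing preserves the total token count, i.e. every
    incidence-matrix column sums to zero.
    """
    pure = all(
        not (set(net.pre(t)) & set(net.post(t))) for t in net.transition_ids
    )
    nonunit = tuple(a for a in net.arcs if a.weight != 1)
    g = net.to_nx()
    n_nodes = g.number_of_nodes()
    connected = n_nodes <= 1 or nx.is_connected(g.to_undirected())
    strongly = n_nodes <= 1 or nx.is_strongly_connected(g)
    c = incidence_matrix(net)
    conserved = bool(np.all(c.sum(axis=0) == 0)) if c.size else True
    inputs = tuple(t for t in net.transition_ids if not net.pre(t))
    outputs = tuple(t for t in net.transition_ids if not net.post(t))
    return StructuralReport(
        is_pure=pure,
        is_ordinary=not nonunit,
        is_connected=connected,
        is_strongly_connected=strongly,
        is_conserved=conserved,
        input_transitions=inputs,
        output_transitions=outputs,
        nonunit_arcs=nonunit,
    )
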