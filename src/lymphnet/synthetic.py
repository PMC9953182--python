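"""Small synthetic P/T nets with known invariant structure.

These generators emulate the structural motifs of compartment models of
cell traffic — conservation cycles, bordered influx/outflux chains,
coupled conservative pairs, and the pure two-step G1/M replication motif —
at sizes where the exact invariant sets are known in closed form or can be
enumerated by brute force.  They make every analysis engine testable
without the bundled lymph-node fixture.
"""

from __future__ import annotations

from math import gcd
from functools import reduce

import numpy as np

from .core import Arc, PetriNet, build_net, incidence_matrix

__all__ = [
    "within_bound",
    "make_cycle",
    "make_bordered_chain",
    "make_conservative_pair",
    "make_replication_motif",
    "make_random_net",
    "brute_force_minimal_invariants",
]


def within_bound(invariants, bound: int = 8):
    """Restrict an engine invariant list to the oracle's coefficient box."""
    return [i for i in invariants if max(i.coefficients.values()) <= bound]


def make_cycle(n: int) -> tuple[PetriNet, list[dict], list[dict]]:
    """A ring of n places and n transitions: p0 -> t0 -> p1 -> ... -> p0.

    Expected invariants: exactly one TI (all transitions, coefficient 1) and
    one PI (all places, coefficient 1); the net is conserved.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    places = [f"p{i}" for i in range(n)]
    transitions = [f"t{i}" for i in range(n)]
    arcs = []
    for i in range(n):
        arcs.append(Arc(f"p{i}", f"t{i}"))
        arcs.append(Arc(f"t{i}", f"p{(i + 1) % n}"))
    net = build_net(places, transitions, arcs)
    expected_tis = [{t: 1 for t in transitions}]
    expected_pis = [{p: 1 for p in places}]
    return net, expected_tis, expected_pis


def make_bordered_chain(n: int) -> tuple[PetriNet, list[dict], list[dict]]:
    """Influx -> p1 -> t1 -> ... -> pn -> outflux.

    One TI covering all n+1 transitions with coefficient 1 (flow-through);
    no PI (every place gains from the border influx).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    places = [f"p{i}" for i in range(1, n + 1)]
    transitions = ["t_in"] + [f"t{i}" for i in range(1, n)] + ["t_out"]
    arcs = [Arc("t_in", "p1")]
    for i in range(1, n):
        arcs.append(Arc(f"p{i}", f"t{i}"))
        arcs.append(Arc(f"t{i}", f"p{i + 1}"))
    arcs.append(Arc(f"p{n}", "t_out"))
    net = build_net(places, transitions, arcs)
    expected_tis = [{t: 1 for t in transitions}]
    return net, expected_tis, []


def make_conservative_pair() -> tuple[PetriNet, list[dict], list[dict]]:
    """Two species bound and released by a shared complex place.

    a + b -> ab -> a + b: each species is conserved through the complex, so
    there are two PIs sharing the complex place, and one TI (bind, release).
    """
    net = build_net(
        ["a", "b", "ab"],
        ["bind", "release"],
        [
            ("a", "bind"),
            ("b", "bind"),
            ("bind", "ab"),
            ("ab", "release"),
            ("release", "a"),
            ("release", "b"),
        ],
    )
    expected_tis = [{"bind": 1, "release": 1}]
    expected_pis = [{"a": 1, "ab": 1}, {"b": 1, "ab": 1}]
    return net, expected_tis, expected_pis


def make_replication_motif() -> tuple[PetriNet, dict]:
    """The pure two-step cell-replication motif: a -G1-> a_g1 -M-> 2 a.

    Replication (cell -> 2 cells) with a G1-phase intermediate keeps the net
    pure: no transition has a shared pre- and post-place, yet firing G1 then
    M increases the cell count by one.  Its weight-to-one (ordinary) version
    conserves tokens.
    """
    net = build_net(
        ["a", "a_g1"],
        ["g1", "m"],
        [("a", "g1"), ("g1", "a_g1"), ("a_g1", "m"), ("m", "a", 2)],
    )
    expected = {
        "pure": True,
        "gain_per_round": 1,
        "ordinary_version_conserved": True,
    }
    return net, expected


def make_random_net(
    seed: int,
    *,
    n_places: int = 4,
    n_transitions: int = 4,
    max_weight: int = 2,
    arc_prob: float = 0.35,
) -> PetriNet:
    """A seed-deterministic random bipartite net (no parallel arcs).

    Every transition keeps at least one incident arc so nets stay
    non-degenerate; isolated places are allowed (they are simply uncovered).
    """
    rng = np.random.default_rng(seed)
    places = [f"p{i}" for i in range(n_places)]
    transitions = [f"t{j}" for j in range(n_transitions)]
    arcs: list[Arc] = []
    for t in transitions:
        for p in places:
            if rng.random() < arc_prob:
                arcs.append(Arc(p, t, int(rng.integers(1, max_weight + 1))))
            if rng.random() < arc_prob:
                arcs.append(Arc(t, p, int(rng.integers(1, max_weight + 1))))
        if not any(a.source == t or a.target == t for a in arcs):
            p = places[int(rng.integers(0, n_places))]
            if rng.random() < 0.5:
                arcs.append(Arc(p, t))
            else:
                arcs.append(Arc(t, p))
    return build_net(places, transitions, arcs)


def _minimal_solutions_by_enumeration(
    a: np.ndarray, bound: int
) -> list[tuple[int, ...]]:
    n_vars = a.shape[1]
    # enumerate all (bound+1)**n_vars coefficient vectors in one numpy batch
    grids = np.meshgrid(*([np.arange(bound + 1)] * n_vars), indexing="ij")
    vectors = np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)
    residual = vectors @ np.asarray(a, dtype=np.int64).T
    mask = np.all(residual == 0, axis=1) & np.any(vectors != 0, axis=1)
    sols = []
    for vec in vectors[mask]:
        vec = tuple(int(v) for v in vec)
        g = reduce(gcd, (v for v in vec if v), 0)
        if g > 1:
            continue  # scaled copy of a smaller solution
        sols.append(vec)
    supports = [frozenset(i for i, v in enumerate(s) if v) for s in sols]
    return sorted(
        s
        for s, sup in zip(sols, supports)
        if not any(o < sup for o in supports)
    )


def brute_force_minimal_invariants(
    net: PetriNet, bound: int = 8
) -> tuple[list[dict[str, int]], list[dict[str, int]]]:
    """Brute-force oracle for the minimal TI and PI sets.

    Enumerates every coefficient vector with entries in [0, bound], keeps the
    exact solutions of ``C x = 0`` (resp. ``y C = 0``), and filters to
    gcd-normalised, support-minimal vectors.  Only valid for tiny nets: the
    size caps keep the enumeration around bound**7 vectors.  Invariants with
    any coefficient above ``bound`` are invisible to this oracle, so engine
    results must be restricted to the same box before comparing (see
    :func:`within_bound`).
    """
    if len(net.transition_ids) > 7 or len(net.place_ids) > 7:
        raise ValueError("oracle restricted to nets with at most 7x7 nodes")
    if bound > 8:
        raise ValueError("oracle bound restricted to <= 8")
    c = incidence_matrix(net)
    tis = [
        {net.transition_ids[i]: v for i, v in enumerate(sol) if v}
        for sol in _minimal_solutions_by_enumeration(c, bound)
    ]
    pis = [
        {net.place_ids[i]: v for i, v in enumerate(sol) if v}
        for sol in _minimal_solutions_by_enumeration(c.T, bound)
    ]
    return tis, pis
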