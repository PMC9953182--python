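"""Manatee invariants: feasibility-oriented combinations of transition
invariants.

A transition invariant (TI) is a token-neutral multiset of firings, but it
need not be *executable* from the empty marking: transitions inside it may
require tokens that only other TIs can provide.  A Manatee invariant (MI)
is a sum of TIs whose combined firing multiset can actually be scheduled
starting from the empty marking, minimal in the sense that no proper
sub-combination containing the same seed TI is already feasible.  MIs
therefore capture complete, self-starting functional pathways, including
couplings between pathways that single TIs miss.

Because conserved species (the place-invariant pools) can never receive
tokens from the empty marking, impure MIs are permanently unrealizable
without them; feasibility is therefore judged from a marking that seeds
the PI-covered pool places with sufficient tokens and leaves every other
place empty.  Construction enumerates combinations of distinct TIs
(multiplicity one each) of bounded size, tests realizability of the summed
Parikh vector by depth-first scheduling with memoisation, and keeps the
union over all seed TIs of the inclusion-minimal feasible combinations
containing that seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .core import PetriNet
from .invariants import Invariant

__all__ = [
    "ManateeInvariant",
    "ManateeResourceError",
    "is_realizable",
    "manatee_invariants",
    "classify_mi",
    "mi_summary",
]


class ManateeResourceError(RuntimeError):
    """Raised when the combination size cap is exhausted without closure."""


@dataclass(frozen=True)
class ManateeInvariant:
    label: str
    ti_components: tuple[str, ...]  # labels of member TIs (multiplicity 1)
    coefficients: dict[str, int]  # summed Parikh vector over support

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.coefficients)

    @property
    def length(self) -> int:
        return len(self.coefficients)

    @property
    def n_components(self) -> int:
        return len(self.ti_components)


def _sum_tis(tis: list[Invariant]) -> dict[str, int]:
    out: dict[str, int] = {}
    for ti in tis:
        for t, c in ti.coefficients.items():
            out[t] = out.get(t, 0) + c
    return out


def _startable_closure(net, support, seeded_places):
    """Transitions fireable in the 'species-flow' abstraction: a transition
    can start once every pre-place is seeded or produced by a transition
    that can itself start.  Necessary (not sufficient) for realizability;
    a cheap filter that rejects most infeasible combinations."""
    available = set(seeded_places)
    startable: set[str] = set()
    changed = True
    while changed:
        changed = False
        for t in support:
            if t in startable:
                continue
            if all(p in available for p in net.pre(t)):
                startable.add(t)
                before = len(available)
                available |= set(net.post(t))
                changed = True
    return startable >= set(support)


def is_realizable(
    net: PetriNet,
    parikh: dict[str, int],
    seeded_places: frozenset[str] = frozenset(),
    *,
    max_states: int = 200_000,
) -> bool:
    """Can the firing multiset ``parikh`` be scheduled from a marking that is
    empty except for ample tokens on ``seeded_places``?

    A structural startability fixpoint rejects most infeasible multisets
    outright; a greedy scheduler accepts most feasible ones; the remainder
    is decided exactly by depth-first search over remaining firing counts
    (the marking is a function of the fired counts, so memoising failed
    remainder states is sound).
    """
    order = [t for t in net.transition_ids if parikh.get(t, 0) > 0]
    if not order:
        return True
    if not _startable_closure(net, order, seeded_places):
        return False
    pre = {t: net.pre(t) for t in order}
    post = {t: net.post(t) for t in order}
    demand = {
        p: sum(pre[t].get(p, 0) * parikh[t] for t in order)
        for p in seeded_places
    }

    def initial():
        return (
            {t: parikh[t] for t in order},
            {p: demand.get(p, 0) for p in net.place_ids},
        )

    # greedy fast path: repeatedly fire the first fireable transition,
    # preferring the most-remaining one; success is conclusive
    remaining, marking = initial()
    progress = True
    while progress:
        progress = False
        for t in sorted(order, key=lambda t: -remaining[t]):
            if remaining[t] and all(marking[p] >= w for p, w in pre[t].items()):
                for p, w in pre[t].items():
                    marking[p] -= w
                for p, w in post[t].items():
                    marking[p] += w
                remaining[t] -= 1
                progress = True
        if all(v == 0 for v in remaining.values()):
            return True

    remaining, marking = initial()
    failed: set[tuple[int, ...]] = set()

    def key() -> tuple[int, ...]:
        return tuple(remaining[t] for t in order)

    def dfs() -> bool:
        if all(v == 0 for v in remaining.values()):
            return True
        k = key()
        if k in failed:
            return False
        if len(failed) > max_states:
            raise ManateeResourceError(
                f"realizability search exceeded {max_states} states"
            )
        for t in order:
            if remaining[t] == 0:
                continue
            if any(marking[p] < w for p, w in pre[t].items()):
                continue
            for p, w in pre[t].items():
                marking[p] -= w
            for p, w in post[t].items():
                marking[p] += w
            remaining[t] -= 1
            if dfs():
                return True
            remaining[t] += 1
            for p, w in post[t].items():
                marking[p] -= w
            for p, w in pre[t].items():
                marking[p] += w
        failed.add(k)
        return False

    return dfs()


def manatee_invariants(
    net: PetriNet,
    tis: list[Invariant],
    pis: list[Invariant] | None = None,
    *,
    max_components: int = 4,
    max_feasibility_checks: int = 200_000,
) -> list[ManateeInvariant]:
    """The complete MI set for a net with TI set ``tis``.

    ``pis`` are the place invariants of the full net; places in their
    supports form conserved pools that no TI can fill from outside, so they
    are treated as supplied when judging feasibility.  Combinations of up to
    ``max_components`` distinct TIs are tested for realizability; an MI is a
    feasible combination that is inclusion-minimal among the feasible
    combinations containing at least one of its member TIs.  Every TI must
    appear in some MI within the cap, otherwise a
    :class:`ManateeResourceError` is raised.
    """
    n = len(tis)
    pool = frozenset().union(*(pi.support for pi in pis)) if pis else frozenset()
    feasible: list[frozenset[int]] = []
    checks = 0
    for size in range(1, max_components + 1):
        for combo in combinations(range(n), size):
            cset = frozenset(combo)
            # skip supersets of known feasible combos: they can never be
            # minimal for any seed they share, and for a new seed i the
            # subset would have to be infeasible; supersets of feasible sets
            # are still candidates for seeds outside the subset, so only
            # skip when every element is covered by a feasible subset.
            subs = [f for f in feasible if f < cset]
            if subs and set().union(*subs) >= cset:
                continue
            checks += 1
            if checks > max_feasibility_checks:
                raise ManateeResourceError(
                    f"exceeded {max_feasibility_checks} feasibility checks"
                )
            parikh = _sum_tis([tis[i] for i in combo])
            if is_realizable(net, parikh, pool):
                feasible.append(cset)

    # minimality per seed, union over seeds
    kept: set[frozenset[int]] = set()
    for i in range(n):
        containing = [f for f in feasible if i in f]
        for f in containing:
            if not any(g < f for g in containing):
                kept.add(f)
    uncovered = [tis[i].label for i in range(n) if not any(i in f for f in kept)]
    if uncovered:
        raise ManateeResourceError(
            f"no feasible combination of <= {max_components} TIs covers {uncovered}"
        )
    ordered = sorted(
        kept, key=lambda f: (len(f), sorted(tis[i].label for i in f))
    )
    mis = []
    for k, f in enumerate(ordered):
        members = sorted(f)
        mis.append(
            ManateeInvariant(
                label=f"MI-{k}",
                ti_components=tuple(tis[i].label for i in members),
                coefficients=_sum_tis([tis[i] for i in members]),
            )
        )
    return mis


def induced_subnet(net: PetriNet, mi: ManateeInvariant) -> tuple[set[str], set[str]]:
    """Transitions of the MI support plus all their pre- and post-places."""
    transitions = set(mi.support)
    places: set[str] = set()
    for t in transitions:
        places |= set(net.pre(t)) | set(net.post(t))
    return places, transitions


def _subnet_has_pi(net: PetriNet, places: set[str], transitions: set[str]) -> bool:
    """Does the induced subnet, taken as a net of its own, admit any
    semi-positive place invariant?"""
    from .core import PetriNet as _PN, Arc as _Arc
    from .invariants import place_invariants as _pis

    sub_places = [p for p in net.places if p.id in places]
    sub_transitions = [t for t in net.transitions if t.id in transitions]
    sub_arcs = [
        _Arc(a.source, a.target, a.weight)
        for a in net.arcs
        if (a.source in places and a.target in transitions)
        or (a.source in transitions and a.target in places)
    ]
    sub = _PN(sub_places, sub_transitions, sub_arcs,
              {p: 0 for p in places})
    return bool(_pis(sub))


def classify_mi(
    mi: ManateeInvariant,
    net: PetriNet,
    pis: list[Invariant] | None = None,
    *,
    antibody_place: str = "AB_TIS",
) -> tuple[bool, bool, int]:
    """(is_pure, produces_antibody, length) for one MI.

    An MI is *pure* when its induced subnet, considered as a net of its
    own, has no place invariant: nothing in the pathway is conserved, so
    it can in principle run from the empty marking.  Impure MIs induce a
    subnet with at least one place invariant and depend on pre-existing
    tokens on it.  ``produces_antibody`` flags MIs with a transition
    producing onto the antibody place.
    """
    places, transitions = induced_subnet(net, mi)
    is_pure = not _subnet_has_pi(net, places, transitions)
    produces_ab = any(antibody_place in net.post(t) for t in transitions)
    return is_pure, produces_ab, mi.length


def mi_summary(
    mis: list[ManateeInvariant],
    net: PetriNet,
    pis: list[Invariant] | None = None,
    *,
    antibody_place: str = "AB_TIS",
    antigen_input: str = "IN_AG_TIS",
):
    """One row per MI: label, length, components, purity, antibody output,
    and whether the MI consumes invading antigen."""
    import pandas as pd

    rows = []
    for mi in mis:
        pure, ab, length = classify_mi(mi, net, antibody_place=antibody_place)
        rows.append(
            {
                "label": mi.label,
                "length": length,
                "n_components": mi.n_components,
                "components": "+".join(mi.ti_components),
                "is_pure": pure,
                "produces_antibody": ab,
                "eliminates_antigen": antigen_input in mi.support,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "length",
            "n_components",
            "components",
            "is_pure",
            "produces_antibody",
            "eliminates_antigen",
        ],
    )
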