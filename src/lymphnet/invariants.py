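"""Minimal semi-positive place and transition invariants.

A transition invariant (TI) is a semi-positive integer vector x over the
transitions with ``C @ x = 0`` (a Parikh vector: firing every transition t
exactly x(t) times reproduces the start marking).  A place invariant (PI) is
a semi-positive integer vector y over the places with ``y @ C = 0``; the
weighted token sum ``sum y(p) * m(p)`` is then conserved by every firing.

Both are computed by Farkas/Fourier–Motzkin elimination on ``[A | I]`` with
exact Python integers, gcd normalisation, and support-minimality filtering
after every elimination step — the standard algorithm for the minimal
generating set of semi-positive solutions of ``A x = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd
from functools import reduce

import numpy as np

from .core import PetriNet, incidence_matrix

__all__ = [
    "Invariant",
    "CoverageReport",
    "InvariantResourceError",
    "minimal_semipositive_solutions",
    "transition_invariants",
    "place_invariants",
    "coverage",
    "classify_tis",
]


class InvariantResourceError(RuntimeError):
    """Raised when the intermediate row count exceeds the configured cap."""


@dataclass(frozen=True)
class Invariant:
    """A minimal semi-positive invariant vector.

    ``kind`` is "TI" (coefficients over transitions) or "PI" (over places).
    ``coefficients`` maps node id -> positive integer over the support only;
    nodes outside the support carry coefficient 0.
    """

    kind: str
    label: str
    coefficients: dict[str, int]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.coefficients)

    @property
    def length(self) -> int:
        return len(self.coefficients)

    def vector(self, order: list[str]) -> np.ndarray:
        return np.array([self.coefficients.get(n, 0) for n in order], dtype=np.int64)

    def __contains__(self, node: str) -> bool:
        return node in self.coefficients


@dataclass(frozen=True)
class CoverageReport:
    kind: str
    covered: dict[str, bool]
    fully_covered: bool


def _normalize(vec: tuple[int, ...]) -> tuple[int, ...]:
    g = reduce(gcd, (v for v in vec if v), 0)
    if g > 1:
        return tuple(v // g for v in vec)
    return vec


def _support(vec: tuple[int, ...]) -> frozenset[int]:
    return frozenset(i for i, v in enumerate(vec) if v)


def _prune_nonminimal(rows: list[tuple[tuple[int, ...], tuple[int, ...]]]):
    """Drop duplicate rows and rows whose solution-part support strictly
    contains another row's support (they cannot lead to minimal invariants).
    """
    rows = list(dict.fromkeys(rows))
    supports = [(_support(sol), i) for i, (_, sol) in enumerate(rows)]
    supports.sort(key=lambda si: (len(si[0]), si[1]))
    kept: list[int] = []
    kept_supports: list[frozenset[int]] = []
    for sup, i in supports:
        if any(ks < sup for ks in kept_supports):
            continue
        kept.append(i)
        kept_supports.append(sup)
    kept.sort()
    return [rows[i] for i in kept]


def minimal_semipositive_solutions(
    a: np.ndarray, *, max_rows: int = 2_000_000
) -> list[tuple[int, ...]]:
    """All support-minimal semi-positive integer solutions of ``a @ x = 0``.

    Farkas elimination: start from ``[a.T | I]`` (one row per variable);
    eliminate the constraint columns one at a time by taking positive
    combinations of rows with opposite signs; keep rows already satisfying
    the column; prune non-support-minimal rows after each step.  Returns
    gcd-normalised coefficient tuples (length = number of variables) in a
    deterministic order (sorted by support, then coefficients).

    ``max_rows`` caps the intermediate row count; exceeding it raises
    :class:`InvariantResourceError` rather than thrashing.
    """
    a = np.asarray(a, dtype=object)
    if a.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n_constraints, n_vars = a.shape
    # rows: (constraint part (being zeroed), solution part)
    rows: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    for j in range(n_vars):
        cons = tuple(int(a[i, j]) for i in range(n_constraints))
        sol = tuple(1 if k == j else 0 for k in range(n_vars))
        rows.append((cons, sol))

    for col in range(n_constraints):
        zero, pos, neg = [], [], []
        for cons, sol in rows:
            v = cons[col]
            if v == 0:
                zero.append((cons, sol))
            elif v > 0:
                pos.append((cons, sol))
            else:
                neg.append((cons, sol))
        if len(zero) + len(pos) * len(neg) > max_rows:
            raise InvariantResourceError(
                f"elimination exceeds {max_rows} intermediate rows at column {col}"
            )
        new_rows = zero
        for cons_p, sol_p in pos:
            vp = cons_p[col]
            for cons_n, sol_n in neg:
                vn = -cons_n[col]
                cons = tuple(vn * cp + vp * cn for cp, cn in zip(cons_p, cons_n))
                sol = tuple(vn * sp + vp * sn for sp, sn in zip(sol_p, sol_n))
                g = reduce(gcd, (v for v in sol if v), 0)
                if g > 1:
                    cons = tuple(v // g for v in cons)
                    sol = tuple(v // g for v in sol)
                new_rows.append((cons, sol))
        rows = _prune_nonminimal(new_rows)

    sols = sorted(
        {_normalize(sol) for _, sol in rows if any(sol)},
        key=lambda s: (sorted(_support(s)), s),
    )
    # final minimality guard (prune is per-step; cheap at this size)
    sups = [_support(s) for s in sols]
    keep = [
        s
        for s, sup in zip(sols, sups)
        if not any(o < sup for o in sups)
    ]
    return keep


def _to_invariants(
    sols: list[tuple[int, ...]], order: list[str], kind: str
) -> list[Invariant]:
    invs = []
    ordered = sorted(
        sols, key=lambda s: (sorted(order[i] for i in _support(s)), s)
    )
    for k, sol in enumerate(ordered):
        coeff = {order[i]: v for i, v in enumerate(sol) if v}
        invs.append(Invariant(kind=kind, label=f"{kind}-{k}", coefficients=coeff))
    return invs


def transition_invariants(net: PetriNet, *, max_rows: int = 2_000_000) -> list[Invariant]:
    """The complete minimal TI set of a net, ordered by sorted support ids."""
    c = incidence_matrix(net)
    sols = minimal_semipositive_solutions(c, max_rows=max_rows)
    return _to_invariants(sols, net.transition_ids, "TI")


def place_invariants(net: PetriNet, *, max_rows: int = 2_000_000) -> list[Invariant]:
    """The complete minimal PI set of a net (transposed problem)."""
    c = incidence_matrix(net)
    sols = minimal_semipositive_solutions(c.T, max_rows=max_rows)
    return _to_invariants(sols, net.place_ids, "PI")


def coverage(net: PetriNet, invariants: list[Invariant]) -> CoverageReport:
    """Node coverage: a node is covered iff it lies in some invariant support.

    For TIs full coverage is the CTI property, for PIs the CPI property.
    """
    kinds = {inv.kind for inv in invariants}
    if len(kinds) > 1:
        raise ValueError(f"mixed invariant kinds: {sorted(kinds)}")
    kind = kinds.pop() if kinds else "TI"
    nodes = net.transition_ids if kind == "TI" else net.place_ids
    known = set(nodes)
    for inv in invariants:
        stray = inv.support - known
        if stray:
            raise ValueError(f"invariant {inv.label} names unknown nodes {sorted(stray)}")
    in_support = set().union(*(inv.support for inv in invariants)) if invariants else set()
    covered = {n: n in in_support for n in nodes}
    return CoverageReport(kind=kind, covered=covered, fully_covered=all(covered.values()))


def classify_tis(invariants: list[Invariant]) -> dict:
    """Partition TIs into trivial (length 2) and non-trivial, with stats."""
    trivial = [inv for inv in invariants if inv.length == 2]
    nontrivial = [inv for inv in invariants if inv.length != 2]
    lengths = sorted(inv.length for inv in nontrivial)
    return {
        "trivial": trivial,
        "nontrivial": nontrivial,
        "n_trivial": len(trivial),
        "n_nontrivial": len(nontrivial),
        "min_nontrivial_length": lengths[0] if lengths else None,
        "max_nontrivial_length": lengths[-1] if lengths else None,
    }
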