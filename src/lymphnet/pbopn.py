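"""Place-bordered ordinary net (PBOPN) reduction.

For conservation auditing, the model is reduced to a net without border
transitions (no influx, outflux or death events) and with all arc weights
set to one (no replication).  In this reduced net every cell species should
be conserved: each place should lie on a place invariant with a clear
biological reading.  The antibody place is the documented exception; after
additionally deleting antibody production the net must be conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Arc, PetriNet, PetriNetError, build_net

__all__ = ["ReductionRecord", "to_pbopn", "delete_antibody_production"]

ANTIBODY_PLACE = "AB_TIS"


@dataclass(frozen=True)
class ReductionRecord:
    """What the PBOPN reduction removed or rewrote."""

    removed_transitions: tuple[str, ...]
    weight_changes: tuple[tuple[Arc, int], ...]  # (new unit arc, old weight)
    deleted_arcs: tuple[Arc, ...]

    def to_frame(self):
        import pandas as pd

        rows = [
            {"kind": "removed_transition", "item": t, "old_weight": ""}
            for t in self.removed_transitions
        ]
        rows += [
            {"kind": "weight_change", "item": f"{a.source}->{a.target}", "old_weight": w}
            for a, w in self.weight_changes
        ]
        rows += [
            {"kind": "deleted_arc", "item": f"{a.source}->{a.target}", "old_weight": a.weight}
            for a in self.deleted_arcs
        ]
        return pd.DataFrame(rows, columns=["kind", "item", "old_weight"])


def to_pbopn(net: PetriNet) -> tuple[PetriNet, ReductionRecord]:
    """Reduce a net to its place-bordered ordinary form.

    Border transitions (empty pre- or post-set) are deleted together with
    their arcs, and every remaining arc weight is set to one.  Places are
    untouched.  Border removal is applied once, not iterated: deleting a
    transition cannot create a new border transition.
    """
    border = {
        t.id
        for t in net.transitions
        if not net.pre(t.id) or not net.post(t.id)
    }
    kept_transitions = [t for t in net.transitions if t.id not in border]
    deleted = tuple(a for a in net.arcs if a.source in border or a.target in border)
    new_arcs, changes = [], []
    for a in net.arcs:
        if a.source in border or a.target in border:
            continue
        unit = Arc(a.source, a.target, 1)
        if a.weight != 1:
            changes.append((unit, a.weight))
        new_arcs.append(unit)
    reduced = PetriNet(net.places, kept_transitions, new_arcs, dict(net.initial_marking))
    record = ReductionRecord(
        removed_transitions=tuple(sorted(border)),
        weight_changes=tuple(changes),
        deleted_arcs=deleted,
    )
    return reduced, record


def delete_antibody_production(
    pbopn_net: PetriNet, place: str = ANTIBODY_PLACE
) -> PetriNet:
    """Remove every arc producing onto the antibody place.

    The place itself stays in the net.  Applying the operation twice is a
    no-op.  Raises if the place does not exist.
    """
    if place not in pbopn_net.place_ids:
        raise PetriNetError(f"place {place!r} not in net; nothing to delete")
    arcs = [
        a
        for a in pbopn_net.arcs
        if not (a.target == place and pbopn_net.is_transition(a.source))
    ]
    return PetriNet(
        pbopn_net.places,
        pbopn_net.transitions,
        arcs,
        dict(pbopn_net.initial_marking),
    )
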