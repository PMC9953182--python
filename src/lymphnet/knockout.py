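"""In-silico knockout analysis based on Manatee invariants.

Knocking out a transition removes every MI that uses it.  A target place is
*affected* when no surviving MI contains a transition producing tokens onto
it: the species can no longer be produced by any self-starting pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import PetriNet, PetriNetError
from .manatee import ManateeInvariant

__all__ = ["KnockoutMatrix", "knockout_matrix", "full_knockout_screen"]

AFFECTED = "affected"
UNAFFECTED = "unaffected"


@dataclass(frozen=True)
class KnockoutMatrix:
    rows: tuple[str, ...]  # knocked-out transitions
    columns: tuple[str, ...]  # target places
    effect: dict[tuple[str, str], str]

    def __getitem__(self, key: tuple[str, str]) -> str:
        return self.effect[key]

    def affected(self, transition: str, place: str) -> bool:
        return self.effect[(transition, place)] == AFFECTED

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [[self.effect[(t, p)] for p in self.columns] for t in self.rows],
            index=list(self.rows),
            columns=list(self.columns),
        )

    def plot(self, ax=None):
        """Red/green dot matrix: red = production no longer possible."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(
                figsize=(1.2 + 0.6 * len(self.columns), 1.0 + 0.5 * len(self.rows))
            )
        for i, t in enumerate(self.rows):
            for j, p in enumerate(self.columns):
                color = "tab:red" if self.affected(t, p) else "tab:green"
                ax.scatter(j, len(self.rows) - 1 - i, s=220, c=color, edgecolors="k")
        ax.set_xticks(range(len(self.columns)), self.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(self.rows)), list(reversed(self.rows)))
        ax.set_xlim(-0.6, len(self.columns) - 0.4)
        ax.set_ylim(-0.6, len(self.rows) - 0.4)
        ax.set_title("In-silico knockout (red: production lost)")
        return ax


def _producers(net: PetriNet, place: str) -> set[str]:
    return {t for t, _w in net.pre(place).items()}


def knockout_matrix(
    net: PetriNet,
    mis: Sequence[ManateeInvariant],
    knocked: Iterable[str],
    targets: Iterable[str],
) -> KnockoutMatrix:
    """Effect of single-transition knockouts on production of target places.

    ``knocked`` may also contain tuples of transitions for combined
    knockouts; the entry key is then the '+'-joined id string.
    """
    knocked = list(knocked)
    targets = list(targets)
    for p in targets:
        if not net.is_place(p):
            raise PetriNetError(f"unknown target place {p!r}")
    effect: dict[tuple[str, str], str] = {}
    row_ids = []
    for k in knocked:
        kset = {k} if isinstance(k, str) else set(k)
        for t in kset:
            if not net.is_transition(t):
                raise PetriNetError(f"unknown transition {t!r}")
        row = "+".join(sorted(kset)) if not isinstance(k, str) else k
        row_ids.append(row)
        surviving = [mi for mi in mis if not (kset & mi.support)]
        for p in targets:
            producers = _producers(net, p)
            alive = any(producers & mi.support for mi in surviving)
            effect[(row, p)] = UNAFFECTED if alive else AFFECTED
    return KnockoutMatrix(tuple(row_ids), tuple(targets), effect)


def full_knockout_screen(
    net: PetriNet, mis: Sequence[ManateeInvariant]
) -> KnockoutMatrix:
    """Single-transition knockouts for every transition against every place."""
    return knockout_matrix(net, mis, net.transition_ids, net.place_ids)
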