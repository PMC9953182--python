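"""The bundled lymph-node model and its construction checks.

The model encodes the adaptive immune response of a human lymph node as a
place/transition net: antigen invades the tissue, subcapsular-sinus
macrophages capture it and hand it via antigen-presenting cells to T cells,
activated T cells recruit B cells into the light zone, activated B cells
proliferate in the dark zone, differentiate over the germinal center into
plasma cells that migrate through the medulla and blood into the tissue,
and plasma cells produce antibodies that opsonize antigen for macrophage
destruction.  Memory B cells replicate in the medulla and sustain the
response after the antigen wave has passed.

Two formal construction conditions are enforced by :func:`validate_model`:

1. the net is covered by transition invariants (CTI) — every reaction takes
   part in at least one functional mode;
2. in the place-bordered ordinary reduction (PBOPN) every place except the
   antibody place lies on a place invariant, and after deleting antibody
   production the reduction is conservative — no species silently leaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .core import PetriNet, PetriNetError, structural_report
from .invariants import coverage, classify_tis, place_invariants, transition_invariants
from .io import read_pnml
from .pbopn import delete_antibody_production, to_pbopn
from .vocab import load_vocabulary, parse_node_id

__all__ = ["load_model", "validate_model", "ValidationReport", "CountCheck"]

ANTIBODY_PLACE = "AB_TIS"

# printed reference counts for the lymph-node model
EXPECTED = {
    "places": 49,
    "transitions": 65,
    "arcs": 149,
    "input transitions": 2,
    "output transitions": 6,
    "weight-2 arcs": 3,
    "PBOPN places": 49,
    "PBOPN transitions": 57,
    "PBOPN arcs": 141,
    "full-net PIs": 4,
    "full-net TIs": 25,
    "trivial TIs": 13,
    "PBOPN PIs": 10,
    "AB-deleted PBOPN PIs": 12,
}


@dataclass(frozen=True)
class CountCheck:
    name: str
    expected: int
    actual: int

    @property
    def passed(self) -> bool:
        return self.expected == self.actual


@dataclass(frozen=True)
class ValidationReport:
    is_cti: bool
    uncovered_transitions: tuple[str, ...]
    pbopn_pi_coverage: dict[str, bool]
    uncovered_pbopn_places: tuple[str, ...]
    ab_deleted_conservative: bool
    count_checks: tuple[CountCheck, ...]

    @property
    def passed(self) -> bool:
        return (
            self.is_cti
            and self.uncovered_pbopn_places == (ANTIBODY_PLACE,)
            and self.ab_deleted_conservative
            and all(c.passed for c in self.count_checks)
        )


def load_model() -> PetriNet:
    """Load the bundled lymph-node net from its PNML fixture."""
    source = resources.files("lymphnet.data").joinpath("lymph_node.pnml")
    try:
        with resources.as_file(source) as path:
            net = read_pnml(path)
    except FileNotFoundError as exc:
        raise PetriNetError("bundled fixture lymph_node.pnml is missing") from exc
    return net


def validate_model(net: PetriNet | None = None) -> ValidationReport:
    """Run both formal construction conditions and all count checks."""
    if net is None:
        net = load_model()
    sr = structural_report(net)
    tis = transition_invariants(net)
    ti_cov = coverage(net, tis)
    cls = classify_tis(tis)
    pis = place_invariants(net)

    pbopn, _record = to_pbopn(net)
    pb_pis = place_invariants(pbopn)
    pb_cov = coverage(pbopn, pb_pis)
    uncovered_places = tuple(p for p, ok in pb_cov.covered.items() if not ok)

    ab_deleted = delete_antibody_production(pbopn)
    ab_pis = place_invariants(ab_deleted)
    ab_cov = coverage(ab_deleted, ab_pis)

    actuals = {
        "places": len(net.places),
        "transitions": len(net.transitions),
        "arcs": len(net.arcs),
        "input transitions": len(sr.input_transitions),
        "output transitions": len(sr.output_transitions),
        "weight-2 arcs": len(sr.nonunit_arcs),
        "PBOPN places": len(pbopn.places),
        "PBOPN transitions": len(pbopn.transitions),
        "PBOPN arcs": len(pbopn.arcs),
        "full-net PIs": len(pis),
        "full-net TIs": len(tis),
        "trivial TIs": cls["n_trivial"],
        "PBOPN PIs": len(pb_pis),
        "AB-deleted PBOPN PIs": len(ab_pis),
    }
    checks = tuple(
        CountCheck(name, EXPECTED[name], actuals[name]) for name in EXPECTED
    )
    return ValidationReport(
        is_cti=ti_cov.fully_covered,
        uncovered_transitions=tuple(
            t for t, ok in ti_cov.covered.items() if not ok
        ),
        pbopn_pi_coverage=dict(pb_cov.covered),
        uncovered_pbopn_places=uncovered_places,
        ab_deleted_conservative=ab_cov.fully_covered,
        count_checks=checks,
    )


def annotate(net: PetriNet) -> dict[str, object]:
    """Parse every node id against the vocabulary; returns id -> ParsedNodeId.

    Raises if any fixture identifier fails to parse — used as a model
    self-check.
    """
    vocab = load_vocabulary()
    return {
        n: parse_node_id(n, vocab)
        for n in (net.place_ids + net.transition_ids)
    }
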