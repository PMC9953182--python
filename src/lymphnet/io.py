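"""Readers and writers for P/T nets: PNML core dialect and SBML Level 3.

PNML (ISO/IEC 15909-2 core model) is the primary serialization: places with
initial markings, transitions, and weighted arcs.  SBML Level 3 encodes the
same net with species as places, reactions as transitions and integer
stoichiometries as arc weights; fractional stoichiometries are rejected
rather than rounded.  Both round-trip the net losslessly (node order, ids,
labels, weights, initial marking).
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .core import Arc, PetriNet, PetriNetError, PlaceDecl, TransitionDecl

__all__ = ["read_pnml", "write_pnml", "read_sbml", "write_sbml"]

PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"
PNML_NET_TYPE = "http://www.pnml.org/version-2009/grammar/ptnet"
SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


# ---------------------------------------------------------------------------
# PNML


def write_pnml(net: PetriNet, path: str | Path) -> None:
    root = etree.Element(_q(PNML_NS, "pnml"), nsmap={None: PNML_NS})
    netel = etree.SubElement(root, _q(PNML_NS, "net"), id="net0", type=PNML_NET_TYPE)
    page = etree.SubElement(netel, _q(PNML_NS, "page"), id="page0")
    for p in net.places:
        pel = etree.SubElement(page, _q(PNML_NS, "place"), id=p.id)
        name = etree.SubElement(pel, _q(PNML_NS, "name"))
        etree.SubElement(name, _q(PNML_NS, "text")).text = p.label or p.id
        tokens = net.initial_marking[p.id]
        if tokens:
            mk = etree.SubElement(pel, _q(PNML_NS, "initialMarking"))
            etree.SubElement(mk, _q(PNML_NS, "text")).text = str(tokens)
    for t in net.transitions:
        tel = etree.SubElement(page, _q(PNML_NS, "transition"), id=t.id)
        name = etree.SubElement(tel, _q(PNML_NS, "name"))
        etree.SubElement(name, _q(PNML_NS, "text")).text = t.label or t.id
    for k, a in enumerate(net.arcs):
        ael = etree.SubElement(
            page, _q(PNML_NS, "arc"), id=f"a{k}", source=a.source, target=a.target
        )
        if a.weight != 1:
            ins = etree.SubElement(ael, _q(PNML_NS, "inscription"))
            etree.SubElement(ins, _q(PNML_NS, "text")).text = str(a.weight)
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def read_pnml(path: str | Path) -> PetriNet:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise PetriNetError(f"malformed PNML {path}: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "pnml":
        raise PetriNetError(f"{path}: root element is <{root.tag}>, expected <pnml>")
    places: list[PlaceDecl] = []
    transitions: list[TransitionDecl] = []
    arcs: list[Arc] = []
    marking: dict[str, int] = {}

    def text_of(el, tag: str) -> str | None:
        child = el.find(f"{_q(PNML_NS, tag)}/{_q(PNML_NS, 'text')}")
        return None if child is None else child.text

    for el in root.iter():
        tag = etree.QName(el).localname
        if tag == "place":
            pid = el.get("id")
            places.append(PlaceDecl(pid, label=text_of(el, "name") or pid))
            raw = text_of(el, "initialMarking")
            marking[pid] = int(raw) if raw else 0
        elif tag == "transition":
            tid = el.get("id")
            transitions.append(TransitionDecl(tid, label=text_of(el, "name") or tid))
        elif tag == "arc":
            raw = text_of(el, "inscription")
            weight = int(raw) if raw else 1
            arcs.append(Arc(el.get("source"), el.get("target"), weight))
    return PetriNet(places, transitions, arcs, marking)


# ---------------------------------------------------------------------------
# SBML


def write_sbml(net: PetriNet, path: str | Path) -> None:
    root = etree.Element(
        _q(SBML_NS, "sbml"), nsmap={None: SBML_NS}, level="3", version="1"
    )
    model = etree.SubElement(root, _q(SBML_NS, "model"), id="net0")
    comps = etree.SubElement(model, _q(SBML_NS, "listOfCompartments"))
    etree.SubElement(
        comps, _q(SBML_NS, "compartment"), id="default", constant="true"
    )
    species_el = etree.SubElement(model, _q(SBML_NS, "listOfSpecies"))
    for p in net.places:
        etree.SubElement(
            species_el,
            _q(SBML_NS, "species"),
            id=p.id,
            name=p.label or p.id,
            compartment="default",
            initialAmount=str(net.initial_marking[p.id]),
            hasOnlySubstanceUnits="true",
            boundaryCondition="false",
            constant="false",
        )
    reactions_el = etree.SubElement(model, _q(SBML_NS, "listOfReactions"))
    for t in net.transitions:
        rel = etree.SubElement(
            reactions_el,
            _q(SBML_NS, "reaction"),
            id=t.id,
            name=t.label or t.id,
            reversible="false",
            fast="false",
        )
        pre, post = net.pre(t.id), net.post(t.id)
        if pre:
            lor = etree.SubElement(rel, _q(SBML_NS, "listOfReactants"))
            for p, w in pre.items():
                etree.SubElement(
                    lor,
                    _q(SBML_NS, "speciesReference"),
                    species=p,
                    stoichiometry=str(w),
                    constant="true",
                )
        if post:
            lop = etree.SubElement(rel, _q(SBML_NS, "listOfProducts"))
            for p, w in post.items():
                etree.SubElement(
                    lop,
                    _q(SBML_NS, "speciesReference"),
                    species=p,
                    stoichiometry=str(w),
                    constant="true",
                )
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _stoich(ref) -> int:
    raw = ref.get("stoichiometry", "1")
    value = float(raw)
    if value != int(value):
        raise PetriNetError(
            f"non-integer stoichiometry {raw!r} for species {ref.get('species')!r}"
        )
    if value < 1:
        raise PetriNetError(
            f"stoichiometry {raw!r} < 1 for species {ref.get('species')!r}"
        )
    return int(value)


def read_sbml(path: str | Path) -> PetriNet:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise PetriNetError(f"malformed SBML {path}: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise PetriNetError(f"{path}: root element is <{root.tag}>, expected <sbml>")
    ns = etree.QName(root).namespace
    model = root.find(_q(ns, "model"))
    if model is None:
        raise PetriNetError(f"{path}: no <model> element")
    places, marking = [], {}
    for sp in model.findall(f"{_q(ns, 'listOfSpecies')}/{_q(ns, 'species')}"):
        pid = sp.get("id")
        places.append(PlaceDecl(pid, label=sp.get("name") or pid))
        amount = float(sp.get("initialAmount", "0") or 0)
        if amount != int(amount) or amount < 0:
            raise PetriNetError(f"species {pid!r}: invalid initialAmount {amount}")
        marking[pid] = int(amount)
    transitions, arcs = [], []
    for rx in model.findall(f"{_q(ns, 'listOfReactions')}/{_q(ns, 'reaction')}"):
        tid = rx.get("id")
        transitions.append(TransitionDecl(tid, label=rx.get("name") or tid))
        for ref in rx.findall(f"{_q(ns, 'listOfReactants')}/{_q(ns, 'speciesReference')}"):
            arcs.append(Arc(ref.get("species"), tid, _stoich(ref)))
        for ref in rx.findall(f"{_q(ns, 'listOfProducts')}/{_q(ns, 'speciesReference')}"):
            arcs.append(Arc(tid, ref.get("species"), _stoich(ref)))
    return PetriNet(places, transitions, arcs, marking)
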