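"""Annotation vocabulary (compartments, species, processes) and the node-id
grammar.

Identifiers follow a compositional scheme:

* places: ``SPECIES[_SPECIES...][_QUALIFIER]_COMPARTMENT`` — the species
  codes of every cell or molecule held by the place (complexes list all
  constituents), an optional state qualifier (``G1`` for a replication-phase
  intermediate, ``D`` for degraded material), and the compartment.
* transitions: ``PROCESS_SPECIES..._COMPARTMENT[_COMPARTMENT]`` — a process
  code, the species involved (``with`` or ``-`` join interacting partners),
  and one compartment, or two for translocations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["AnnotationVocabulary", "ParsedNodeId", "load_vocabulary", "parse_node_id"]


class NodeIdError(ValueError):
    """Raised when an identifier does not parse against the vocabulary."""


@dataclass(frozen=True)
class ParsedNodeId:
    kind: str  # "place" | "transition"
    process: str | None
    species: tuple[str, ...]
    compartments: tuple[str, ...]
    qualifiers: tuple[str, ...] = ()


@dataclass(frozen=True)
class AnnotationVocabulary:
    compartments: dict[str, str]
    species: dict[str, dict]
    processes: dict[str, dict]
    qualifiers: dict[str, str]

    def species_name(self, code: str) -> str:
        return self.species[code]["name"]


def load_vocabulary(path: str | Path | None = None) -> AnnotationVocabulary:
    """Load the bundled vocabulary, or one from an explicit YAML file."""
    if path is None:
        source = resources.files("lymphnet.data").joinpath("vocabulary.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return AnnotationVocabulary(
        compartments=dict(raw["compartments"]),
        species={k: dict(v) for k, v in raw["species"].items()},
        processes={k: dict(v) for k, v in raw["processes"].items()},
        qualifiers=dict(raw.get("qualifiers", {})),
    )


def parse_node_id(node_id: str, vocabulary: AnnotationVocabulary) -> ParsedNodeId:
    """Decompose a node id into process, species and compartment codes.

    Raises :class:`NodeIdError` naming the offending token on failure.
    """
    tokens: list[str] = []
    for raw in node_id.split("_"):
        tokens.extend(raw.split("-"))
    if not tokens:
        raise NodeIdError(f"empty identifier {node_id!r}")

    process = None
    kind = "place"
    if tokens[0] in vocabulary.processes and tokens[0] not in vocabulary.species:
        kind = "transition"
        process = tokens[0]
        tokens = tokens[1:]

    compartments: list[str] = []
    while tokens and tokens[-1] in vocabulary.compartments:
        compartments.insert(0, tokens.pop())
        if kind == "place" or len(compartments) == 2:
            break
    if not compartments:
        raise NodeIdError(f"{node_id!r}: no trailing compartment code")
    if kind == "place" and len(compartments) != 1:
        raise NodeIdError(f"{node_id!r}: places carry exactly one compartment")
    if len(compartments) == 2 and process != "TRA":
        raise NodeIdError(f"{node_id!r}: only translocations span two compartments")

    species: list[str] = []
    qualifiers: list[str] = []
    for tok in tokens:
        if tok == "with":
            continue
        if tok in vocabulary.species:
            species.append(tok)
        elif tok in vocabulary.qualifiers:
            qualifiers.append(tok)
        else:
            raise NodeIdError(f"{node_id!r}: unknown token {tok!r}")
    if kind == "place" and not species:
        raise NodeIdError(f"{node_id!r}: place names at least one species")
    if kind == "transition" and process not in ("IN", "OUT") and not species:
        raise NodeIdError(f"{node_id!r}: transition names at least one species")
    return ParsedNodeId(
        kind=kind,
        process=process,
        species=tuple(species),
        compartments=tuple(compartments),
        qualifiers=tuple(qualifiers),
    )
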