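"""The bundled lymph-node model: printed counts, vocabulary, validation."""

import pytest

from lymphnet.core import structural_report
from lymphnet.invariants import classify_tis, coverage
from lymphnet.model import annotate, load_model, validate_model
from lymphnet.vocab import NodeIdError, load_vocabulary, parse_node_id


def test_model_dimensions(model):
    assert len(model.places) == 49
    assert len(model.transitions) == 65
    assert len(model.arcs) == 149


def test_model_structural_predicates(model):
    sr = structural_report(model)
    assert sr.is_pure and sr.is_connected
    assert not sr.is_ordinary and not sr.is_conserved
    assert not sr.is_strongly_connected
    assert set(sr.input_transitions) == {"IN_AG_TIS", "IN_B_BL"}
    assert len(sr.output_transitions) == 6
    assert len(sr.nonunit_arcs) == 3
    assert all(a.weight == 2 for a in sr.nonunit_arcs)


def test_weight_two_arcs_are_the_replication_and_elimination_arcs(model):
    sr = structural_report(model)
    arcs = {(a.source, a.target) for a in sr.nonunit_arcs}
    assert arcs == {
        ("M_B1_DZ", "B1_DZ"),       # mitosis of activated B cells
        ("M_B3_ME", "B3_ME"),       # mitosis of memory B cells
        ("B1_DZ", "ENC_M_with_B1_DZ"),  # macrophage engulfs two B1 cells
    }


def test_antibody_release_produces_onto_ab_tis(model):
    assert "AB_TIS" in model.post("REL_AB_TIS")


def test_no_place_lacks_both_pre_and_post_transition(model):
    for p in model.place_ids:
        assert model.pre(p) or model.post(p)


def test_empty_marking_enables_exactly_the_input_transitions(model):
    from lymphnet.core import enabled

    m = model.empty_marking()
    live = {t for t in model.transition_ids if enabled(model, m, t)}
    assert live == {"IN_AG_TIS", "IN_B_BL"}


def test_model_is_cti_with_25_tis(model, model_tis):
    assert len(model_tis) == 25
    assert coverage(model, model_tis).fully_covered
    cls = classify_tis(model_tis)
    assert cls["n_trivial"] == 13
    assert cls["min_nontrivial_length"] == 5
    assert cls["max_nontrivial_length"] == 28


def test_antibody_production_ti_has_eight_transitions(model_tis):
    ab_tis = [
        ti for ti in model_tis
        if "REL_AB_TIS" in ti.support and "IN_AG_TIS" in ti.support
    ]
    assert len(ab_tis) == 1
    assert ab_tis[0].length == 8


def test_four_pis_are_the_conserved_cell_species(model, model_pis):
    """Each full-net PI collects exactly the places holding one conserved
    species (macrophages, T cells, dendritic cells, APCs), complexes
    included."""
    vocab = load_vocabulary()
    assert len(model_pis) == 4
    tracked = set()
    for pi in model_pis:
        species_sets = [set(parse_node_id(p, vocab).species) for p in pi.support]
        common = set.intersection(*species_sets)
        conserved = common & {"M", "T", "DC", "APC"}
        assert len(conserved) == 1, f"PI without unique conserved species: {pi.support}"
        code = conserved.pop()
        tracked.add(code)
        # the support is complete: every place containing the species is in it
        carriers = {
            p for p in model.place_ids
            if code in parse_node_id(p, vocab).species
        }
        assert pi.support == frozenset(carriers)
    assert tracked == {"M", "T", "DC", "APC"}


def test_every_identifier_parses_against_vocabulary(model):
    parsed = annotate(model)
    assert len(parsed) == 49 + 65
    assert parsed["B3_ME"].species == ("B3",)
    assert parsed["B3_ME"].compartments == ("ME",)
    assert parsed["IN_AG_TIS"].process == "IN"
    assert parsed["IN_AG_TIS"].species == ("AG",)
    assert parsed["ENC_M_with_B1_DZ"].process == "ENC"
    assert set(parsed["ENC_M_with_B1_DZ"].species) == {"M", "B1"}
    assert parsed["SEP_M-AG-AB_TIS"].species == ("M", "AG", "AB")
    assert parsed["TRA_B_BL_TZ"].compartments == ("BL", "TZ")


def test_unparseable_ids_are_rejected():
    vocab = load_vocabulary()
    with pytest.raises(NodeIdError, match="XX"):
        parse_node_id("ENC_XX_TZ", vocab)
    with pytest.raises(NodeIdError, match="compartment"):
        parse_node_id("ENC_M_with_AG", vocab)


def test_validation_report_all_checks_pass(model):
    report = validate_model(model)
    assert report.is_cti
    assert report.uncovered_transitions == ()
    assert report.uncovered_pbopn_places == ("AB_TIS",)
    assert report.ab_deleted_conservative
    failed = [c for c in report.count_checks if not c.passed]
    assert not failed, f"failed count checks: {failed}"
    assert report.passed


def test_load_model_identical_on_reload(model):
    again = load_model()
    assert again.place_ids == model.place_ids
    assert again.transition_ids == model.transition_ids
    assert sorted((a.source, a.target, a.weight) for a in again.arcs) == sorted(
        (a.source, a.target, a.weight) for a in model.arcs
    )
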