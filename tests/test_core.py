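"""P/T-net kernel: construction, firing rule, incidence, structural report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lymphnet.core import (
    Arc,
    Marking,
    PetriNetError,
    build_net,
    enabled,
    fire,
    incidence_matrix,
    structural_report,
)
from lymphnet.synthetic import make_cycle, make_random_net


def test_minimal_net_pre_post_sets():
    net = build_net(["a"], ["t"], [("a", "t")])
    assert net.pre("t") == {"a": 1}
    assert net.post("t") == {}
    assert net.post("a") == {"t": 1}


@pytest.mark.parametrize(
    "places, transitions, arcs, message",
    [
        (["a", "a"], ["t"], [], "duplicate"),
        (["a"], ["a"], [], "overlap"),
        (["a", "b"], ["t"], [("a", "b")], "place-to-place"),
        (["a"], ["t", "u"], [("t", "u")], "transition-to-transition"),
        (["a"], ["t"], [("a", "t"), ("a", "t")], "parallel"),
        (["a"], ["t"], [("a", "x")], "endpoint"),
    ],
)
def test_invalid_nets_rejected(places, transitions, arcs, message):
    with pytest.raises(PetriNetError, match=message):
        build_net(places, transitions, arcs)


def test_nonpositive_weight_rejected():
    with pytest.raises(PetriNetError, match="weight"):
        Arc("a", "t", 0)


def test_marking_is_total_and_nonnegative():
    net = build_net(["a", "b"], ["t"], [("a", "t")])
    with pytest.raises(PetriNetError):
        Marking({"a": -1, "b": 0})
    with pytest.raises(PetriNetError):
        net.marking({"z": 1})
    m = net.marking({"a": 2})
    assert m["b"] == 0 and m.total() == 2


def test_incidence_matrix_single_transfer():
    net = build_net(["a", "b"], ["t"], [("a", "t"), ("t", "b")])
    c = incidence_matrix(net)
    assert c.tolist() == [[-1], [1]]


def test_incidence_against_per_arc_summation_oracle():
    for seed in range(100):
        net = make_random_net(seed, n_places=5, n_transitions=5, max_weight=3)
        c = incidence_matrix(net)
        expected = np.zeros_like(c)
        p_idx = {p: i for i, p in enumerate(net.place_ids)}
        t_idx = {t: j for j, t in enumerate(net.transition_ids)}
        for a in net.arcs:
            if a.source in p_idx:
                expected[p_idx[a.source], t_idx[a.target]] -= a.weight
            else:
                expected[p_idx[a.target], t_idx[a.source]] += a.weight
        assert (c == expected).all()


def test_enabled_and_fire_semantics():
    net = build_net(
        ["a", "b"], ["t_in", "t"], [("t_in", "a"), ("a", "t", 2), ("t", "b")]
    )
    empty = net.empty_marking()
    assert enabled(net, empty, "t_in")  # input transitions always enabled
    assert not enabled(net, net.marking({"a": 1}), "t")  # weight 2 needed
    m = net.marking({"a": 2})
    m2 = fire(net, m, "t")
    assert m2["a"] == 0 and m2["b"] == 1
    assert m["a"] == 2  # input marking untouched
    with pytest.raises(PetriNetError, match="not enabled"):
        fire(net, empty, "t")
    with pytest.raises(PetriNetError, match="unknown transition"):
        enabled(net, empty, "nope")


def test_fire_reverse_fire_on_cycle_restores_marking():
    net, _, _ = make_cycle(2)
    m0 = net.marking({"p0": 1})
    m1 = fire(net, m0, "t0")
    m2 = fire(net, m1, "t1")
    assert m2 == m0


def test_firing_difference_equals_incidence_column():
    for seed in range(30):
        net = make_random_net(seed, n_places=4, n_transitions=4, max_weight=3)
        c = incidence_matrix(net)
        m = net.marking({p: 5 for p in net.place_ids})
        for j, t in enumerate(net.transition_ids):
            if not enabled(net, m, t):
                continue
            m2 = fire(net, m, t)
            delta = [m2[p] - m[p] for p in net.place_ids]
            assert delta == c[:, j].tolist()


def test_structural_report_cycle():
    net, _, _ = make_cycle(2)
    sr = structural_report(net)
    assert sr.is_pure and sr.is_ordinary and sr.is_connected
    assert sr.is_strongly_connected and sr.is_conserved
    assert not sr.input_transitions and not sr.output_transitions


def test_structural_report_flags_impurity_and_weights():
    net = build_net(["a", "b"], ["t"], [("a", "t"), ("t", "a"), ("t", "b", 2)])
    sr = structural_report(net)
    assert not sr.is_pure  # a is both pre- and post-place of t
    assert not sr.is_ordinary and len(sr.nonunit_arcs) == 1
    assert not sr.is_conserved  # weight-2 production gains tokens


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), steps=st.integers(1, 30))
def test_conserved_net_token_count_invariant(seed, steps):
    """Firing never changes the total token count of a conserved net."""
    net, _, _ = make_cycle(4)
    rng = np.random.default_rng(seed)
    m = net.marking({"p0": 3, "p2": 1})
    total = m.total()
    for _ in range(steps):
        options = [t for t in net.transition_ids if enabled(net, m, t)]
        if not options:
            break
        m = fire(net, m, options[int(rng.integers(len(options)))])
        assert m.total() == total
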