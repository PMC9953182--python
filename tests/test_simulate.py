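"""Asynchronous stochastic simulation: determinism, conservation, scenarios."""

import numpy as np
import pytest

from lymphnet.core import PetriNetError, build_net
from lymphnet.simulate import (
    ScenarioConfig,
    load_marking,
    run_scenario,
    save_marking,
    simulate,
)
from lymphnet.synthetic import make_bordered_chain


def test_single_input_transition_accumulates_tokens():
    net = build_net(["a"], ["t_in"], [("t_in", "a")])
    traj = simulate(net, ScenarioConfig(steps=50, seed=0, tracked_places=("a",)))
    assert traj.series["a"][-1] == 50


def test_seed_determinism(model):
    a = run_scenario(model, "B", seed=5, steps=2_000, keep_firing_log=True)
    b = run_scenario(model, "B", seed=5, steps=2_000, keep_firing_log=True)
    assert a.firing_log == b.firing_log
    assert a.final_marking == b.final_marking
    c = run_scenario(model, "B", seed=6, steps=2_000, keep_firing_log=True)
    assert c.firing_log != a.firing_log


def test_firing_log_replay_reproduces_final_marking(model):
    from lymphnet.core import fire

    traj = run_scenario(model, "B", seed=3, steps=1_000, keep_firing_log=True)
    m = model.marking({p: 100 for p in ("AG_TIS", "M_TIS", "APC_TZ", "T_BL", "DC_GC")})
    for t in traj.firing_log:
        m = fire(model, m, t)
    assert m == traj.final_marking


def test_deadlock_recorded_not_raised():
    net, _, _ = make_bordered_chain(1)
    # no tokens, only t_in enabled; disabling it deadlocks immediately
    traj = simulate(
        net,
        ScenarioConfig(steps=10, seed=0, disabled_transitions=frozenset({"t_in"}),
                       tracked_places=("p1",)),
    )
    assert traj.halted_at == 0
    assert traj.series["p1"] == [0]


def test_unknown_disabled_transition_rejected(model):
    with pytest.raises(PetriNetError):
        simulate(model, ScenarioConfig(steps=1, seed=0,
                                       disabled_transitions=frozenset({"zz"})))


def test_pi_weighted_sums_constant_along_trajectory(model, model_pis):
    cfg = ScenarioConfig(
        steps=2_000,
        seed=11,
        initial_marking=model.marking(
            {p: 100 for p in ("AG_TIS", "M_TIS", "APC_TZ", "T_BL", "DC_GC")}
        ),
        tracked_places=tuple(model.place_ids),
        record_every=100,
    )
    traj = simulate(model, cfg)
    for pi in model_pis:
        sums = {
            sum(pi.coefficients.get(p, 0) * traj.series[p][k] for p in model.place_ids)
            for k in range(len(traj.recorded_steps))
        }
        assert sums == {100}


def test_scenario_a_zero_marking_theorem(model):
    """From the empty marking, every place on a zero-token place invariant
    stays empty, so no activation and no antibody ever appears."""
    traj = run_scenario(model, "A", seed=2, steps=5_000, record_every=50)
    assert set(traj.series["AB_TIS"]) == {0}
    assert set(traj.series["B1_DZ"]) == {0}
    assert set(traj.series["B3_ME"]) == {0}
    assert traj.series["AG_TIS"][-1] > 0


def test_marking_save_load_round_trip(tmp_path, model):
    m = model.marking({"AG_TIS": 7, "M_TIS": 3})
    path = tmp_path / "marking.tsv"
    save_marking(m, path)
    assert load_marking(path) == dict(m)


def test_load_marking_rejects_negative_and_malformed(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("a\t-1\n")
    with pytest.raises(PetriNetError, match="negative"):
        load_marking(bad)
    bad.write_text("a;3\n")
    with pytest.raises(PetriNetError, match="malformed"):
        load_marking(bad)


def test_scenario_c_from_saved_marking_is_bit_identical(tmp_path, model):
    adapted = run_scenario(model, "B", seed=9, steps=2_000)
    path = tmp_path / "adapted.tsv"
    save_marking(adapted.final_marking, path)
    direct = run_scenario(model, "C", seed=4, steps=1_000,
                          saved_marking=dict(adapted.final_marking),
                          keep_firing_log=True)
    reloaded = run_scenario(model, "C", seed=4, steps=1_000,
                            saved_marking=load_marking(path),
                            keep_firing_log=True)
    assert direct.firing_log == reloaded.firing_log
    assert direct.final_marking == reloaded.final_marking


def test_scenario_c_disables_antigen_influx(model):
    traj = run_scenario(model, "C", seed=1, steps=500, keep_firing_log=True)
    assert "IN_AG_TIS" not in set(traj.firing_log)


def test_scenario_d_long_memory(model):
    """After a longer adaptation the memory pool survives a continued run
    without antigen inflow far more often than not."""
    traj = run_scenario(model, "D", seed=0, steps=5_000,
                        adaptation_steps=5_000, record_every=200)
    assert "AB_TIS" in traj.series and traj.steps == 5_000
    assert traj.final_marking["AG_TIS"] >= 0  # sanity: valid marking
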