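"""Asynchronous stochastic token simulation.

One transition is fired per step, chosen uniformly at random among the
enabled (and not explicitly disabled) transitions; input transitions are
always enabled and compete on equal footing.  All reactions share one
notional time scale — the model carries no kinetic rates, and the dynamics
emerge from the combinatorial structure of the net alone.  A run is fully
reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import Marking, PetriNet, PetriNetError

__all__ = [
    "ScenarioConfig",
    "Trajectory",
    "simulate",
    "save_marking",
    "load_marking",
    "run_scenario",
    "SCENARIO_SEED_PLACES",
    "TRACKED_PLACES",
]

# Scenario B of the standard in-silico experiments: 100 tokens on antigen in
# the tissue plus on each conserved cell pool (macrophages, antigen-presenting
# cells, T cells, dendritic cells).
SCENARIO_SEED_PLACES = ("AG_TIS", "M_TIS", "APC_TZ", "T_BL", "DC_GC")
SCENARIO_TOKENS = 100
TRACKED_PLACES = ("AG_TIS", "B_BL", "B1_DZ", "B3_ME", "AB_TIS")
ANTIGEN_INFLUX = "IN_AG_TIS"


@dataclass(frozen=True)
class ScenarioConfig:
    steps: int
    seed: int
    initial_marking: Mapping[str, int] | None = None
    disabled_transitions: frozenset[str] = frozenset()
    tracked_places: tuple[str, ...] = TRACKED_PLACES
    record_every: int = 1
    keep_firing_log: bool = True

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class Trajectory:
    seed: int
    steps: int
    recorded_steps: list[int]
    series: dict[str, list[int]]
    final_marking: Marking
    firing_log: list[str] | None = None
    halted_at: int | None = None  # step index of deadlock, if any

    def series_array(self, place: str) -> np.ndarray:
        return np.asarray(self.series[place], dtype=np.int64)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.series, index=self.recorded_steps)
        df.index.name = "step"
        return df

    def plot(self, ax=None, markersize: float = 2.0):
        """Dot-series plot of the tracked places over simulation steps."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for place, values in self.series.items():
            ax.plot(
                self.recorded_steps, values, ".", markersize=markersize, label=place
            )
        ax.set_xlabel("simulation step")
        ax.set_ylabel("tokens")
        ax.legend(markerscale=4, fontsize=8)
        return ax


def simulate(net: PetriNet, config: ScenarioConfig) -> Trajectory:
    """Run an asynchronous simulation; deadlock halts the run early.

    Enabled-set bookkeeping is incremental: after each firing only
    transitions adjacent to changed places are re-checked.
    """
    unknown = config.disabled_transitions - set(net.transition_ids)
    if unknown:
        raise PetriNetError(f"disabled transitions not in net: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    marking = dict(
        net.initial_marking if config.initial_marking is None else config.initial_marking
    )
    if set(marking) != set(net.place_ids):
        marking = dict(net.marking(marking))

    active = [t for t in net.transition_ids if t not in config.disabled_transitions]
    pre = {t: net.pre(t) for t in active}
    post = {t: net.post(t) for t in active}
    # place -> active transitions whose enabledness depends on it
    dependents: dict[str, list[str]] = {p: [] for p in net.place_ids}
    for t in active:
        for p in pre[t]:
            dependents[p].append(t)

    def is_enabled(t: str) -> bool:
        return all(marking[p] >= w for p, w in pre[t].items())

    enabled = {t for t in active if is_enabled(t)}
    tracked = list(config.tracked_places)
    series: dict[str, list[int]] = {p: [] for p in tracked}
    recorded: list[int] = []
    log: list[str] | None = [] if config.keep_firing_log else None

    def record(step: int) -> None:
        recorded.append(step)
        for p in tracked:
            series[p].append(marking[p])

    record(0)
    halted = None
    for step in range(1, config.steps + 1):
        if not enabled:
            halted = step - 1
            break
        choices = sorted(enabled)
        t = choices[int(rng.integers(len(choices)))]
        for p, w in pre[t].items():
            marking[p] -= w
        for p, w in post[t].items():
            marking[p] = marking.get(p, 0) + w
        touched = set(pre[t]) | set(post[t])
        for p in touched:
            for dep in dependents[p]:
                if is_enabled(dep):
                    enabled.add(dep)
                else:
                    enabled.discard(dep)
        if log is not None:
            log.append(t)
        if step % config.record_every == 0 or step == config.steps:
            record(step)
    return Trajectory(
        seed=config.seed,
        steps=config.steps,
        recorded_steps=recorded,
        series=series,
        final_marking=Marking(marking),
        firing_log=log,
        halted_at=halted,
    )


def save_marking(marking: Mapping[str, int], path: str | Path) -> None:
    """Write a marking as a flat ``place<TAB>count`` text file."""
    lines = [f"{p}\t{int(c)}" for p, c in marking.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_marking(path: str | Path) -> dict[str, int]:
    """Read a flat marking file; negative or malformed counts are errors."""
    counts: dict[str, int] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            place, raw = line.split("\t")
            value = int(raw)
        except ValueError as exc:
            raise PetriNetError(f"{path}:{i}: malformed marking line {line!r}") from exc
        if value < 0:
            raise PetriNetError(f"{path}:{i}: negative count for {place!r}")
        counts[place] = value
    return counts


def run_scenario(
    net: PetriNet,
    scenario: str,
    seed: int,
    *,
    steps: int | None = None,
    saved_marking: Mapping[str, int] | None = None,
    adaptation_steps: int | None = None,
    record_every: int = 1,
    keep_firing_log: bool = False,
) -> Trajectory:
    """The four standard in-silico experiments.

    A: empty initial marking, 10,000 steps — no immune response possible.
    B: 100 tokens on antigen and on each conserved cell pool, 10,000 steps —
       adaptation and antibody production.
    C: continue from an adapted marking (B after 10,000 steps by default)
       with antigen influx disabled, 10,000 steps — memory loss.
    D: as C but adapted for 20,000 steps and continued for 100,000 —
       long-lived but eventually finite memory.

    For C and D a ``saved_marking`` may be supplied (e.g. reloaded from
    disk); otherwise the adaptation phase is simulated first with a seed
    derived from ``seed``.
    """
    scenario = scenario.upper()
    if scenario not in {"A", "B", "C", "D"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "A":
        config = ScenarioConfig(
            steps=10_000 if steps is None else steps,
            seed=seed,
            record_every=record_every,
            keep_firing_log=keep_firing_log,
        )
        return simulate(net, config)
    if scenario == "B":
        init = net.marking({p: SCENARIO_TOKENS for p in SCENARIO_SEED_PLACES})
        config = ScenarioConfig(
            steps=10_000 if steps is None else steps,
            seed=seed,
            initial_marking=init,
            record_every=record_every,
            keep_firing_log=keep_firing_log,
        )
        return simulate(net, config)
    # C / D: restart from an adapted state without antigen inflow
    default_adapt = 10_000 if scenario == "C" else 20_000
    if saved_marking is None:
        adapt = run_scenario(
            net,
            "B",
            seed + 1_000_003,
            steps=default_adapt if adaptation_steps is None else adaptation_steps,
            record_every=max(1, default_adapt // 10),
        )
        saved_marking = dict(adapt.final_marking)
    config = ScenarioConfig(
        steps=(10_000 if scenario == "C" else 100_000) if steps is None else steps,
        seed=seed,
        initial_marking=saved_marking,
        disabled_transitions=frozenset({ANTIGEN_INFLUX}),
        record_every=record_every,
        keep_firing_log=keep_firing_log,
    )
    return simulate(net, config)
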