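"""Scenario worlds as stochastic state machines, and replicate runners.

A :class:`World` is a set of named states.  Each non-terminal state *emits* a
compound stimulus (possibly drawn from a probabilistic mixture, e.g. "the food
source alone 80% of the time, together with a conspecific 20% of the time"),
the agent responds, and the declared transition distribution for the pair
(emitted stimulus, behaviour) yields a consequence stimulus and a next state.
A transition outcome may also carry observation events (witnessed stimulus
successions that update only w values) and annotation flags (scenario-defined
per-trial event markers such as "escaped").

A *trial* (one learning opportunity, e.g. one encounter) runs the machine from
its start distribution to a terminal state, applying the learning updates for
every experienced triplet.  :func:`run_replicates` repeats trials over many
independent replicates and returns per-trial averaged traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np

from .core import (
    AgentMemory,
    CompoundStimulus,
    ConfigurationError,
    apply_experience,
    apply_observation,
    response_distribution,
    sample_behaviour,
)

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import Scenario

__all__ = [
    "ScenarioDefinitionError",
    "MalformedWorldError",
    "ObservationEvent",
    "Outcome",
    "WorldState",
    "World",
    "TrialRecord",
    "TraceQuantity",
    "advance",
    "run_trial",
    "run_replicates",
    "collect_replicate_traces",
]

#: Hard per-trial step limit: converts malformed (non-terminating) worlds
#: into errors rather than hangs.
MAX_TRIAL_STEPS = 1000

_PROB_TOL = 1e-9

# placeholder used while validating outcomes whose next state may be undefined
class _Sentinel:
    terminal = True

_TERMINAL_SENTINEL = _Sentinel()


class ScenarioDefinitionError(ConfigurationError):
    """A world references unknown names or has malformed distributions."""


class MalformedWorldError(RuntimeError):
    """A trial exceeded the step guard without reaching a terminal state."""


# ---------------------------------------------------------------------------
# World definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservationEvent:
    """A witnessed stimulus-only succession (S, S'); updates w but no v."""

    stimulus: CompoundStimulus
    next_stimulus: CompoundStimulus


@dataclass(frozen=True)
class Outcome:
    """One branch of a transition distribution.

    ``consequence=None`` means the step ends stimulus continuity: the agent's
    behaviour removes it from the situation (e.g. escaping into a burrow)
    and no consequent stimulus is experienced, so no learning update is
    applied for that step.  Such outcomes must lead to a terminal state.
    """

    probability: float
    consequence: CompoundStimulus | None
    next_state: str
    observations: tuple[ObservationEvent, ...] = ()
    annotations: frozenset[str] = frozenset()


@dataclass(frozen=True)
class WorldState:
    """A named state: an emission mixture plus a transition table.

    ``transitions`` maps (emitted CompoundStimulus, behaviour name) to a
    tuple of :class:`Outcome` whose probabilities sum to 1.  Terminal states
    emit nothing and end the trial.
    """

    name: str
    emissions: tuple[tuple[float, CompoundStimulus], ...] = ()
    transitions: Mapping[tuple[CompoundStimulus, str], tuple[Outcome, ...]] = field(
        default_factory=dict
    )
    terminal: bool = False


@dataclass(frozen=True)
class World:
    """A validated state machine with a start-state distribution."""

    states: Mapping[str, WorldState]
    start: tuple[tuple[float, str], ...]  # (probability, state name)

    def validate(self, element_names: Iterable[str], behaviours: Iterable[str]) -> None:
        """Check distribution normalization, name resolution and termination."""
        element_names = set(element_names)
        behaviours = set(behaviours)

        def _check_compound(compound: CompoundStimulus, where: str) -> None:
            unknown = compound.elements - element_names
            if unknown:
                raise ScenarioDefinitionError(
                    f"{where}: unknown stimulus element(s) {sorted(unknown)}"
                )

        if abs(sum(p for p, _ in self.start) - 1.0) > _PROB_TOL:
            raise ScenarioDefinitionError("start-state probabilities do not sum to 1")
        for _, name in self.start:
            if name not in self.states:
                raise ScenarioDefinitionError(f"start state {name!r} not defined")

        for state in self.states.values():
            if state.terminal:
                continue
            if not state.emissions:
                raise ScenarioDefinitionError(
                    f"state {state.name!r}: non-terminal state has no emissions"
                )
            if abs(sum(p for p, _ in state.emissions) - 1.0) > _PROB_TOL:
                raise ScenarioDefinitionError(
                    f"state {state.name!r}: emission probabilities do not sum to 1"
                )
            for _, compound in state.emissions:
                _check_compound(compound, f"state {state.name!r} emission")
                for b in behaviours:
                    if (compound, b) not in state.transitions:
                        raise ScenarioDefinitionError(
                            f"state {state.name!r}: no transition for "
                            f"({compound.label()!r}, {b!r})"
                        )
            for (compound, b), outcomes in state.transitions.items():
                _check_compound(compound, f"state {state.name!r} transition key")
                if b not in behaviours:
                    raise ScenarioDefinitionError(
                        f"state {state.name!r}: unknown behaviour {b!r} in transition"
                    )
                if abs(sum(o.probability for o in outcomes) - 1.0) > _PROB_TOL:
                    raise ScenarioDefinitionError(
                        f"state {state.name!r}: transition probabilities for "
                        f"({compound.label()!r}, {b!r}) do not sum to 1"
                    )
                for o in outcomes:
                    if o.consequence is None:
                        if not self.states.get(o.next_state, _TERMINAL_SENTINEL).terminal:
                            raise ScenarioDefinitionError(
                                f"state {state.name!r}: an outcome without a "
                                "consequence stimulus must lead to a terminal state"
                            )
                    else:
                        _check_compound(o.consequence, f"state {state.name!r} consequence")
                    if o.next_state not in self.states:
                        raise ScenarioDefinitionError(
                            f"state {state.name!r}: undefined next state {o.next_state!r}"
                        )
                    for obs in o.observations:
                        _check_compound(obs.stimulus, f"state {state.name!r} observation")
                        _check_compound(
                            obs.next_stimulus, f"state {state.name!r} observation"
                        )

        # every state must be able to reach a terminal state (no infinite trials)
        reaches: set[str] = {s.name for s in self.states.values() if s.terminal}
        changed = True
        while changed:
            changed = False
            for state in self.states.values():
                if state.name in reaches:
                    continue
                nexts = {
                    o.next_state
                    for outcomes in state.transitions.values()
                    for o in outcomes
                }
                if nexts & reaches:
                    reaches.add(state.name)
                    changed = True
        unreachable = set(self.states) - reaches
        if unreachable:
            raise ScenarioDefinitionError(
                f"no terminal state reachable from state(s) {sorted(unreachable)}"
            )


# ---------------------------------------------------------------------------
# Running trials
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One trial: the experienced S -> B -> S' triplets plus event flags.

    The consequence of a triplet is None when the step ended stimulus
    continuity (no consequent stimulus was experienced).
    """

    steps: list[tuple[CompoundStimulus, str, CompoundStimulus | None]]
    annotations: set[str]
    trial_index: int = 0
    replicate_index: int = 0


def _sample_mixture(pairs: Sequence[tuple[float, object]], rng: np.random.Generator):
    if len(pairs) == 1:
        return pairs[0][1]
    r = rng.random()
    acc = 0.0
    for p, item in pairs:
        acc += p
        if r < acc:
            return item
    return pairs[-1][1]


def advance(
    state: WorldState,
    emitted: CompoundStimulus,
    behaviour: str,
    rng: np.random.Generator,
) -> Outcome:
    """Draw an outcome from the transition distribution of (emitted, behaviour).

    A missing transition entry is a scenario-definition error: worlds must be
    fully specified, there is no silent default consequence.
    """
    if state.terminal:
        raise ScenarioDefinitionError(f"cannot advance from terminal state {state.name!r}")
    key = (emitted, behaviour)
    if key not in state.transitions:
        raise ScenarioDefinitionError(
            f"state {state.name!r}: no transition for ({emitted.label()!r}, {behaviour!r})"
        )
    outcomes = state.transitions[key]
    if len(outcomes) == 1:
        return outcomes[0]
    r = rng.random()
    acc = 0.0
    for o in outcomes:
        acc += o.probability
        if r < acc:
            return o
    return outcomes[-1]


def run_trial(
    memory: AgentMemory,
    world: World,
    rng: np.random.Generator,
    trial_index: int = 0,
    replicate_index: int = 0,
    max_steps: int = MAX_TRIAL_STEPS,
) -> TrialRecord:
    """Run one trial to a terminal state, learning along the way.

    At each step the current state emits a stimulus, the agent chooses a
    behaviour by the softmax rule, the world advances, and the memory is
    updated for the experienced triplet and for every attached observation
    event (w only).  The memory is updated in place.
    """
    record = TrialRecord(
        steps=[], annotations=set(), trial_index=trial_index, replicate_index=replicate_index
    )
    state = world.states[_sample_mixture(world.start, rng)]
    for _ in range(max_steps):
        if state.terminal:
            return record
        emitted = _sample_mixture(state.emissions, rng)
        dist = response_distribution(memory, emitted)
        behaviour = sample_behaviour(dist, rng, memory.behaviours)
        outcome = advance(state, emitted, behaviour, rng)
        if outcome.consequence is not None:
            apply_experience(memory, emitted, behaviour, outcome.consequence)
        for obs in outcome.observations:
            apply_observation(memory, obs.stimulus, obs.next_stimulus)
        record.steps.append((emitted, behaviour, outcome.consequence))
        record.annotations |= outcome.annotations
        state = world.states[outcome.next_state]
    if state.terminal:
        return record
    raise MalformedWorldError(
        f"trial exceeded {max_steps} steps without reaching a terminal state"
    )


# ---------------------------------------------------------------------------
# Traced quantities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceQuantity:
    """A quantity recorded once per trial.

    kind:
      * ``"v"``    — v(element -> behaviour); args = (element, behaviour)
      * ``"w"``    — w(element); args = (element,)
      * ``"p"``    — model response probability Pr(behaviour | compound) from
        the softmax rule (not an empirical frequency); args = (compound, behaviour)
      * ``"pseq"`` — product of response probabilities along a path of
        (compound, behaviour) pairs, i.e. the model probability of performing
        a full correct sequence; args = ((compound, behaviour), ...)
      * ``"ann"``  — empirical 0/1 flag: 1.0 if the trial carried the given
        annotation; args = (flag,)
    """

    label: str
    kind: str
    args: tuple

    def evaluate(self, memory: AgentMemory, record: TrialRecord | None) -> float:
        if self.kind == "v":
            return memory.get_v(*self.args)
        if self.kind == "w":
            return memory.get_w(self.args[0])
        if self.kind == "p":
            compound, behaviour = self.args
            dist = response_distribution(memory, compound)
            return float(dist[memory.behaviours.index(behaviour)])
        if self.kind == "pseq":
            p = 1.0
            for compound, behaviour in self.args:
                dist = response_distribution(memory, compound)
                p *= float(dist[memory.behaviours.index(behaviour)])
            return p
        if self.kind == "ann":
            if record is None:
                return float("nan")
            return 1.0 if self.args[0] in record.annotations else 0.0
        raise ConfigurationError(f"unknown trace quantity kind: {self.kind!r}")


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------

def _replicate_rng(master_seed: int, replicate_index: int) -> np.random.Generator:
    # Counter-based split: each replicate's stream depends only on
    # (master_seed, replicate), never on execution order.  Arms share the
    # replicate streams, so identical worlds yield identical trajectories
    # (paired comparisons between arms).
    return np.random.default_rng(
        np.random.SeedSequence((int(master_seed), int(replicate_index)))
    )


def collect_replicate_traces(
    scenario: "Scenario",
    arm: str,
    n_replicates: int,
    n_trials: int,
    master_seed: int,
) -> np.ndarray:
    """Raw traces for one arm: array of shape (n_replicates, n_trials + 1, n_quantities).

    Row ``t`` holds the model quantities (v, w, response probabilities) after
    ``t`` completed trials — row 0 is the initial state, the last row the
    final state — together with the annotation flags of trial ``t - 1``
    (NaN in row 0, where no trial has run yet).
    """
    if n_replicates < 1 or n_trials < 1:
        raise ValueError("n_replicates and n_trials must be >= 1")
    world = scenario.arms[arm].world
    quantities = scenario.trace
    out = np.empty((n_replicates, n_trials + 1, len(quantities)))
    for rep in range(n_replicates):
        rng = _replicate_rng(master_seed, rep)
        memory = scenario.arms[arm].initial_memory.copy()
        record: TrialRecord | None = None
        for t in range(n_trials + 1):
            out[rep, t] = [q.evaluate(memory, record) for q in quantities]
            if t < n_trials:
                record = run_trial(memory, world, rng, trial_index=t, replicate_index=rep)
    return out


def run_replicates(
    scenario: "Scenario",
    n_replicates: int | None = None,
    n_trials: int | None = None,
    master_seed: int = 0,
    arms: Sequence[str] | None = None,
):
    """Run all (or selected) arms of a scenario and summarize across replicates.

    Each replicate starts from the arm's initial memory with an independent
    rng derived deterministically from (master_seed, arm, replicate), so
    identical inputs give bitwise-identical tables.  Returns a tidy
    :class:`pandas.DataFrame` with columns
    (arm, trial_index, quantity, mean, stderr, n_replicates).
    """
    from .analysis import summarize  # local import to avoid a cycle

    import pandas as pd

    n_replicates = scenario.n_replicates if n_replicates is None else n_replicates
    n_trials = scenario.n_trials if n_trials is None else n_trials
    if n_replicates < 1 or n_trials < 1:
        raise ValueError("n_replicates and n_trials must be >= 1")
    arms = list(scenario.arms) if arms is None else list(arms)
    tables = []
    for arm in arms:
        traces = collect_replicate_traces(scenario, arm, n_replicates, n_trials, master_seed)
        tables.append(summarize(traces, [q.label for q in scenario.trace], arm=arm))
    return pd.concat(tables, ignore_index=True)
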