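"""Builders for the five social-learning scenarios, plus combinatorics helpers.

Each builder assembles a :class:`Scenario`: stimulus elements with innate
values, a behaviour repertoire, one world (state machine) per experimental
arm (e.g. social vs individual learning), initial memories encoding the
scenario's predispositions (non-zero prior v/w values), replicate defaults,
and the quantities to trace.

Shared default magnitudes (all configurable per builder):

* reward value ``u = 25`` for the primary reinforcer,
* prior S-R value ``10`` where a scenario assumes a strong pre-existing
  response (e.g. an innate tendency to approach conspecifics),
* warning-call value ``u = -10`` for innately aversive signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

from .core import (
    AgentMemory,
    CompoundStimulus,
    ConfigurationError,
    LearningParameters,
    StimulusElement,
)
from .environment import ObservationEvent, Outcome, TraceQuantity, World, WorldState

__all__ = [
    "Arm",
    "Scenario",
    "SCENARIO_BUILDERS",
    "build_social_response",
    "build_imitation",
    "build_transfer",
    "build_sequence",
    "build_avoidance",
    "count_successions",
    "count_behaviour_sequences",
]

DEFAULT_REWARD = 25.0  # innate value of the primary reinforcer
DEFAULT_PRIOR = 10.0   # prior v value encoding a strong predisposed response
DEFAULT_WARNING = -10.0  # innate value of the conspecific warning call


@dataclass(frozen=True)
class Arm:
    """One experimental arm: a world plus the initial memory it starts from."""

    name: str
    world: World
    initial_memory: AgentMemory


@dataclass(frozen=True)
class Scenario:
    """An internally consistent learning scenario, ready to run."""

    name: str
    elements: Mapping[str, StimulusElement]
    repertoire: tuple[str, ...]
    arms: Mapping[str, Arm]
    trace: tuple[TraceQuantity, ...]
    n_replicates: int
    n_trials: int
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_trials < 1:
            raise ConfigurationError("n_replicates and n_trials must be >= 1")
        for arm in self.arms.values():
            arm.world.validate(self.elements, self.repertoire)
            if arm.initial_memory.behaviours != self.repertoire:
                raise ConfigurationError(
                    f"arm {arm.name!r}: repertoire mismatch with scenario"
                )


# ---------------------------------------------------------------------------
# small construction helpers
# ---------------------------------------------------------------------------

def _elements(*els: StimulusElement) -> dict[str, StimulusElement]:
    out: dict[str, StimulusElement] = {}
    for el in els:
        if el.name in out:
            raise ConfigurationError(f"duplicate element name {el.name!r}")
        out[el.name] = el
    return out

def _end() -> WorldState:
    return WorldState(name="end", terminal=True)

def _nonzero(pairs):
    """Drop zero-probability branches so degenerate mixtures collapse exactly."""
    return tuple(p for p in pairs if p[0] > 0.0)

def _once(consequence: CompoundStimulus, next_state: str, *,
          observations: tuple[ObservationEvent, ...] = (),
          annotations: frozenset[str] = frozenset()) -> tuple[Outcome, ...]:
    return (Outcome(1.0, consequence, next_state, observations, annotations),)


# ---------------------------------------------------------------------------
# 1. Learning a response to a social stimulus
# ---------------------------------------------------------------------------

def build_social_response(
    u_reward: float = DEFAULT_REWARD,
    alpha_v: float = 0.1,
    beta: float = 1.0,
    n_replicates: int = 1000,
    n_trials: int = 300,
) -> Scenario:
    """A social stimulus; responding B to it is rewarded, anything else is not.

    Pure instrumental (S-R) learning: the Pavlovian rate is 0 because no
    stimulus-value learning is required in this scenario.  The learned value
    v(S_social -> B) converges to the reinforcer value ``u_reward`` while
    v(S_social -> other) stays at 0.
    """
    els = _elements(
        StimulusElement("S_social", 0.0, is_social=True),
        StimulusElement("S_reward", u_reward),
        StimulusElement("S_no_reward", 0.0),
    )
    repertoire = ("B", "other")
    social = CompoundStimulus(["S_social"])
    encounter = WorldState(
        name="encounter",
        emissions=((1.0, social),),
        transitions={
            (social, "B"): _once(CompoundStimulus(["S_reward"]), "end",
                                 annotations=frozenset({"rewarded"})),
            (social, "other"): _once(CompoundStimulus(["S_no_reward"]), "end"),
        },
    )
    world = World(states={"encounter": encounter, "end": _end()}, start=((1.0, "encounter"),))
    params = LearningParameters(alpha_v=alpha_v, alpha_w=0.0, beta=beta)
    memory = AgentMemory(elements=els, behaviours=repertoire, params=params)
    trace = (
        TraceQuantity("p:S_social->B", "p", (social, "B")),
        TraceQuantity("v:S_social->B", "v", ("S_social", "B")),
        TraceQuantity("v:S_social->other", "v", ("S_social", "other")),
        TraceQuantity("ann:responded", "ann", ("rewarded",)),
    )
    return Scenario(
        name="social_response",
        elements=els,
        repertoire=repertoire,
        arms={"social": Arm("social", world, memory)},
        trace=trace,
        n_replicates=n_replicates,
        n_trials=n_trials,
        metadata={"u_reward": u_reward, "alpha_v": alpha_v, "beta": beta},
    )


# ---------------------------------------------------------------------------
# 2. Learning to imitate (contextual imitation)
# ---------------------------------------------------------------------------

def build_imitation(
    k: int = 2,
    u_reward: float = DEFAULT_REWARD,
    alpha_v: float = 0.1,
    beta: float = 1.0,
    n_replicates: int = 1000,
    n_trials: int = 300,
) -> Scenario:
    """Observed behaviours [B_1]..[B_k] appear equiprobably; matching is rewarded.

    The learner sees the percept of one of ``k`` behaviours and is rewarded
    only for repeating the behaviour just observed, which builds the S-R
    associations v([B_i] -> B_i).  Larger repertoires (larger ``k``) slow
    acquisition: there are more behaviours to try out.
    """
    if k < 2:
        raise ConfigurationError(f"imitation requires k >= 2 observed behaviours, got {k}")
    percepts = [f"[B{i}]" for i in range(1, k + 1)]
    behaviours = tuple(f"B{i}" for i in range(1, k + 1))
    els = _elements(
        *[StimulusElement(p, 0.0, is_social=True) for p in percepts],
        StimulusElement("S_reward", u_reward),
        StimulusElement("S_no_reward", 0.0),
    )
    reward = CompoundStimulus(["S_reward"])
    no_reward = CompoundStimulus(["S_no_reward"])
    emissions = tuple((1.0 / k, CompoundStimulus([p])) for p in percepts)
    transitions = {}
    for i, p in enumerate(percepts):
        for j, b in enumerate(behaviours):
            transitions[(CompoundStimulus([p]), b)] = _once(
                reward if i == j else no_reward, "end",
                annotations=frozenset({"imitated"}) if i == j else frozenset(),
            )
    world = World(
        states={
            "observe": WorldState("observe", emissions=emissions, transitions=transitions),
            "end": _end(),
        },
        start=((1.0, "observe"),),
    )
    params = LearningParameters(alpha_v=alpha_v, alpha_w=0.0, beta=beta)
    memory = AgentMemory(elements=els, behaviours=behaviours, params=params)
    trace = (
        TraceQuantity("p:[B1]->B1", "p", (CompoundStimulus(["[B1]"]), "B1")),
        TraceQuantity("v:[B1]->B1", "v", ("[B1]", "B1")),
        TraceQuantity("v:[B1]->B2", "v", ("[B1]", "B2")),
        TraceQuantity("ann:imitated", "ann", ("imitated",)),
    )
    return Scenario(
        name="imitation",
        elements=els,
        repertoire=behaviours,
        arms={"imitation": Arm("imitation", world, memory)},
        trace=trace,
        n_replicates=n_replicates,
        n_trials=n_trials,
        metadata={"k": k, "u_reward": u_reward},
    )


# ---------------------------------------------------------------------------
# 3. Transfer: learning a response to a non-social stimulus
# ---------------------------------------------------------------------------

def build_transfer(
    with_imitation_prior: bool = False,
    v_prior: float = DEFAULT_PRIOR,
    u_reward: float = DEFAULT_REWARD,
    p_social: float = 0.2,
    n_behaviours: int = 10,
    beta: float = 1.0,
    n_replicates: int = 1000,
    n_trials: int = 30,
) -> Scenario:
    """Social exposure bootstraps a response to a non-social stimulus S_x.

    The learner meets S_x alone with probability ``1 - p_social`` and in
    compound with a social element the rest of the time.  Responding with the
    target behaviour is rewarded either way.  In the default variant the
    social element is a conspecific's presence and the prior is an approach
    tendency v(S_social -> B) = ``v_prior``; with ``with_imitation_prior`` the
    social element is the percept [B1] of the rewarded behaviour and the
    prior is an established imitative response v([B1] -> B1), compared
    against a naive arm with no such prior.  The repertoire has
    ``n_behaviours`` options, so naive exploration starts at probability
    1/n_behaviours.
    """
    if not (0.0 <= p_social <= 1.0):
        raise ConfigurationError(f"p_social must be in [0, 1], got {p_social}")
    if n_behaviours < 2:
        raise ConfigurationError("n_behaviours must be >= 2")
    social_el = "[B1]" if with_imitation_prior else "S_social"
    target = "B1" if with_imitation_prior else "B"
    if with_imitation_prior:
        behaviours = tuple(f"B{i}" for i in range(1, n_behaviours + 1))
    else:
        behaviours = ("B",) + tuple(f"other{i}" for i in range(1, n_behaviours))
    els = _elements(
        StimulusElement(social_el, 0.0, is_social=True),
        StimulusElement("S_x", 0.0),
        StimulusElement("S_reward", u_reward),
        StimulusElement("S_no_reward", 0.0),
    )
    reward = CompoundStimulus(["S_reward"])
    no_reward = CompoundStimulus(["S_no_reward"])
    alone = CompoundStimulus(["S_x"])
    compound = CompoundStimulus([social_el, "S_x"])

    def _forage_state(emissions) -> WorldState:
        transitions = {}
        for _, emitted in emissions:
            for b in behaviours:
                transitions[(emitted, b)] = _once(
                    reward if b == target else no_reward, "end",
                    annotations=frozenset({"responded"}) if b == target else frozenset(),
                )
        return WorldState("forage", emissions=emissions, transitions=transitions)

    social_world = World(
        states={
            "forage": _forage_state(_nonzero(((1.0 - p_social, alone), (p_social, compound)))),
            "end": _end(),
        },
        start=((1.0, "forage"),),
    )
    individual_world = World(
        states={"forage": _forage_state(((1.0, alone),)), "end": _end()},
        start=((1.0, "forage"),),
    )
    params = LearningParameters(alpha_v=0.1, alpha_w=0.0, beta=beta)
    primed = AgentMemory(elements=els, behaviours=behaviours, params=params)
    primed.set_v(social_el, target, v_prior)
    naive = AgentMemory(elements=els, behaviours=behaviours, params=params)
    if with_imitation_prior:
        arms = {
            "imitating": Arm("imitating", social_world, primed),
            "naive": Arm("naive", social_world, naive),
        }
    else:
        arms = {
            "social": Arm("social", social_world, primed),
            "individual": Arm("individual", individual_world, naive),
        }
    trace = (
        TraceQuantity(f"p:S_x->{target}", "p", (alone, target)),
        TraceQuantity(f"v:S_x->{target}", "v", ("S_x", target)),
        TraceQuantity(f"v:{social_el}->{target}", "v", (social_el, target)),
        TraceQuantity("ann:responded", "ann", ("responded",)),
    )
    return Scenario(
        name="transfer_imitation" if with_imitation_prior else "transfer",
        elements=els,
        repertoire=behaviours,
        arms=arms,
        trace=trace,
        n_replicates=n_replicates,
        n_trials=n_trials,
        metadata={
            "with_imitation_prior": with_imitation_prior,
            "v_prior": v_prior,
            "u_reward": u_reward,
            "p_social": p_social,
            "n_behaviours": n_behaviours,
        },
    )


# ---------------------------------------------------------------------------
# 4. Learning a behaviour sequence (conditioned reinforcement and chaining)
# ---------------------------------------------------------------------------

def build_sequence(
    v_prior: float = DEFAULT_PRIOR,
    u_reward: float = DEFAULT_REWARD,
    u_social: float = DEFAULT_REWARD,
    p_social: float = 0.2,
    p_obs: float = 0.5,
    alpha_w: float = 0.1,
    v_x_prior: float = 0.0,
    n_behaviours: int = 10,
    beta: float = 1.0,
    n_replicates: int = 1000,
    n_trials: int = 300,
) -> Scenario:
    """Two-step chain S_x -> B1 -> S_y -> B2 -> S_reward (the food-truck case).

    The first step is never primary-rewarded, so autonomous performance
    requires the intermediate stimulus S_y to acquire conditioned value w(S_y)
    that can reinforce the first response.  In the social arm, conspecifics
    accompany S_x a fraction ``p_social`` of encounters; the learner has a
    predisposed approach response v(S_social -> B1) = ``v_prior``, conspecific
    proximity is itself reinforcing (``u_social`` > 0), and while at the
    second step in company it witnesses, with probability ``p_obs``, an
    experienced individual performing B2 and feeding — a stimulus succession
    that endows S_y with conditioned value without the learner responding.
    The individual arm never encounters social stimuli.  ``v_x_prior`` sets
    an initial v(S_x -> B1) in *both* arms (useful to study extinction of an
    already-acquired first response when ``alpha_w`` is 0).

    The repertoire holds ``n_behaviours`` options at every step (B1 correct
    first, B2 correct second, the rest unproductive), so naive discovery of
    the full sequence is an n^l exploration problem; with only two options a
    single lucky completion saturates the second response and the exploration
    burden the scenario is about disappears.
    """
    if not (0.0 <= p_social <= 1.0 and 0.0 <= p_obs <= 1.0):
        raise ConfigurationError("p_social and p_obs must be in [0, 1]")
    if n_behaviours < 2:
        raise ConfigurationError("n_behaviours must be >= 2")
    els = _elements(
        StimulusElement("S_social", u_social, is_social=True),
        StimulusElement("S_x", 0.0),
        StimulusElement("S_y", 0.0),
        StimulusElement("[B2]", 0.0, is_social=True),
        StimulusElement("[S_reward]", 0.0, is_social=True),
        StimulusElement("S_reward", u_reward),
        StimulusElement("S_no_reward", 0.0),
    )
    behaviours = ("B1", "B2") + tuple(f"other{i}" for i in range(1, n_behaviours - 1))
    x = CompoundStimulus(["S_x"])
    soc_x = CompoundStimulus(["S_social", "S_x"])
    y = CompoundStimulus(["S_y"])
    soc_y = CompoundStimulus(["S_social", "S_y"])
    reward = CompoundStimulus(["S_reward"])
    no_reward = CompoundStimulus(["S_no_reward"])
    witnessed = (
        ObservationEvent(soc_y, CompoundStimulus(["S_social", "[B2]"])),
        ObservationEvent(CompoundStimulus(["S_social", "[B2]"]),
                         CompoundStimulus(["S_social", "[S_reward]"])),
    )

    def _step2(name: str, emitted: CompoundStimulus) -> WorldState:
        transitions = {
            (emitted, b): _once(no_reward, "end") for b in behaviours if b != "B2"
        }
        transitions[(emitted, "B2")] = _once(
            reward, "end", annotations=frozenset({"sequence_completed"})
        )
        return WorldState(name, emissions=((1.0, emitted),), transitions=transitions)

    def _step1_transitions(emitted: CompoundStimulus, success: tuple[Outcome, ...]):
        transitions = {
            (emitted, b): _once(no_reward, "end") for b in behaviours if b != "B1"
        }
        transitions[(emitted, "B1")] = success
        return transitions

    social_step1 = WorldState(
        "step1",
        emissions=_nonzero(((1.0 - p_social, x), (p_social, soc_x))),
        transitions={
            **_step1_transitions(x, _once(y, "step2_alone")),
            **_step1_transitions(
                soc_x,
                tuple(
                    o for o in (
                        Outcome(p_obs, soc_y, "step2_social", observations=witnessed),
                        Outcome(1.0 - p_obs, soc_y, "step2_social"),
                    )
                    if o.probability > 0.0
                ),
            ),
        },
    )
    social_world = World(
        states={
            "step1": social_step1,
            "step2_alone": _step2("step2_alone", y),
            "step2_social": _step2("step2_social", soc_y),
            "end": _end(),
        },
        start=((1.0, "step1"),),
    )
    individual_step1 = WorldState(
        "step1",
        emissions=((1.0, x),),
        transitions=_step1_transitions(x, _once(y, "step2_alone")),
    )
    individual_world = World(
        states={
            "step1": individual_step1,
            "step2_alone": _step2("step2_alone", y),
            "end": _end(),
        },
        start=((1.0, "step1"),),
    )
    params = LearningParameters(alpha_v=0.1, alpha_w=alpha_w, beta=beta)
    social_mem = AgentMemory(elements=els, behaviours=behaviours, params=params)
    social_mem.set_v("S_social", "B1", v_prior)
    individual_mem = AgentMemory(elements=els, behaviours=behaviours, params=params)
    for mem in (social_mem, individual_mem):
        if v_x_prior:
            mem.set_v("S_x", "B1", v_x_prior)
    trace = (
        TraceQuantity("p_full_sequence", "pseq", ((x, "B1"), (y, "B2"))),
        TraceQuantity("p:S_x->B1", "p", (x, "B1")),
        TraceQuantity("p:S_y->B2", "p", (y, "B2")),
        TraceQuantity("v:S_x->B1", "v", ("S_x", "B1")),
        TraceQuantity("v:S_y->B2", "v", ("S_y", "B2")),
        TraceQuantity("w:S_y", "w", ("S_y",)),
        TraceQuantity("ann:sequence_completed", "ann", ("sequence_completed",)),
    )
    return Scenario(
        name="sequence",
        elements=els,
        repertoire=behaviours,
        arms={
            "social": Arm("social", social_world, social_mem),
            "individual": Arm("individual", individual_world, individual_mem),
        },
        trace=trace,
        n_replicates=n_replicates,
        n_trials=n_trials,
        metadata={
            "v_prior": v_prior,
            "u_reward": u_reward,
            "u_social": u_social,
            "p_social": p_social,
            "p_obs": p_obs,
            "alpha_w": alpha_w,
            "v_x_prior": v_x_prior,
            "n_behaviours": n_behaviours,
        },
    )


# ---------------------------------------------------------------------------
# 5. Avoidance learning with warning calls
# ---------------------------------------------------------------------------

def build_avoidance(
    heterospecific_call: bool = False,
    u_warning: float = DEFAULT_WARNING,
    p_leave: float = 0.2,
    p_companion: float = 0.5,
    p_call: float = 0.5,
    p_hetero: float = 0.5,
    n_replicates: int = 2000,
    n_trials: int = 300,
) -> Scenario:
    """Predator avoidance learned from innately aversive conspecific warning calls.

    Per encounter the learner is with an experienced companion with
    probability ``p_companion``; the companion calls with probability
    ``p_call``.  At each step the learner may escape, which ends the
    encounter and, with it, stimulus continuity: fleeing into cover leaves
    no consequent stimulus to learn from, so escape is neither rewarded nor
    punished.  Otherwise the predator leaves on its own with probability
    ``p_leave`` (experienced as a return to a neutral safe situation); if it
    stays and a call is given the learner experiences
    S_predator -> B_ignore -> S_warning, the key learning event.  Avoidance
    is thus driven entirely by the negative values: ignoring is punished
    first by the innately aversive call and later by the now-negative
    predator stimulus itself (S_predator -> B_ignore -> S_predator).  The
    comparison arm never hears calls, and since injury is not modelled it
    has no learning signal at all.  With ``heterospecific_call``, calling
    encounters begin (probability ``p_hetero``) with an unfamiliar
    heterospecific call S_x that is always followed by the conspecific call,
    so w(S_x) converges to u(S_warning).
    """
    for name, p in (("p_leave", p_leave), ("p_companion", p_companion),
                    ("p_call", p_call), ("p_hetero", p_hetero)):
        if not (0.0 <= p <= 1.0):
            raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
    if u_warning >= 0:
        raise ConfigurationError(f"u_warning must be negative, got {u_warning}")
    el_list = [
        StimulusElement("S_predator", 0.0),
        StimulusElement("S_warning", u_warning, is_social=True),
        StimulusElement("S_safe", 0.0),
    ]
    if heterospecific_call:
        el_list.append(StimulusElement("S_hetero", 0.0))
    els = _elements(*el_list)
    behaviours = ("B_escape", "B_ignore")
    pred = CompoundStimulus(["S_predator"])
    warn = CompoundStimulus(["S_warning"])
    safe = CompoundStimulus(["S_safe"])

    def _pred_state(name: str, stay_consequence: CompoundStimulus) -> WorldState:
        return WorldState(
            name,
            emissions=((1.0, pred),),
            transitions={
                # escape: no consequent stimulus, no learning update
                (pred, "B_escape"): (Outcome(1.0, None, "end",
                                             annotations=frozenset({"escaped"})),),
                (pred, "B_ignore"): (
                    Outcome(p_leave, safe, "end",
                            annotations=frozenset({"ignored_throughout"})),
                    Outcome(1.0 - p_leave, stay_consequence, name),
                ),
            },
        )

    p_call_enc = p_companion * p_call
    states = {
        "pred_call": _pred_state("pred_call", warn),
        "pred_nocall": _pred_state("pred_nocall", pred),
        "end": _end(),
    }
    if heterospecific_call:
        hetero = CompoundStimulus(["S_hetero"])
        states["hetero"] = WorldState(
            "hetero",
            emissions=((1.0, hetero),),
            transitions={
                (hetero, "B_ignore"): _once(warn, "pred_call"),
                (hetero, "B_escape"): _once(warn, "end",
                                            annotations=frozenset({"escaped"})),
            },
        )
        start = _nonzero((
            (p_call_enc * p_hetero, "hetero"),
            (p_call_enc * (1.0 - p_hetero), "pred_call"),
            (1.0 - p_call_enc, "pred_nocall"),
        ))
    else:
        start = _nonzero(((p_call_enc, "pred_call"), (1.0 - p_call_enc, "pred_nocall")))
    social_world = World(states=states, start=start)
    individual_world = World(
        states={"pred_nocall": _pred_state("pred_nocall", pred), "end": _end()},
        start=((1.0, "pred_nocall"),),
    )
    params = LearningParameters(alpha_v=0.1, alpha_w=0.1, beta=1.0)
    trace = [
        TraceQuantity("p:S_predator->B_escape", "p", (pred, "B_escape")),
        TraceQuantity("v:S_predator->B_ignore", "v", ("S_predator", "B_ignore")),
        TraceQuantity("v:S_predator->B_escape", "v", ("S_predator", "B_escape")),
        TraceQuantity("w:S_predator", "w", ("S_predator",)),
        TraceQuantity("ann:escaped", "ann", ("escaped",)),
        TraceQuantity("ann:ignored_throughout", "ann", ("ignored_throughout",)),
    ]
    if heterospecific_call:
        trace.append(TraceQuantity("w:S_hetero", "w", ("S_hetero",)))
    return Scenario(
        name="avoidance_hetero" if heterospecific_call else "avoidance",
        elements=els,
        repertoire=behaviours,
        arms={
            "social": Arm(
                "social",
                social_world,
                AgentMemory(elements=els, behaviours=behaviours, params=params),
            ),
            "individual": Arm(
                "individual",
                individual_world,
                AgentMemory(elements=els, behaviours=behaviours, params=params),
            ),
        },
        trace=tuple(trace),
        n_replicates=n_replicates,
        n_trials=n_trials,
        metadata={
            "heterospecific_call": heterospecific_call,
            "u_warning": u_warning,
            "p_leave": p_leave,
            "p_companion": p_companion,
            "p_call": p_call,
            "p_hetero": p_hetero,
        },
    )


# ---------------------------------------------------------------------------
# Combinatorics of successions and behaviour sequences
# ---------------------------------------------------------------------------

def count_successions(k_base_elements: int) -> int:
    """Number of ordered two-step stimulus successions over k base elements.

    With k elements there are 2^k - 1 non-empty compounds, hence
    (2^k - 1)^2 ordered successions S -> S' (9 for k = 2, 49 for k = 3).
    """
    if not isinstance(k_base_elements, int) or k_base_elements < 1:
        raise ValueError(f"k_base_elements must be an integer >= 1, got {k_base_elements!r}")
    return (2 ** k_base_elements - 1) ** 2


def count_behaviour_sequences(n_behaviours: int, length: int) -> int:
    """Number n^l of behaviour sequences of a given length over n behaviours.

    This is the size of the exploration problem a learner faces when a
    sequence must be discovered from its first step with no intermediate
    reward — the reason entry patterns and conditioned reinforcement matter.
    """
    if not isinstance(n_behaviours, int) or n_behaviours < 1:
        raise ValueError(f"n_behaviours must be an integer >= 1, got {n_behaviours!r}")
    if not isinstance(length, int) or length < 1:
        raise ValueError(f"length must be an integer >= 1, got {length!r}")
    return n_behaviours ** length


SCENARIO_BUILDERS: dict[str, Callable[..., Scenario]] = {
    "social_response": build_social_response,
    "imitation": build_imitation,
    "transfer": build_transfer,
    "sequence": build_sequence,
    "avoidance": build_avoidance,
}
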