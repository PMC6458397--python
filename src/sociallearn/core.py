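"""Core associative-learning model.

The learner maintains two kinds of memory:

* ``v(S -> B)`` — stimulus–response (instrumental) values: the estimated
  reward obtainable by responding to stimulus element ``S`` with behaviour
  ``B``.
* ``w(S)`` — stimulus (Pavlovian) values: the response-independent estimate
  of reward expected after ``S``; learned ``w`` values act as conditioned
  reinforcers and enable response chaining.

Each stimulus element additionally carries an innate reinforcement value
``u(S)`` (a primary reinforcer if non-zero).  After an experience
``S -> B -> S'`` both memories are driven towards the *total* value of the
outcome, ``u(S') + w(S')``, by error-correction updates with learning rates
``alpha_v`` and ``alpha_w`` (a Rescorla–Wagner-style delta rule with the
reinforcement value split into an innate and a learned part):

    dv(S -> B) = alpha_v * [u(S') + w(S') - v(S -> B)]
    dw(S)      = alpha_w * [u(S') + w(S') - w(S)]

The ``w`` update does not depend on which behaviour was performed, so it also
applies to pure stimulus successions observed without responding (see
:func:`apply_observation`).

Compound stimuli (several elements experienced at once) follow the classic
summation convention: the value of a compound is the sum of the values of its
elements, and an experience with a compound updates every element by the same
amount, using the compound's summed value inside the error term.

Decision-making is a softmax over the v values of the current (compound)
stimulus with exploration parameter ``beta``: ``beta = 0`` gives uniform
choice, large ``beta`` is near-greedy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "StimulusElement",
    "CompoundStimulus",
    "Behaviour",
    "LearningParameters",
    "AgentMemory",
    "compound_v",
    "compound_total_value",
    "response_distribution",
    "sample_behaviour",
    "apply_experience",
    "apply_observation",
    "memory_to_text",
    "memory_from_text",
]


class ConfigurationError(ValueError):
    """A scenario or memory refers to unknown names or invalid values."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusElement:
    """A named perceptual element with innate reinforcement value ``u``.

    ``is_social`` is metadata only: learning treats social and non-social
    elements identically.  ``u`` may be negative (e.g. a warning call),
    zero (neutral) or positive (a primary reward).
    """

    name: str
    u: float = 0.0
    is_social: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("stimulus element name must be non-empty")
        if not math.isfinite(self.u):
            raise ConfigurationError(f"u({self.name}) must be finite, got {self.u!r}")


@dataclass(frozen=True)
class Behaviour:
    """A named behaviour in the learner's repertoire."""

    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("behaviour name must be non-empty")


class CompoundStimulus:
    """A set of co-occurring stimulus elements, the unit perceived at one step.

    Equality is set equality: element order never affects any computed value.
    """

    __slots__ = ("elements",)

    def __init__(self, elements: Iterable[str] | str):
        if isinstance(elements, str):
            elements = (elements,)
        names = tuple(e.name if isinstance(e, StimulusElement) else str(e) for e in elements)
        if not names:
            raise ConfigurationError("a compound stimulus must contain at least one element")
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate elements in compound stimulus: {names}")
        object.__setattr__(self, "elements", frozenset(names))

    def __setattr__(self, *a):  # immutability guard
        raise AttributeError("CompoundStimulus is immutable")

    def __eq__(self, other) -> bool:
        return isinstance(other, CompoundStimulus) and self.elements == other.elements

    def __hash__(self) -> int:
        return hash(self.elements)

    def __iter__(self):
        return iter(sorted(self.elements))

    def __len__(self) -> int:
        return len(self.elements)

    def __contains__(self, name: str) -> bool:
        return name in self.elements

    def label(self) -> str:
        return " ".join(sorted(self.elements))

    def __repr__(self) -> str:
        return f"CompoundStimulus({self.label()!r})"


@dataclass(frozen=True)
class LearningParameters:
    """Learning rates and exploration parameter.

    alpha_v : S-R learning rate, in (0, 1].
    alpha_w : stimulus-value learning rate, in [0, 1]; 0 disables Pavlovian
        (conditioned-reinforcement) learning entirely.
    beta : softmax exploration parameter, >= 0.
    """

    alpha_v: float = 0.1
    alpha_w: float = 0.1
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_v <= 1.0):
            raise ConfigurationError(f"alpha_v must be in (0, 1], got {self.alpha_v}")
        if not (0.0 <= self.alpha_w <= 1.0):
            raise ConfigurationError(f"alpha_w must be in [0, 1], got {self.alpha_w}")
        if not (self.beta >= 0.0 and math.isfinite(self.beta)):
            raise ConfigurationError(f"beta must be finite and >= 0, got {self.beta}")


@dataclass
class AgentMemory:
    """The learner's v-table, w-table and learning parameters.

    Missing entries read as 0 (the default initial condition); non-zero
    priors are set explicitly by scenarios.  ``elements`` and ``behaviours``
    define the known names: referencing anything else is a configuration
    error rather than a silent zero.
    """

    elements: Mapping[str, StimulusElement]
    behaviours: tuple[str, ...]
    params: LearningParameters = field(default_factory=LearningParameters)
    v: dict[tuple[str, str], float] = field(default_factory=dict)
    w: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.behaviours = tuple(
            b.name if isinstance(b, Behaviour) else str(b) for b in self.behaviours
        )
        if len(self.behaviours) < 2:
            raise ConfigurationError("a repertoire must contain at least 2 behaviours")
        if len(set(self.behaviours)) != len(self.behaviours):
            raise ConfigurationError("duplicate behaviour names in repertoire")
        for key, value in list(self.v.items()) + list(self.w.items()):
            if not math.isfinite(value):
                raise ConfigurationError(f"non-finite memory value for {key}: {value}")

    # -- name checking ------------------------------------------------------

    def _check_element(self, name: str) -> None:
        if name not in self.elements:
            raise ConfigurationError(f"unknown stimulus element: {name!r}")

    def _check_behaviour(self, name: str) -> None:
        if name not in self.behaviours:
            raise ConfigurationError(f"unknown behaviour: {name!r}")

    # -- accessors ----------------------------------------------------------

    def get_v(self, element: str, behaviour: str) -> float:
        self._check_element(element)
        self._check_behaviour(behaviour)
        return self.v.get((element, behaviour), 0.0)

    def get_w(self, element: str) -> float:
        self._check_element(element)
        return self.w.get(element, 0.0)

    def set_v(self, element: str, behaviour: str, value: float) -> None:
        self._check_element(element)
        self._check_behaviour(behaviour)
        self.v[(element, behaviour)] = float(value)

    def set_w(self, element: str, value: float) -> None:
        self._check_element(element)
        self.w[element] = float(value)

    def copy(self) -> "AgentMemory":
        return AgentMemory(
            elements=self.elements,
            behaviours=self.behaviours,
            params=self.params,
            v=dict(self.v),
            w=dict(self.w),
        )


# ---------------------------------------------------------------------------
# Value computation
# ---------------------------------------------------------------------------

def _as_behaviour_name(behaviour: str | Behaviour) -> str:
    return behaviour.name if isinstance(behaviour, Behaviour) else str(behaviour)


def compound_v(memory: AgentMemory, stimulus: CompoundStimulus, behaviour: str | Behaviour) -> float:
    """Summed S-R value of a compound: v(S1 S2 ... -> B) = sum_i v(Si -> B)."""
    b = _as_behaviour_name(behaviour)
    memory._check_behaviour(b)
    total = 0.0
    for el in stimulus.elements:
        memory._check_element(el)
        total += memory.v.get((el, b), 0.0)
    return total


def compound_total_value(memory: AgentMemory, stimulus: CompoundStimulus) -> float:
    """Total reinforcement value of a compound: sum_i u(Si) + sum_i w(Si)."""
    total = 0.0
    for el in stimulus.elements:
        memory._check_element(el)
        total += memory.elements[el].u + memory.w.get(el, 0.0)
    return total


def response_distribution(
    memory: AgentMemory,
    stimulus: CompoundStimulus,
    repertoire: Sequence[str | Behaviour] | None = None,
) -> np.ndarray:
    """Softmax choice probabilities over the repertoire given a stimulus.

    Pr(S -> B) = exp(beta v(S -> B)) / sum_B' exp(beta v(S -> B')), computed
    with max-subtraction so large values do not overflow.
    """
    names = (
        [_as_behaviour_name(b) for b in repertoire]
        if repertoire is not None
        else list(memory.behaviours)
    )
    if not names:
        raise ConfigurationError("repertoire must be non-empty")
    x = np.array([memory.params.beta * compound_v(memory, stimulus, b) for b in names])
    x -= x.max()
    e = np.exp(x)
    return e / e.sum()


def sample_behaviour(
    dist: np.ndarray,
    rng: np.random.Generator,
    repertoire: Sequence[str | Behaviour],
) -> str:
    """Draw a behaviour according to ``dist`` (reproducible under a fixed rng)."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 1 or len(dist) != len(repertoire):
        raise ValueError("distribution length does not match repertoire")
    if np.any(dist < 0) or not np.isclose(dist.sum(), 1.0, atol=1e-9):
        raise ValueError(f"invalid probability distribution: {dist}")
    # inverse-CDF draw (cheaper than Generator.choice for short vectors)
    r = rng.random() * dist.sum()
    acc = 0.0
    idx = len(dist) - 1
    for i, p in enumerate(dist):
        acc += p
        if r < acc:
            idx = i
            break
    return _as_behaviour_name(repertoire[idx])


# ---------------------------------------------------------------------------
# Learning updates
# ---------------------------------------------------------------------------

def apply_experience(
    memory: AgentMemory,
    stimulus: CompoundStimulus,
    behaviour: str | Behaviour,
    next_stimulus: CompoundStimulus,
) -> AgentMemory:
    """Update memory for one experience S -> B -> S' (in place; returns memory).

    Every element of S receives the same v and w increments, computed from the
    pre-update compound values (simultaneous update):

        dv = alpha_v * [u(S') + w(S') - v(S -> B)]    (performed B only)
        dw = alpha_w * [u(S') + w(S') - w(S)]         (behaviour-independent)
    """
    b = _as_behaviour_name(behaviour)
    memory._check_behaviour(b)
    for el in stimulus.elements:
        memory._check_element(el)
    total_next = compound_total_value(memory, next_stimulus)
    v_before = compound_v(memory, stimulus, b)
    w_before = sum(memory.w.get(el, 0.0) for el in stimulus.elements)
    dv = memory.params.alpha_v * (total_next - v_before)
    dw = memory.params.alpha_w * (total_next - w_before)
    for el in stimulus.elements:
        memory.v[(el, b)] = memory.v.get((el, b), 0.0) + dv
        if memory.params.alpha_w != 0.0:
            memory.w[el] = memory.w.get(el, 0.0) + dw
    return memory


def apply_observation(
    memory: AgentMemory,
    stimulus: CompoundStimulus,
    next_stimulus: CompoundStimulus,
) -> AgentMemory:
    """Update memory for a witnessed stimulus succession S -> S' (w only).

    Observing another individual provides a succession of stimuli without the
    learner responding, so only stimulus values change (observational
    conditioning); no S-R value is touched.
    """
    for el in stimulus.elements:
        memory._check_element(el)
    if memory.params.alpha_w == 0.0:
        return memory
    total_next = compound_total_value(memory, next_stimulus)
    w_before = sum(memory.w.get(el, 0.0) for el in stimulus.elements)
    dw = memory.params.alpha_w * (total_next - w_before)
    for el in stimulus.elements:
        memory.w[el] = memory.w.get(el, 0.0) + dw
    return memory


# ---------------------------------------------------------------------------
# Flat text serialization (element, behaviour, v) / (element, w)
# ---------------------------------------------------------------------------

def memory_to_text(memory: AgentMemory) -> str:
    """Serialize the v/w tables to a flat, sorted key-value text table."""
    lines = []
    for (el, b), value in sorted(memory.v.items()):
        lines.append(f"v\t{el}\t{b}\t{value!r}")
    for el, value in sorted(memory.w.items()):
        lines.append(f"w\t{el}\t{value!r}")
    return "\n".join(lines) + ("\n" if lines else "")


def memory_from_text(
    text: str,
    elements: Mapping[str, StimulusElement],
    behaviours: Sequence[str],
    params: LearningParameters | None = None,
) -> AgentMemory:
    """Rebuild an :class:`AgentMemory` from :func:`memory_to_text` output."""
    memory = AgentMemory(
        elements=elements,
        behaviours=tuple(behaviours),
        params=params or LearningParameters(),
    )
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if parts[0] == "v" and len(parts) == 4:
            memory.set_v(parts[1], parts[2], float(parts[3]))
        elif parts[0] == "w" and len(parts) == 3:
            memory.set_w(parts[1], float(parts[2]))
        else:
            raise ConfigurationError(f"malformed memory table line {lineno}: {line!r}")
    return memory
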