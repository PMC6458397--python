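"""Declarative run configuration (YAML dialect).

A config file either names a built-in scenario (with parameter overrides) or
defines a custom world from scratch.  Validation is strict: unknown keys are
rejected and every failure names the offending key path, so a typo never
silently becomes a default.  Schema sketch::

    scenario: social_response        # built-in, or use `custom:` instead
    overrides: {u_reward: 25.0}      # builder keyword arguments
    custom:
      name: my_world
      elements:      {S_social: {u: 0.0, social: true}, S_reward: {u: 25.0}}
      behaviours:    [B, other]
      parameters:    {alpha_v: 0.1, alpha_w: 0.1, beta: 1.0}   # optional
      priors:
        v: [{element: S_social, behaviour: B, value: 10.0}]
        w: []
      world:
        start: [{state: encounter, p: 1.0}]
        states:
          encounter:
            emissions: [{stimulus: [S_social], p: 1.0}]
            transitions:
              - when: {stimulus: [S_social], behaviour: B}
                outcomes:
                  - {p: 1.0, consequence: [S_reward], next: end,
                     annotate: [rewarded]}
          end: {terminal: true}
      trace:
        - {kind: p, stimulus: [S_social], behaviour: B}
        - {kind: v, element: S_social, behaviour: B}
      n_replicates: 1000
      n_trials: 300
    run:
      seed: 1          # mandatory for batch runs: no silent nondeterminism
      output_dir: out
      plots: false

Observation events attach to outcomes as
``observe: [{from: [S_y], to: [S_social, "[B2]"]}]``; an outcome may omit
``consequence`` (write ``consequence: null``) to end stimulus continuity,
in which case ``next`` must be a terminal state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .core import (
    AgentMemory,
    CompoundStimulus,
    ConfigurationError,
    LearningParameters,
    StimulusElement,
)
from .environment import ObservationEvent, Outcome, TraceQuantity, World, WorldState
from .scenarios import SCENARIO_BUILDERS, Arm, Scenario

__all__ = ["RunConfig", "ConfigError", "parse_config", "load_config"]


class ConfigError(ConfigurationError):
    """Invalid run configuration; the message names the offending key."""


@dataclass(frozen=True)
class RunConfig:
    """Resolved run parameters for the command line."""

    scenario: str | None = None
    overrides: Mapping[str, Any] = field(default_factory=dict)
    seed: int | None = None
    n_replicates: int | None = None
    n_trials: int | None = None
    output_dir: str = "runs"
    emit_plots: bool = False


def _require_mapping(node: Any, path: str) -> Mapping:
    if not isinstance(node, Mapping):
        raise ConfigError(f"{path}: expected a mapping, got {type(node).__name__}")
    return node


def _require_list(node: Any, path: str) -> list:
    if not isinstance(node, list):
        raise ConfigError(f"{path}: expected a list, got {type(node).__name__}")
    return node


def _reject_unknown(node: Mapping, allowed: set[str], path: str) -> None:
    unknown = set(node) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


def _number(node: Any, path: str) -> float:
    if isinstance(node, bool) or not isinstance(node, (int, float)):
        raise ConfigError(f"{path}: expected a number, got {node!r}")
    return float(node)


def _compound(node: Any, path: str) -> CompoundStimulus:
    names = _require_list(node, path)
    try:
        return CompoundStimulus([str(n) for n in names])
    except ConfigurationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _parse_elements(node: Any) -> dict[str, StimulusElement]:
    out = {}
    for name, spec in _require_mapping(node, "custom.elements").items():
        path = f"custom.elements.{name}"
        spec = _require_mapping(spec if spec is not None else {}, path)
        _reject_unknown(spec, {"u", "social"}, path)
        out[str(name)] = StimulusElement(
            str(name),
            u=_number(spec.get("u", 0.0), f"{path}.u"),
            is_social=bool(spec.get("social", False)),
        )
    if not out:
        raise ConfigError("custom.elements: at least one element is required")
    return out


def _parse_outcome(node: Any, path: str) -> Outcome:
    node = _require_mapping(node, path)
    _reject_unknown(node, {"p", "consequence", "next", "annotate", "observe"}, path)
    for key in ("p", "next"):
        if key not in node:
            raise ConfigError(f"{path}: missing required key {key!r}")
    consequence = None
    if node.get("consequence") is not None:
        consequence = _compound(node["consequence"], f"{path}.consequence")
    observations = []
    for i, obs in enumerate(_require_list(node.get("observe", []), f"{path}.observe")):
        opath = f"{path}.observe[{i}]"
        obs = _require_mapping(obs, opath)
        _reject_unknown(obs, {"from", "to"}, opath)
        if "from" not in obs or "to" not in obs:
            raise ConfigError(f"{opath}: needs both 'from' and 'to'")
        observations.append(
            ObservationEvent(
                _compound(obs["from"], f"{opath}.from"),
                _compound(obs["to"], f"{opath}.to"),
            )
        )
    return Outcome(
        probability=_number(node["p"], f"{path}.p"),
        consequence=consequence,
        next_state=str(node["next"]),
        observations=tuple(observations),
        annotations=frozenset(
            str(a) for a in _require_list(node.get("annotate", []), f"{path}.annotate")
        ),
    )


def _parse_state(name: str, node: Any) -> WorldState:
    path = f"custom.world.states.{name}"
    node = _require_mapping(node if node is not None else {}, path)
    _reject_unknown(node, {"terminal", "emissions", "transitions"}, path)
    if node.get("terminal", False):
        return WorldState(name=str(name), terminal=True)
    emissions = []
    for i, em in enumerate(_require_list(node.get("emissions", []), f"{path}.emissions")):
        epath = f"{path}.emissions[{i}]"
        em = _require_mapping(em, epath)
        _reject_unknown(em, {"stimulus", "p"}, epath)
        emissions.append(
            (_number(em.get("p", 1.0), f"{epath}.p"),
             _compound(em.get("stimulus"), f"{epath}.stimulus"))
        )
    transitions: dict[tuple[CompoundStimulus, str], tuple[Outcome, ...]] = {}
    for i, tr in enumerate(_require_list(node.get("transitions", []), f"{path}.transitions")):
        tpath = f"{path}.transitions[{i}]"
        tr = _require_mapping(tr, tpath)
        _reject_unknown(tr, {"when", "outcomes"}, tpath)
        on = _require_mapping(tr.get("when"), f"{tpath}.when")
        _reject_unknown(on, {"stimulus", "behaviour"}, f"{tpath}.when")
        key = (
            _compound(on.get("stimulus"), f"{tpath}.when.stimulus"),
            str(on.get("behaviour")),
        )
        if key in transitions:
            raise ConfigError(f"{tpath}: duplicate transition for {key[0].label()!r}/{key[1]!r}")
        outcomes = tuple(
            _parse_outcome(o, f"{tpath}.outcomes[{j}]")
            for j, o in enumerate(_require_list(tr.get("outcomes"), f"{tpath}.outcomes"))
        )
        transitions[key] = outcomes
    return WorldState(name=str(name), emissions=tuple(emissions), transitions=transitions)


_TRACE_KEYS = {
    "p": {"kind", "stimulus", "behaviour", "label"},
    "pseq": {"kind", "path", "label"},
    "v": {"kind", "element", "behaviour", "label"},
    "w": {"kind", "element", "label"},
    "ann": {"kind", "flag", "label"},
}


def _parse_trace(node: Any) -> tuple[TraceQuantity, ...]:
    out = []
    for i, tq in enumerate(_require_list(node, "custom.trace")):
        path = f"custom.trace[{i}]"
        tq = _require_mapping(tq, path)
        kind = str(tq.get("kind", ""))
        if kind not in _TRACE_KEYS:
            raise ConfigError(f"{path}.kind: unknown trace kind {kind!r}")
        _reject_unknown(tq, _TRACE_KEYS[kind], path)
        if kind == "p":
            compound = _compound(tq.get("stimulus"), f"{path}.stimulus")
            behaviour = str(tq.get("behaviour"))
            args: tuple = (compound, behaviour)
            default_label = f"p:{compound.label()}->{behaviour}"
        elif kind == "pseq":
            steps = []
            for j, step in enumerate(_require_list(tq.get("path"), f"{path}.path")):
                spath = f"{path}.path[{j}]"
                step = _require_mapping(step, spath)
                _reject_unknown(step, {"stimulus", "behaviour"}, spath)
                steps.append(
                    (_compound(step.get("stimulus"), f"{spath}.stimulus"),
                     str(step.get("behaviour")))
                )
            args = tuple(steps)
            default_label = "p_full_sequence"
        elif kind == "v":
            args = (str(tq.get("element")), str(tq.get("behaviour")))
            default_label = f"v:{args[0]}->{args[1]}"
        elif kind == "w":
            args = (str(tq.get("element")),)
            default_label = f"w:{args[0]}"
        else:  # ann
            args = (str(tq.get("flag")),)
            default_label = f"ann:{args[0]}"
        out.append(TraceQuantity(str(tq.get("label", default_label)), kind, args))
    if not out:
        raise ConfigError("custom.trace: at least one traced quantity is required")
    return tuple(out)


def _parse_custom(node: Any) -> Scenario:
    path = "custom"
    node = _require_mapping(node, path)
    _reject_unknown(
        node,
        {"name", "elements", "behaviours", "parameters", "priors", "world",
         "trace", "n_replicates", "n_trials"},
        path,
    )
    elements = _parse_elements(node.get("elements"))
    behaviours = tuple(
        str(b) for b in _require_list(node.get("behaviours"), "custom.behaviours")
    )
    pnode = _require_mapping(node.get("parameters", {}) or {}, "custom.parameters")
    _reject_unknown(pnode, {"alpha_v", "alpha_w", "beta"}, "custom.parameters")
    try:
        params = LearningParameters(
            alpha_v=_number(pnode.get("alpha_v", 0.1), "custom.parameters.alpha_v"),
            alpha_w=_number(pnode.get("alpha_w", 0.1), "custom.parameters.alpha_w"),
            beta=_number(pnode.get("beta", 1.0), "custom.parameters.beta"),
        )
        memory = AgentMemory(elements=elements, behaviours=behaviours, params=params)
    except ConfigurationError as exc:
        raise ConfigError(f"custom: {exc}") from exc
    prnode = _require_mapping(node.get("priors", {}) or {}, "custom.priors")
    _reject_unknown(prnode, {"v", "w"}, "custom.priors")
    try:
        for i, pv in enumerate(_require_list(prnode.get("v", []), "custom.priors.v")):
            pv = _require_mapping(pv, f"custom.priors.v[{i}]")
            _reject_unknown(pv, {"element", "behaviour", "value"}, f"custom.priors.v[{i}]")
            memory.set_v(str(pv.get("element")), str(pv.get("behaviour")),
                         _number(pv.get("value"), f"custom.priors.v[{i}].value"))
        for i, pw in enumerate(_require_list(prnode.get("w", []), "custom.priors.w")):
            pw = _require_mapping(pw, f"custom.priors.w[{i}]")
            _reject_unknown(pw, {"element", "value"}, f"custom.priors.w[{i}]")
            memory.set_w(str(pw.get("element")),
                         _number(pw.get("value"), f"custom.priors.w[{i}].value"))
    except ConfigurationError as exc:
        raise ConfigError(f"custom.priors: {exc}") from exc

    wnode = _require_mapping(node.get("world"), "custom.world")
    _reject_unknown(wnode, {"start", "states"}, "custom.world")
    states = {
        str(name): _parse_state(str(name), snode)
        for name, snode in _require_mapping(wnode.get("states"), "custom.world.states").items()
    }
    start = []
    for i, st in enumerate(_require_list(wnode.get("start"), "custom.world.start")):
        spath = f"custom.world.start[{i}]"
        st = _require_mapping(st, spath)
        _reject_unknown(st, {"state", "p"}, spath)
        start.append((_number(st.get("p", 1.0), f"{spath}.p"), str(st.get("state"))))
    world = World(states=states, start=tuple(start))
    try:
        world.validate(elements, behaviours)
    except ConfigurationError as exc:
        raise ConfigError(f"custom.world: {exc}") from exc

    name = str(node.get("name", "custom"))
    try:
        return Scenario(
            name=name,
            elements=elements,
            repertoire=behaviours,
            arms={name: Arm(name, world, memory)},
            trace=_parse_trace(node.get("trace")),
            n_replicates=int(node.get("n_replicates", 1000)),
            n_trials=int(node.get("n_trials", 100)),
            metadata={"source": "config"},
        )
    except ConfigurationError as exc:
        raise ConfigError(f"custom: {exc}") from exc


def parse_config(text: str) -> tuple[RunConfig, Scenario | None]:
    """Parse and validate a YAML run configuration.

    Returns the run parameters and, for ``custom`` configs, the fully built
    scenario (built-in scenarios are constructed later, after overrides are
    applied).  Every validation failure names the offending key path.
    """
    try:
        root = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"not valid YAML: {exc}") from exc
    root = _require_mapping(root if root is not None else {}, "<root>")
    _reject_unknown(root, {"scenario", "overrides", "custom", "run"}, "<root>")
    if ("scenario" in root) == ("custom" in root):
        raise ConfigError("<root>: exactly one of 'scenario' or 'custom' is required")

    rnode = _require_mapping(root.get("run", {}) or {}, "run")
    _reject_unknown(
        rnode, {"seed", "n_replicates", "n_trials", "output_dir", "plots"}, "run"
    )
    seed = rnode.get("seed")
    if seed is not None and (isinstance(seed, bool) or not isinstance(seed, int)):
        raise ConfigError("run.seed: expected an integer")

    scenario_name = root.get("scenario")
    overrides = dict(_require_mapping(root.get("overrides", {}) or {}, "overrides"))
    custom = None
    if scenario_name is not None:
        scenario_name = str(scenario_name)
        if scenario_name not in SCENARIO_BUILDERS:
            raise ConfigError(
                f"scenario: unknown scenario {scenario_name!r}; "
                f"available: {sorted(SCENARIO_BUILDERS)}"
            )
    else:
        if overrides:
            raise ConfigError("overrides: only valid together with a built-in 'scenario'")
        custom = _parse_custom(root.get("custom"))

    cfg = RunConfig(
        scenario=scenario_name,
        overrides=overrides,
        seed=seed,
        n_replicates=rnode.get("n_replicates"),
        n_trials=rnode.get("n_trials"),
        output_dir=str(rnode.get("output_dir", "runs")),
        emit_plots=bool(rnode.get("plots", False)),
    )
    return cfg, custom


def load_config(path) -> tuple[RunConfig, Scenario | None]:
    """Read and parse a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_config(fh.read())
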