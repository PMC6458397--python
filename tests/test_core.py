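"""Unit and property tests for the learning equations and the softmax rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sociallearn import (
    AgentMemory,
    CompoundStimulus,
    ConfigurationError,
    LearningParameters,
    StimulusElement,
    apply_experience,
    apply_observation,
    compound_total_value,
    compound_v,
    memory_from_text,
    memory_to_text,
    response_distribution,
    sample_behaviour,
)

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


# ---------------------------------------------------------------------------
# compound value summation
# ---------------------------------------------------------------------------

def test_compound_v_sums_element_values(memory):
    S = CompoundStimulus(["X", "Y"])
    assert compound_v(memory, S, "B") == 0.0  # empty memory reads as 0
    memory.set_v("X", "B", 5.0)
    assert compound_v(memory, CompoundStimulus(["X"]), "B") == 5.0
    memory.set_v("X", "B", 3.0)
    memory.set_v("Y", "B", 4.0)
    assert compound_v(memory, S, "B") == 7.0


def test_compound_total_value_sums_innate_and_learned(elements):
    els = {
        "A": StimulusElement("A", 2.0),
        "Bst": StimulusElement("Bst", -2.0),
        "S_reward": StimulusElement("S_reward", 25.0),
    }
    mem = AgentMemory(elements=els, behaviours=("B", "other"))
    assert compound_total_value(mem, CompoundStimulus(["S_reward"])) == 25.0
    mem.set_w("A", 1.0)
    assert compound_total_value(mem, CompoundStimulus(["A", "Bst"])) == 1.0
    neutral = AgentMemory(elements=els, behaviours=("B", "other"))
    neutral_els = CompoundStimulus(["A", "Bst"])
    assert compound_total_value(neutral, neutral_els) == 0.0  # all w = 0, u cancel


def test_compound_stimulus_set_semantics():
    assert CompoundStimulus(["X", "Y"]) == CompoundStimulus(["Y", "X"])
    with pytest.raises(ConfigurationError):
        CompoundStimulus([])
    with pytest.raises(ConfigurationError):
        CompoundStimulus(["X", "X"])


def test_unknown_names_are_configuration_errors(memory):
    with pytest.raises(ConfigurationError):
        compound_v(memory, CompoundStimulus(["nope"]), "B")
    with pytest.raises(ConfigurationError):
        compound_v(memory, CompoundStimulus(["X"]), "nope")
    with pytest.raises(ConfigurationError):
        compound_total_value(memory, CompoundStimulus(["nope"]))
    with pytest.raises(ConfigurationError):
        apply_experience(memory, CompoundStimulus(["nope"]), "B", CompoundStimulus(["X"]))


# ---------------------------------------------------------------------------
# softmax decision rule
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=200)
@given(vals=st.lists(finite, min_size=2, max_size=6))
def test_softmax_beta_zero_is_uniform(vals):
    """With no exploitation pressure every behaviour is equally likely."""
    behaviours = tuple(f"b{i}" for i in range(len(vals)))
    els = {"X": StimulusElement("X", 0.0)}
    mem = AgentMemory(elements=els, behaviours=behaviours,
                      params=LearningParameters(beta=0.0))
    for b, v in zip(behaviours, vals):
        mem.set_v("X", b, v)
    dist = response_distribution(mem, CompoundStimulus(["X"]))
    assert np.allclose(dist, 1.0 / len(vals), atol=1e-12)


@settings(deadline=None, max_examples=200)
@given(
    vals=st.lists(finite, min_size=2, max_size=6),
    beta=st.floats(min_value=0, max_value=10),
)
def test_softmax_normalization_and_order_invariance(vals, beta):
    behaviours = tuple(f"b{i}" for i in range(len(vals)))
    els = {"X": StimulusElement("X"), "Y": StimulusElement("Y")}
    mem = AgentMemory(elements=els, behaviours=behaviours,
                      params=LearningParameters(beta=beta))
    for b, v in zip(behaviours, vals):
        mem.set_v("X", b, v / 2)
        mem.set_v("Y", b, v / 2)
    d1 = response_distribution(mem, CompoundStimulus(["X", "Y"]))
    d2 = response_distribution(mem, CompoundStimulus(["Y", "X"]))
    assert abs(d1.sum() - 1.0) < 1e-12
    assert np.all(d1 >= 0)
    assert np.array_equal(d1, d2)  # element order never matters


def test_softmax_two_option_closed_form(memory):
    memory.set_v("X", "B", 25.0)
    dist = response_distribution(memory, CompoundStimulus(["X"]))
    expected = 1.0 / (1.0 + math.exp(-25.0))
    assert dist[0] == pytest.approx(expected, rel=1e-12)
    assert dist[1] == pytest.approx(1.0 - expected, rel=1e-9)


def test_softmax_is_stable_for_huge_values(elements):
    mem = AgentMemory(elements=elements, behaviours=("B", "other"),
                      params=LearningParameters(beta=50.0))
    mem.set_v("X", "B", 1e4)
    dist = response_distribution(mem, CompoundStimulus(["X"]))
    assert np.all(np.isfinite(dist))
    assert dist[0] == pytest.approx(1.0)


def test_increasing_beta_sharpens_the_argmax(elements):
    probs = []
    for beta in (0.0, 0.5, 1.0, 2.0, 5.0):
        mem = AgentMemory(elements=elements, behaviours=("B", "other"),
                          params=LearningParameters(beta=beta))
        mem.set_v("X", "B", 2.0)
        probs.append(response_distribution(mem, CompoundStimulus(["X"]))[0])
    assert all(a < b for a, b in zip(probs, probs[1:]))


def test_empty_repertoire_rejected(memory):
    with pytest.raises(ConfigurationError):
        response_distribution(memory, CompoundStimulus(["X"]), repertoire=[])


# ---------------------------------------------------------------------------
# behaviour sampling
# ---------------------------------------------------------------------------

def test_sample_behaviour_degenerate_and_reproducible(rng):
    assert all(
        sample_behaviour(np.array([1.0, 0.0]), rng, ("a", "b")) == "a" for _ in range(20)
    )
    draws1 = [
        sample_behaviour(np.array([0.5, 0.5]), np.random.default_rng(7), ("a", "b"))
    ]
    draws2 = [
        sample_behaviour(np.array([0.5, 0.5]), np.random.default_rng(7), ("a", "b"))
    ]
    assert draws1 == draws2


def test_sample_behaviour_empirical_frequency(rng):
    draws = [sample_behaviour(np.array([0.5, 0.5]), rng, ("a", "b")) for _ in range(10_000)]
    freq = draws.count("a") / len(draws)
    assert abs(freq - 0.5) < 0.02


def test_sample_behaviour_rejects_invalid_distribution(rng):
    with pytest.raises(ValueError):
        sample_behaviour(np.array([0.5, 0.2]), rng, ("a", "b"))
    with pytest.raises(ValueError):
        sample_behaviour(np.array([-0.5, 1.5]), rng, ("a", "b"))


# ---------------------------------------------------------------------------
# learning updates
# ---------------------------------------------------------------------------

def test_single_experience_error_correction(memory):
    """First rewarded trial moves v one learning-rate step towards the reward."""
    apply_experience(memory, CompoundStimulus(["X"]), "B", CompoundStimulus(["S_reward"]))
    assert memory.get_v("X", "B") == pytest.approx(2.5)  # 0.1 * (25 - 0)
    assert memory.get_v("X", "other") == 0.0


def test_neutral_outcome_changes_nothing(memory):
    apply_experience(memory, CompoundStimulus(["X"]), "B", CompoundStimulus(["S_neutral"]))
    assert memory.get_v("X", "B") == 0.0
    assert memory.get_w("X") == 0.0


def test_repeated_training_converges_to_reinforcer_value(memory):
    for _ in range(300):
        apply_experience(memory, CompoundStimulus(["X"]), "B",
                         CompoundStimulus(["S_reward"]))
    assert memory.get_v("X", "B") == pytest.approx(25.0, abs=1e-9)


@settings(deadline=None, max_examples=50)
@given(
    alpha=st.floats(min_value=0.01, max_value=1.0),
    v0=finite,
    u=st.floats(min_value=-30, max_value=30),
)
def test_geometric_convergence_closed_form(alpha, v0, u):
    """|v_t - u| shrinks exactly geometrically for a terminal outcome with w=0."""
    els = {"X": StimulusElement("X"), "R": StimulusElement("R", u)}
    mem = AgentMemory(elements=els, behaviours=("B", "other"),
                      params=LearningParameters(alpha_v=alpha, alpha_w=0.0))
    mem.set_v("X", "B", v0)
    for t in range(1, 40):
        apply_experience(mem, CompoundStimulus(["X"]), "B", CompoundStimulus(["R"]))
        expected = u - (u - v0) * (1.0 - alpha) ** t
        assert mem.get_v("X", "B") == pytest.approx(expected, rel=1e-9, abs=1e-9)


def test_w_update_is_behaviour_independent(elements):
    """Experiences differing only in the response leave bitwise-identical w tables."""
    m1 = AgentMemory(elements=elements, behaviours=("B", "other"))
    m2 = AgentMemory(elements=elements, behaviours=("B", "other"))
    for S, S_next in [
        (["X"], ["S_reward"]),
        (["X", "Y"], ["S_neutral"]),
        (["Y"], ["S_reward", "X"]),
    ]:
        apply_experience(m1, CompoundStimulus(S), "B", CompoundStimulus(S_next))
        apply_experience(m2, CompoundStimulus(S), "other", CompoundStimulus(S_next))
    assert m1.w == m2.w


def test_nonperformed_responses_unchanged(memory):
    memory.set_v("X", "other", 3.0)
    apply_experience(memory, CompoundStimulus(["X"]), "B", CompoundStimulus(["S_reward"]))
    assert memory.get_v("X", "other") == 3.0


def test_compound_update_spreads_equally(memory):
    """Every element of an n-element compound gets the same increment."""
    memory.set_v("X", "B", 1.0)
    S = CompoundStimulus(["X", "Y"])
    before = {el: memory.get_v(el, "B") for el in ("X", "Y")}
    v_before = compound_v(memory, S, "B")
    apply_experience(memory, S, "B", CompoundStimulus(["S_reward"]))
    deltas = {el: memory.get_v(el, "B") - before[el] for el in ("X", "Y")}
    assert deltas["X"] == deltas["Y"] == pytest.approx(0.1 * (25.0 - 1.0))
    assert compound_v(memory, S, "B") - v_before == pytest.approx(2 * deltas["X"])


def test_updates_use_pre_update_values():
    """Self-referential successions must not see their own partial update."""
    els = {"X": StimulusElement("X", 4.0)}
    mem = AgentMemory(elements=els, behaviours=("B", "other"),
                      params=LearningParameters(alpha_v=0.5, alpha_w=0.5))
    mem.set_w("X", 2.0)
    # T = u(X) + w(X) = 6 evaluated before any update
    apply_experience(mem, CompoundStimulus(["X"]), "B", CompoundStimulus(["X"]))
    assert mem.get_v("X", "B") == pytest.approx(3.0)  # 0.5 * (6 - 0)
    assert mem.get_w("X") == pytest.approx(4.0)       # 2 + 0.5 * (6 - 2)


def test_observation_updates_w_only(memory):
    apply_observation(memory, CompoundStimulus(["X"]), CompoundStimulus(["S_reward"]))
    assert memory.get_w("X") == pytest.approx(2.5)
    assert all(v == 0.0 for v in memory.v.values())


def test_alpha_w_zero_disables_stimulus_value_learning(elements):
    mem = AgentMemory(elements=elements, behaviours=("B", "other"),
                      params=LearningParameters(alpha_w=0.0))
    apply_experience(mem, CompoundStimulus(["X"]), "B", CompoundStimulus(["S_reward"]))
    apply_observation(mem, CompoundStimulus(["Y"]), CompoundStimulus(["S_reward"]))
    assert mem.w == {}
    assert mem.get_v("X", "B") == pytest.approx(2.5)


# ---------------------------------------------------------------------------
# parameters and serialization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        {"alpha_v": 0.0},
        {"alpha_v": 1.5},
        {"alpha_w": -0.1},
        {"beta": -1.0},
        {"beta": float("inf")},
    ],
)
def test_invalid_learning_parameters_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        LearningParameters(**kwargs)


def test_learning_parameter_defaults():
    p = LearningParameters()
    assert (p.alpha_v, p.alpha_w, p.beta) == (0.1, 0.1, 1.0)


def test_memory_text_roundtrip(memory):
    memory.set_v("X", "B", 3.25)
    memory.set_v("Y", "other", -1.5)
    memory.set_w("S_reward", 0.125)
    text = memory_to_text(memory)
    back = memory_from_text(text, memory.elements, memory.behaviours, memory.params)
    assert back.v == memory.v
    assert back.w == memory.w
    with pytest.raises(ConfigurationError):
        memory_from_text("garbage line", memory.elements, memory.behaviours)
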