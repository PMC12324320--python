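"""Normalized-Hill logic-ODE simulation: functional form, gates, integration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from signetbench.network import Network, Node, Reaction
from signetbench.sim import (
    CompiledGate,
    SimulationConfig,
    compile_model,
    hill_constants,
    integrate,
    node_rhs,
    normalized_hill,
    reaction_flux,
    steady_state_oracle,
)
from signetbench.synthetic import SyntheticSpec, generate_network


def test_hill_constraint_points():
    for n, ec50 in [(1.4, 0.5), (2.0, 0.4), (3.5, 0.6), (1.1, 0.3)]:
        assert normalized_hill(0.0, n, ec50) == pytest.approx(0.0, abs=1e-12)
        assert normalized_hill(ec50, n, ec50) == pytest.approx(0.5, abs=1e-12)
        assert normalized_hill(1.0, n, ec50) == pytest.approx(1.0, abs=1e-12)


def test_hill_default_gain_constant():
    B, Kn = hill_constants(1.4, 0.5)
    # numerical solution of the (0,0)/(0.5,0.5)/(1,1) constraint equations
    ec = 0.5**1.4
    assert B == pytest.approx((ec - 1) / (2 * ec - 1), abs=1e-12)
    assert B == pytest.approx(2.5649, abs=5e-5)
    assert Kn == pytest.approx(B - 1.0)


def test_hill_degenerate_constants_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        normalized_hill(0.3, n=1.0, ec50=0.5)  # 2*EC50^n == 1


@given(st.floats(0.1, 4.0), st.floats(0.05, 0.95))
def test_hill_monotone_and_bounded(n, ec50):
    if abs(2 * ec50**n - 1) < 1e-6:
        return
    x = np.linspace(0, 1, 101)
    f = normalized_hill(x, n, ec50)
    assert np.all(np.diff(f) >= -1e-12)
    assert np.all((f >= 0) & (f <= 1))


def _gate(w=1.0, acts=(), inhs=(), target=0):
    return CompiledGate(w, 1.4, 0.5, np.array(acts, dtype=int),
                        np.array(inhs, dtype=int), target)


def test_reaction_flux_cases():
    ymax = np.ones(2)
    assert reaction_flux(_gate(w=0.7), np.zeros(2), ymax) == pytest.approx(0.7)
    # one activator at ymax: f(1) = 1
    assert reaction_flux(_gate(acts=[0]), np.array([1.0, 0.0]), ymax) == pytest.approx(1.0)
    # one inhibitor at 0: factor (1 - f(0)) = 1
    assert reaction_flux(_gate(inhs=[1]), np.array([0.0, 0.0]), ymax) == pytest.approx(1.0)
    # knocked-out activator treated as inactive
    assert reaction_flux(_gate(acts=[0]), np.zeros(2), np.array([0.0, 1.0])) == 0.0


@pytest.mark.parametrize(
    "fluxes, expected",
    [([0.5, 0.5], 0.75), ([0.8], 0.8), ([0.5, 0.5, 0.5], 0.875)],
)
def test_or_combination(fluxes, expected):
    # left-to-right fold of a+b-ab equals 1 - prod(1-f), so order-independent
    acc = 0.0
    for f in fluxes:
        acc = acc + f - acc * f
    assert acc == pytest.approx(expected)
    assert acc == pytest.approx(1.0 - np.prod([1.0 - f for f in fluxes]))


def test_node_rhs_or_via_model():
    net = Network(
        nodes=[Node("A"), Node("B"), Node("C")],
        reactions=[Reaction("=> C", weight=0.5), Reaction("=> C", weight=0.5)],
    )
    model = compile_model(net)
    dy = node_rhs(model, np.zeros(3))
    assert dy[2] == pytest.approx(0.75)  # OR(0.5, 0.5) * ymax / tau
    assert dy[0] == dy[1] == 0.0  # undriven nodes at 0 stay at 0


def test_undriven_node_decays():
    net = Network(nodes=[Node("A", y0=0.8)], reactions=[])
    dy = node_rhs(compile_model(net), np.array([0.8]))
    assert dy[0] == pytest.approx(-0.8)


def test_single_input_matches_exponential_solution():
    net = Network(nodes=[Node("A", tau=2.0)], reactions=[Reaction("=> A", weight=1.0)])
    result = integrate(compile_model(net), SimulationConfig(t_end=8.0, n_eval=20,
                                                            rtol=1e-10, atol=1e-12))
    expected = 1.0 - np.exp(-result.t / 2.0)
    assert np.max(np.abs(result.y[:, 0] - expected)) < 1e-6


def test_two_node_chain_saturates():
    net = Network(
        nodes=[Node("A"), Node("B")],
        reactions=[Reaction("=> A", weight=1.0), Reaction("A => B")],
    )
    state = integrate(compile_model(net)).state
    assert state.converged
    assert state["A"] == pytest.approx(1.0, abs=1e-4)
    assert state["B"] == pytest.approx(1.0, abs=1e-4)


def test_zero_inputs_give_zero_steady_state(toy_network):
    config = SimulationConfig(inputs={"A": 0.0, "B": 0.0})
    state = integrate(compile_model(toy_network), config).state
    assert state.converged and np.allclose(state.activities, 0.0)


def test_knockout_clamps_node_off(chain_network):
    model = compile_model(chain_network)
    stim = SimulationConfig(inputs={"ISO": 1.0})
    assert integrate(model, stim).state["ANP"] > 0.9
    ko = SimulationConfig(inputs={"ISO": 1.0}, knockouts=["ADRB1"])
    state = integrate(model, ko).state
    assert state["ADRB1"] == 0.0 and state["ANP"] < 1e-3


def test_overexpression_drives_node_to_ymax(chain_network):
    config = SimulationConfig(overexpression=["ADRB1"])
    state = integrate(compile_model(chain_network), config).state
    assert state["ADRB1"] == pytest.approx(1.0, abs=1e-4)
    assert state["ANP"] > 0.9


def test_stimulus_on_regulated_node_is_or_combined(chain_network):
    # a node with upstream regulation can still receive an external stimulus
    config = SimulationConfig(inputs={"ADRB1": 1.0})
    state = integrate(compile_model(chain_network), config).state
    assert state["ADRB1"] == pytest.approx(1.0, abs=1e-4)


@pytest.mark.parametrize("seed", range(10))
def test_trajectories_bounded(seed):
    spec = SyntheticSpec(n_nodes=25, n_inputs=3, n_outputs=4,
                         mean_in_degree=1.8, feedback_frac=0.2, seed=seed)
    net = generate_network(spec)
    model = compile_model(net)
    inputs = {nid: 1.0 for nid in net.input_nodes}
    result = integrate(model, SimulationConfig(inputs=inputs))
    assert np.all(result.y >= -1e-9)
    assert np.all(result.y <= model.ymax[None, :] + 1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_oracle_agrees_with_integrator_on_acyclic_models(seed):
    spec = SyntheticSpec(n_nodes=40, n_inputs=4, n_outputs=6,
                         mean_in_degree=1.6, seed=100 + seed)
    net = generate_network(spec)
    model = compile_model(net)
    config = SimulationConfig(inputs={nid: 0.8 for nid in net.input_nodes})
    s_int = integrate(model, config).state
    s_fix = steady_state_oracle(model, config)
    assert s_int.converged and s_fix.converged
    assert np.max(np.abs(s_int.activities - s_fix.activities)) < 1e-5


def test_oracle_identity_model_is_zero():
    net = Network(nodes=[Node("A"), Node("B", y0=0.4)], reactions=[])
    state = steady_state_oracle(compile_model(net))
    assert state.converged and np.allclose(state.activities, 0.0, atol=1e-6)


def test_negative_feedback_is_flagged_or_converges():
    # two-node mutual antagonism with strong drive: the oracle must either
    # converge or report non-convergence, never silently return garbage
    net = Network(
        nodes=[Node("A"), Node("B")],
        reactions=[
            Reaction("=> A", weight=1.0),
            Reaction("!B => A"),
            Reaction("A => B"),
            Reaction("!A => B"),
        ],
    )
    model = compile_model(net)
    state = steady_state_oracle(model, SimulationConfig())
    if state.converged:
        resid = np.max(np.abs(node_rhs(model, state.activities)))
        assert resid <= 1e-6


def test_config_rejects_bad_tolerances_and_weights():
    with pytest.raises(ValueError):
        SimulationConfig(ss_tol=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(inputs={"A": 1.5})
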