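"""Logic-based differential equation simulation of signaling networks.

Each node carries a normalized activity y in [0, ymax]. A reaction's flux is
its weight times an AND-gate over regulators: activators contribute a
normalized Hill activation f(y), inhibitors the complement 1 - f(y). Multiple
reactions converging on one node combine with a probabilistic OR
(f1 + f2 - f1*f2), and each node relaxes toward its gated drive:

    dy_i/dt = (F_i(y) * ymax_i - y_i) / tau_i

The normalized Hill function is constrained to pass through (0,0),
(EC50, 0.5) and (1,1):

    f(x) = B x^n / (K^n + x^n),  B = (EC50^n - 1)/(2 EC50^n - 1),  K^n = B - 1

With default parameters (w = 1, n = 1.4, EC50 = 0.5, tau = 1) the formalism
needs no measured rate constants, which is what makes automated translation
of text-derived reaction lists into predictive models possible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import Network

__all__ = [
    "normalized_hill",
    "hill_constants",
    "CompiledGate",
    "LogicModel",
    "SimulationConfig",
    "SteadyState",
    "SimResult",
    "compile_model",
    "reaction_flux",
    "node_rhs",
    "integrate",
    "steady_state_oracle",
]


def hill_constants(n: float, ec50: float) -> tuple[float, float]:
    """Solve the (0,0)/(EC50,0.5)/(1,1) constraints for B and K^n."""
    if n <= 0:
        raise ValueError("Hill coefficient n must be > 0")
    if not (0.0 < ec50 < 1.0):
        raise ValueError("EC50 must be in (0, 1)")
    denom = 2.0 * ec50**n - 1.0
    if abs(denom) < 1e-12:
        raise ValueError(f"degenerate Hill constants: 2*EC50^n = 1 (n={n}, EC50={ec50})")
    B = (ec50**n - 1.0) / denom
    Kn = B - 1.0
    return B, Kn


def normalized_hill(x, n: float = 1.4, ec50: float = 0.5):
    """Normalized Hill activation f(x) on [0,1]; inputs clamped, output clamped."""
    B, Kn = hill_constants(n, ec50)
    x = np.clip(x, 0.0, 1.0)
    xn = x**n
    return np.clip(B * xn / (Kn + xn), 0.0, 1.0)


@dataclass
class CompiledGate:
    """One reaction compiled to index form with precomputed Hill constants."""

    weight: float
    n: float
    ec50: float
    act_idx: np.ndarray  # activator node indices
    inh_idx: np.ndarray  # inhibitor node indices
    target_idx: int
    B: float = 0.0
    Kn: float = 0.0

    def __post_init__(self) -> None:
        self.B, self.Kn = hill_constants(self.n, self.ec50)


@dataclass
class LogicModel:
    """A network compiled to an ODE system ready for integration."""

    node_ids: list[str]
    y0: np.ndarray
    ymax: np.ndarray
    tau: np.ndarray
    gates: list[CompiledGate]
    by_target: list[list[CompiledGate]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.by_target:
            self.by_target = [[] for _ in self.node_ids]
            for gate in self.gates:
                self.by_target[gate.target_idx].append(gate)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index(self, node_id: str) -> int:
        return self.node_ids.index(node_id)


@dataclass
class SimulationConfig:
    """Integration settings plus the condition to simulate.

    ``inputs`` overrides the weight of a node's input reaction (adding one if
    the node has none), which is how stimulus levels are set. ``knockouts``
    clamp ymax to 0; ``overexpression`` sets y0 := ymax with input weight 1.
    """

    t_end: float | None = None  # default 40 * max(tau)
    ss_tol: float = 1e-6
    rtol: float = 1e-7
    atol: float = 1e-9
    inputs: dict[str, float] = field(default_factory=dict)
    knockouts: list[str] = field(default_factory=list)
    overexpression: list[str] = field(default_factory=list)
    n_eval: int = 101  # trajectory sampling points

    def __post_init__(self) -> None:
        for val in (self.ss_tol, self.rtol, self.atol):
            if val <= 0:
                raise ValueError("tolerances must be > 0")
        for node, w in self.inputs.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"input weight for {node} must be in [0,1], got {w}")


@dataclass
class SteadyState:
    """Final activities of a run; ``converged`` means max|dy/dt| <= ss_tol."""

    activities: np.ndarray
    converged: bool
    t_reached: float
    node_ids: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.activities, index=self.node_ids, name="activity")

    def __getitem__(self, node_id: str) -> float:
        return float(self.activities[self.node_ids.index(node_id)])


@dataclass
class SimResult:
    """Trajectory plus the steady state reached."""

    t: np.ndarray
    y: np.ndarray  # shape (n_times, n_nodes)
    state: SteadyState
    node_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.y, columns=self.node_ids)
        frame.insert(0, "time", self.t)
        return frame


def compile_model(net: Network) -> LogicModel:
    """Compile a validated network into index-based ODE form."""
    index = {nid: i for i, nid in enumerate(net.node_ids)}
    gates = []
    for rxn in net.reactions:
        acts, inhs = [], []
        for reg, sign in rxn.regulators:
            (acts if sign > 0 else inhs).append(index[reg])
        gates.append(
            CompiledGate(
                weight=rxn.weight,
                n=rxn.n,
                ec50=rxn.ec50,
                act_idx=np.asarray(acts, dtype=int),
                inh_idx=np.asarray(inhs, dtype=int),
                target_idx=index[rxn.target],
            )
        )
    return LogicModel(
        node_ids=list(net.node_ids),
        y0=np.array([n.y0 for n in net.nodes], dtype=float),
        ymax=np.array([n.ymax for n in net.nodes], dtype=float),
        tau=np.array([n.tau for n in net.nodes], dtype=float),
        gates=gates,
    )


def _gate_hill(gate: CompiledGate, x: np.ndarray):
    xn = np.clip(x, 0.0, 1.0) ** gate.n
    return np.clip(gate.B * xn / (gate.Kn + xn), 0.0, 1.0)


def reaction_flux(gate: CompiledGate, y: np.ndarray, ymax: np.ndarray) -> float:
    """w * prod f(activators) * prod (1 - f(inhibitors)); inputs return w."""
    flux = gate.weight
    # knocked-out regulators (ymax 0) are treated as fully inactive
    if gate.act_idx.size:
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(ymax[gate.act_idx] > 0, y[gate.act_idx] / ymax[gate.act_idx], 0.0)
        flux *= float(np.prod(_gate_hill(gate, x)))
    if gate.inh_idx.size:
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(ymax[gate.inh_idx] > 0, y[gate.inh_idx] / ymax[gate.inh_idx], 0.0)
        flux *= float(np.prod(1.0 - _gate_hill(gate, x)))
    return flux


def _drive(model: LogicModel, y: np.ndarray) -> np.ndarray:
    """Per-node OR-combined activation F(y) in [0,1]."""
    F = np.zeros(model.n_nodes)
    for i, gates in enumerate(model.by_target):
        if not gates:
            continue
        none_active = 1.0
        for gate in gates:
            none_active *= 1.0 - reaction_flux(gate, y, model.ymax)
        F[i] = 1.0 - none_active
    return F


def node_rhs(model: LogicModel, y: np.ndarray) -> np.ndarray:
    """dy/dt = (F(y) * ymax - y) / tau, with y clamped to [0, ymax] inside."""
    y = np.clip(y, 0.0, model.ymax)
    return (_drive(model, y) * model.ymax - y) / model.tau


def apply_conditions(model: LogicModel, config: SimulationConfig) -> LogicModel:
    """Return a copy of the model with inputs, knockouts, and over-expression applied.

    Condition nodes absent from the model are skipped: a model that lacks the
    perturbed species simply cannot respond to the perturbation.
    """
    model = copy.deepcopy(model)
    known = set(model.node_ids)
    for node, weight in config.inputs.items():
        if node not in known:
            continue
        idx = model.index(node)
        input_gates = [g for g in model.by_target[idx]
                       if g.act_idx.size == 0 and g.inh_idx.size == 0]
        if input_gates:
            for gate in input_gates:
                gate.weight = weight
        else:
            gate = CompiledGate(weight, 1.4, 0.5,
                                np.empty(0, dtype=int), np.empty(0, dtype=int), idx)
            model.gates.append(gate)
            model.by_target[idx].append(gate)
    for node in config.overexpression:
        if node not in known:
            continue
        idx = model.index(node)
        model.y0[idx] = model.ymax[idx]
        gate = CompiledGate(1.0, 1.4, 0.5,
                            np.empty(0, dtype=int), np.empty(0, dtype=int), idx)
        model.gates.append(gate)
        model.by_target[idx].append(gate)
    for node in config.knockouts:
        if node not in known:
            continue
        idx = model.index(node)
        model.ymax[idx] = 0.0
        model.y0[idx] = 0.0
    return model


def integrate(model: LogicModel, config: SimulationConfig | None = None) -> SimResult:
    """Adaptive stiff-capable integration from y0 until steady state or t_end.

    Terminates early when max|dy/dt| drops below ``ss_tol`` (a terminal event,
    so the criterion is step-size independent).
    """
    config = config or SimulationConfig()
    model = apply_conditions(model, config)
    if model.n_nodes == 0:  # degenerate: nothing to integrate
        state = SteadyState(np.empty(0), True, 0.0, [])
        return SimResult(np.array([0.0]), np.empty((1, 0)), state, [])
    t_end = config.t_end if config.t_end is not None else 40.0 * float(model.tau.max())
    y0 = np.clip(model.y0, 0.0, model.ymax)

    def rhs(_t, y):
        return node_rhs(model, y)

    def at_steady_state(_t, y):
        return float(np.max(np.abs(node_rhs(model, y)))) - config.ss_tol

    if at_steady_state(0.0, y0) <= 0.0:
        state = SteadyState(y0.copy(), True, 0.0, list(model.node_ids))
        return SimResult(np.array([0.0]), y0[None, :], state, list(model.node_ids))

    at_steady_state.terminal = True
    at_steady_state.direction = -1
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        rtol=config.rtol,
        atol=config.atol,
        t_eval=np.linspace(0.0, t_end, config.n_eval),
        events=at_steady_state,
        dense_output=False,
    )
    if sol.status == -1:
        raise RuntimeError(f"integration failed: {sol.message}; last state {sol.y[:, -1]}")
    if sol.status == 1 and sol.t_events[0].size:  # steady-state event
        t_final = float(sol.t_events[0][0])
        y_final = sol.y_events[0][0]
        t = np.append(sol.t, t_final)
        y = np.vstack([sol.y.T, y_final])
    else:
        t_final = float(sol.t[-1])
        y_final = sol.y[:, -1]
        t = sol.t
        y = sol.y.T
    y = np.clip(y, 0.0, model.ymax)
    y_final = np.clip(y_final, 0.0, model.ymax)
    converged = float(np.max(np.abs(node_rhs(model, y_final)))) <= config.ss_tol * 1.01
    state = SteadyState(y_final, converged, t_final, list(model.node_ids))
    return SimResult(t, y, state, list(model.node_ids))


def steady_state_oracle(
    model: LogicModel,
    config: SimulationConfig | None = None,
    damping: float = 0.5,
    max_iter: int = 20000,
) -> SteadyState:
    """Damped fixed-point solution of y = F(y) * ymax.

    Independent of the time integrator; used to cross-check steady states on
    small models. Non-convergence (oscillatory or multistable systems) is
    reported via ``converged=False`` rather than raised.
    """
    config = config or SimulationConfig()
    model = apply_conditions(model, config)
    if model.n_nodes == 0:
        return SteadyState(np.empty(0), True, 0.0, [])
    y = np.clip(model.y0, 0.0, model.ymax)
    for iteration in range(max_iter):
        target = _drive(model, y) * model.ymax
        y_next = (1.0 - damping) * y + damping * target
        y = np.clip(y_next, 0.0, model.ymax)
        residual = float(np.max(np.abs(node_rhs(model, y))))
        if residual <= config.ss_tol * 0.1:
            return SteadyState(y, True, float(iteration), list(model.node_ids))
    return SteadyState(y, False, float(max_iter), list(model.node_ids))
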