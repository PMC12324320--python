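"""Qualitative validation of simulated perturbation responses.

Each experiment records a condition (stimulus inputs and an optional
knockout/over-expression), an output node, and the literature-reported
qualitative outcome (increase / decrease / no_change). The model is simulated
to steady state under control and condition; the predicted direction of the
output's change is compared with the expected one, and accuracy is the
percentage of scorable experiments matched.

A model that lacks the output node cannot respond, so its prediction is
no_change by default (configurably, such experiments can instead be excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .network import normalize_id
from .sim import LogicModel, SimulationConfig, SteadyState, integrate

__all__ = [
    "Experiment",
    "ValidationResult",
    "ValidationReport",
    "classify_change",
    "run_experiment",
    "score_validation",
    "read_experiments",
    "write_experiments",
    "DEFAULT_EPSILON",
]

logger = logging.getLogger(__name__)

#: classification threshold on normalized activity change
DEFAULT_EPSILON = 1e-3

_CLASSES = ("increase", "decrease", "no_change")


@dataclass
class Experiment:
    """One validation record from the experiment table."""

    id: str
    condition: dict[str, float]
    output: str
    expected: str
    knockouts: list[str] = field(default_factory=list)
    overexpression: list[str] = field(default_factory=list)
    reference: str = ""

    def __post_init__(self) -> None:
        if self.expected not in _CLASSES:
            raise ValueError(f"expected must be one of {_CLASSES}, got {self.expected!r}")
        self.output = normalize_id(self.output)
        self.condition = {normalize_id(k): float(v) for k, v in self.condition.items()}
        self.knockouts = [normalize_id(k) for k in self.knockouts]
        self.overexpression = [normalize_id(k) for k in self.overexpression]


@dataclass
class ValidationResult:
    experiment_id: str
    predicted: str
    expected: str
    match: bool
    delta: float
    scorable: bool = True
    missing_output: bool = False


@dataclass
class ValidationReport:
    results: list[ValidationResult]
    n_experiments: int
    n_scorable: int
    accuracy_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.experiment_id, r.predicted, r.expected, r.match, r.delta,
                 r.scorable, r.missing_output)
                for r in self.results
            ],
            columns=["id", "predicted", "expected", "match", "delta",
                     "scorable", "missing_output"],
        )


def classify_change(y_condition: float, y_control: float,
                    epsilon: float = DEFAULT_EPSILON) -> str:
    """Direction of the activity change, with a dead-band of width epsilon.

    Strict inequalities: a change of exactly +/- epsilon is no_change.
    """
    delta = y_condition - y_control
    if delta > epsilon:
        return "increase"
    if delta < -epsilon:
        return "decrease"
    return "no_change"


def _condition_config(baseline: SimulationConfig, exp: Experiment) -> SimulationConfig:
    return SimulationConfig(
        t_end=baseline.t_end,
        ss_tol=baseline.ss_tol,
        rtol=baseline.rtol,
        atol=baseline.atol,
        inputs={**baseline.inputs, **exp.condition},
        knockouts=[*baseline.knockouts, *exp.knockouts],
        overexpression=[*baseline.overexpression, *exp.overexpression],
        n_eval=baseline.n_eval,
    )


def run_experiment(
    model: LogicModel,
    exp: Experiment,
    baseline: SimulationConfig | None = None,
    epsilon: float = DEFAULT_EPSILON,
    control_state: SteadyState | None = None,
    condition_state: SteadyState | None = None,
) -> ValidationResult:
    """Simulate control vs condition and classify the output's response.

    ``control_state`` lets a caller reuse one baseline steady state across a
    whole experiment table. A model without the output node predicts
    no_change (it cannot respond); a non-converged simulation makes the
    experiment unscorable.
    """
    baseline = baseline or SimulationConfig()
    if exp.output not in model.node_ids:
        predicted = "no_change"
        return ValidationResult(exp.id, predicted, exp.expected,
                                predicted == exp.expected, 0.0, missing_output=True)
    try:
        if control_state is None:
            control_state = integrate(model, baseline).state
        cond_state = condition_state
        if cond_state is None:
            cond_state = integrate(model, _condition_config(baseline, exp)).state
    except RuntimeError as err:
        logger.warning("experiment %s: simulation failed (%s)", exp.id, err)
        return ValidationResult(exp.id, "no_change", exp.expected, False, 0.0,
                                scorable=False)
    if not (control_state.converged and cond_state.converged):
        return ValidationResult(exp.id, "no_change", exp.expected, False, 0.0,
                                scorable=False)
    delta = cond_state[exp.output] - control_state[exp.output]
    predicted = classify_change(cond_state[exp.output], control_state[exp.output], epsilon)
    return ValidationResult(exp.id, predicted, exp.expected,
                            predicted == exp.expected, delta)


def score_validation(
    model: LogicModel,
    experiments: list[Experiment],
    baseline: SimulationConfig | None = None,
    epsilon: float = DEFAULT_EPSILON,
    missing_output: str = "count",
) -> ValidationReport:
    """Accuracy (percent) of the model over a table of experiments.

    ``missing_output`` is ``"count"`` (a missing output node scores as a
    no_change prediction, usually a mismatch) or ``"exclude"`` (such
    experiments are dropped from the denominator). Unscorable experiments
    (non-converged simulations) are always excluded and reported.
    """
    if missing_output not in ("count", "exclude"):
        raise ValueError("missing_output must be 'count' or 'exclude'")
    baseline = baseline or SimulationConfig()
    control_state: SteadyState | None = None
    try:
        control_state = integrate(model, baseline).state
        if not control_state.converged:
            control_state = None
    except RuntimeError:
        control_state = None
    # experiment tables reuse a handful of conditions; simulate each once
    condition_cache: dict[tuple, SteadyState | None] = {}
    results = []
    for exp in experiments:
        key = (
            tuple(sorted(exp.condition.items())),
            tuple(sorted(exp.knockouts)),
            tuple(sorted(exp.overexpression)),
        )
        cond_state = condition_cache.get(key)
        if cond_state is None and key not in condition_cache and exp.output in model.node_ids:
            try:
                cond_state = integrate(model, _condition_config(baseline, exp)).state
            except RuntimeError:
                cond_state = None
            condition_cache[key] = cond_state
        results.append(
            run_experiment(model, exp, baseline, epsilon,
                           control_state=control_state, condition_state=cond_state)
        )
    scorable = [
        r for r in results
        if r.scorable and not (missing_output == "exclude" and r.missing_output)
    ]
    if not scorable:
        raise ValueError("no scorable experiments")
    accuracy = 100.0 * sum(r.match for r in scorable) / len(scorable)
    n_unscorable = len(results) - len(scorable)
    if n_unscorable:
        logger.info("%d experiment(s) excluded from scoring", n_unscorable)
    return ValidationReport(results, len(results), len(scorable), accuracy)


# --- experiment table I/O ----------------------------------------------------
# columns: id, inputs ("A=1;B=0.5"), perturbation ("KO:NODE" / "OE:NODE",
# semicolon-separated, may be empty), output, expected, reference

_COLUMNS = ["id", "inputs", "perturbation", "output", "expected", "reference"]


def _parse_inputs(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        node, _, weight = item.partition("=")
        out[node.strip()] = float(weight) if weight else 1.0
    return out


def read_experiments(path: str | Path) -> list[Experiment]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"experiment table missing column(s): {sorted(missing)}")
    experiments = []
    for _, row in frame.iterrows():
        knockouts, overexpression = [], []
        for item in str(row["perturbation"]).split(";"):
            item = item.strip()
            if not item:
                continue
            kind, _, node = item.partition(":")
            if kind.upper() == "KO":
                knockouts.append(node)
            elif kind.upper() == "OE":
                overexpression.append(node)
            else:
                raise ValueError(f"unknown perturbation spec: {item!r}")
        experiments.append(
            Experiment(
                id=str(row["id"]),
                condition=_parse_inputs(row["inputs"]),
                output=str(row["output"]),
                expected=str(row["expected"]),
                knockouts=knockouts,
                overexpression=overexpression,
                reference=str(row["reference"]),
            )
        )
    return experiments


def write_experiments(experiments: list[Experiment], path: str | Path) -> None:
    rows = []
    for exp in experiments:
        inputs = ";".join(f"{k}={v:g}" for k, v in exp.condition.items())
        perturbation = ";".join(
            [f"KO:{k}" for k in exp.knockouts] + [f"OE:{k}" for k in exp.overexpression]
        )
        rows.append((exp.id, inputs, perturbation, exp.output, exp.expected, exp.reference))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
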