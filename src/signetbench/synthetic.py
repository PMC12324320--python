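"""Synthetic inputs for end-to-end pipeline testing.

Everything the benchmarking pipeline consumes can be generated here with a
seed: layered ground-truth networks shaped like curated signaling models
(stimulus inputs feeding intermediate cascades feeding output genes),
corrupted predictions with an exactly planted recall, plain-text transcripts
in the phrasing dialects different language models use, and experiment
tables whose expected outcomes come from simulating the ground truth itself.

The point of the planted-truth design is that downstream scores have known
exact values: a corrupted network that keeps k of m ground-truth edges must
measure recall k/m, and a ground-truth model scored on its own experiment
table must reach 100% accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network, SignedEdge, network_from_edges, to_signed_edges
from .sim import SimulationConfig, compile_model, integrate
from .validate import DEFAULT_EPSILON, Experiment, classify_change

__all__ = [
    "SyntheticSpec",
    "NoiseSpec",
    "CorruptionResult",
    "generate_network",
    "corrupt_network",
    "render_llm_transcript",
    "generate_experiments",
    "TRANSCRIPT_DIALECTS",
]

TRANSCRIPT_DIALECTS = ("plain", "bulleted", "arrow")


@dataclass
class SyntheticSpec:
    """Shape parameters for a generated ground-truth network.

    ``n_reactions`` counts input reactions plus regulator reactions, matching
    how curated Netflux models report their size. If omitted it is derived
    from ``mean_in_degree`` over the non-input nodes. A quarter of regulator
    edges are inhibitory by default, a rough signaling-network proportion.
    """

    n_nodes: int
    n_inputs: int = 4
    n_outputs: int = 6
    n_reactions: int | None = None
    mean_in_degree: float = 1.5
    frac_inhibitory: float = 0.25
    feedback_frac: float = 0.0
    and_frac: float = 0.0  # fraction of multi-regulator targets gated with AND
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_outputs < 0:
            raise ValueError("need n_inputs >= 1 and n_outputs >= 0")
        if self.n_inputs + self.n_outputs > self.n_nodes:
            raise ValueError("n_inputs + n_outputs must not exceed n_nodes")
        n_regulated = self.n_nodes - self.n_inputs
        if self.n_reactions is None:
            self.n_reactions = self.n_inputs + max(
                n_regulated, round(self.mean_in_degree * n_regulated)
            )
        if self.n_reactions < self.n_inputs + n_regulated:
            raise ValueError(
                "n_reactions too small: every non-input node needs >= 1 regulator"
            )


def _node_names(spec: SyntheticSpec) -> list[str]:
    inputs = [f"IN{i + 1}" for i in range(spec.n_inputs)]
    n_mid = spec.n_nodes - spec.n_inputs - spec.n_outputs
    mids = [f"M{i + 1}" for i in range(n_mid)]
    outs = [f"OUT{i + 1}" for i in range(spec.n_outputs)]
    return inputs + mids + outs


def generate_network(spec: SyntheticSpec, name: str = "synthetic",
                     phenotype: str = "synthetic") -> Network:
    """Layered directed network: inputs -> intermediates -> outputs.

    Every non-input node receives at least one regulator from an earlier
    node, so the default graph is acyclic and fully driven by its inputs;
    ``feedback_frac`` adds backward edges on top. Deterministic in the seed.
    """
    rng = np.random.default_rng(spec.seed)
    names = _node_names(spec)
    order = {nid: i for i, nid in enumerate(names)}
    edges: set[tuple[str, str]] = set()
    signed: list[SignedEdge] = []

    def add_edge(src: str, dst: str) -> None:
        sign = -1 if rng.random() < spec.frac_inhibitory else +1
        edges.add((src, dst))
        signed.append(SignedEdge(src, dst, sign))

    # backbone: one upstream regulator per non-input node
    for i in range(spec.n_inputs, spec.n_nodes):
        src = names[int(rng.integers(0, i))]
        add_edge(src, names[i])

    n_extra = spec.n_reactions - spec.n_inputs - (spec.n_nodes - spec.n_inputs)
    n_feedback = round(spec.feedback_frac * n_extra)
    attempts = 0
    while n_extra > 0 and attempts < 100 * spec.n_reactions:
        attempts += 1
        i, j = rng.integers(0, spec.n_nodes, size=2)
        if i == j:
            continue
        backward = order[names[int(i)]] > order[names[int(j)]]
        if backward and n_feedback <= 0:
            continue
        if int(j) < spec.n_inputs:  # inputs are driven externally only
            continue
        src, dst = names[int(i)], names[int(j)]
        if (src, dst) in edges:
            continue
        add_edge(src, dst)
        n_extra -= 1
        if backward:
            n_feedback -= 1
    if n_extra > 0:
        raise ValueError("infeasible spec: could not place all requested reactions")

    net = network_from_edges(signed, name=name, phenotype=phenotype,
                             node_universe=names, basal_weight=0.0)
    if spec.and_frac > 0:
        net = _merge_and_gates(net, spec.and_frac, rng)
    return net


def _merge_and_gates(net: Network, and_frac: float, rng: np.random.Generator) -> Network:
    """Merge pairs of single-regulator reactions on shared targets into AND rules."""
    from collections import defaultdict

    from .network import Reaction, build_rule

    by_target: dict[str, list] = defaultdict(list)
    keep = []
    for rxn in net.reactions:
        if rxn.is_input:
            keep.append(rxn)
        else:
            by_target[rxn.target].append(rxn)
    for target, rxns in by_target.items():
        if len(rxns) >= 2 and rng.random() < and_frac:
            merged_regs = rxns[0].regulators + rxns[1].regulators
            acts = [r for r, s in merged_regs if s > 0]
            inhs = [r for r, s in merged_regs if s < 0]
            keep.append(Reaction(build_rule(acts, inhs, target)))
            keep.extend(rxns[2:])
        else:
            keep.extend(rxns)
    return Network(name=net.name, phenotype=net.phenotype,
                   nodes=list(net.nodes), reactions=keep)


@dataclass
class CorruptionResult:
    """A degraded copy of a ground truth with the planted truth recorded."""

    network: Network
    kept: set[SignedEdge]       # true edges surviving with correct sign
    flipped: set[SignedEdge]    # true edges kept but with sign inverted
    spurious: set[SignedEdge]   # edges absent from the ground truth

    @property
    def edges(self) -> set[SignedEdge]:
        return self.kept | self.flipped | self.spurious


def corrupt_network(
    gt: Network,
    recall_target: float,
    n_spurious: int = 0,
    sign_flip_rate: float = 0.0,
    seed: int = 0,
) -> CorruptionResult:
    """Degrade a ground truth to emulate partial text-mined reconstruction.

    Keeps exactly ``round(recall_target * m)`` of the m ground-truth signed
    edges (uniform, without replacement), inverts the sign of a fraction of
    the kept edges, and adds ``n_spurious`` edges between node pairs with no
    ground-truth interaction. Sign flips and spurious edges do not match any
    ground-truth edge, so the measured recall equals the planted one exactly.
    """
    if not (0.0 <= recall_target <= 1.0):
        raise ValueError("recall_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gt_edges = sorted(to_signed_edges(gt))
    m = len(gt_edges)
    n_keep = round(recall_target * m)
    kept_idx = rng.choice(m, size=n_keep, replace=False)
    kept = {gt_edges[i] for i in sorted(kept_idx)}

    n_flip = round(sign_flip_rate * n_keep)
    flip_choice = rng.choice(n_keep, size=n_flip, replace=False) if n_flip else []
    kept_list = sorted(kept)
    flipped = {
        SignedEdge(e.source, e.target, -e.sign)
        for e in (kept_list[i] for i in sorted(flip_choice))
    }
    kept -= {SignedEdge(e.source, e.target, -e.sign) for e in flipped}

    gt_pairs = {(e.source, e.target) for e in gt_edges}
    ids = gt.node_ids
    candidates = [
        (a, b) for a in ids for b in ids if a != b and (a, b) not in gt_pairs
    ]
    if n_spurious > len(candidates):
        raise ValueError(f"n_spurious={n_spurious} exceeds {len(candidates)} available non-edges")
    spurious = set()
    if n_spurious:
        chosen = rng.choice(len(candidates), size=n_spurious, replace=False)
        for i in sorted(chosen):
            a, b = candidates[i]
            sign = -1 if rng.random() < 0.5 else +1
            spurious.add(SignedEdge(a, b, sign))

    pred_edges = kept | flipped | spurious
    node_params = {n.id: n for n in gt.nodes}
    network = network_from_edges(
        pred_edges, name=f"{gt.name}-corrupt", phenotype=gt.phenotype,
        node_params=node_params,
    )
    return CorruptionResult(network, kept, flipped, spurious)


@dataclass
class NoiseSpec:
    """How much non-statement text to interleave into a rendered transcript.

    Noise lines never place a lexicon verb between two in-list symbols, so
    the planted edge set survives parse + filter exactly.
    """

    n_prose: int = 0
    n_nondirectional: int = 0
    n_out_of_list: int = 0


_PROSE = [
    "Here are the direct interactions supported by the literature:",
    "Based on the available literature, I can identify the following interactions.",
    "Let me know if you would like references for any of these.",
    "These interactions are well established in the signaling literature.",
]

_ACT_VERBS = ["stimulates", "activates", "up-regulates", "induces", "promotes"]
_INH_VERBS = ["inhibits", "down-regulates", "suppresses", "represses", "blocks"]


def _statement_line(edge: SignedEdge, dialect: str, index: int,
                    rng: np.random.Generator) -> str:
    verbs = _ACT_VERBS if edge.sign > 0 else _INH_VERBS
    verb = verbs[int(rng.integers(0, len(verbs)))]
    if dialect == "plain":
        return f"{edge.source} {verb} {edge.target}"
    if dialect == "bulleted":
        return f"{index}. {edge.source} → {edge.target} ({verb})"
    if dialect == "arrow":
        kind = "activation" if edge.sign > 0 else "inhibition"
        return f"{edge.source} -> {edge.target}: {kind}"
    raise ValueError(f"unknown dialect: {dialect!r}")


def render_llm_transcript(
    edges: list[SignedEdge],
    dialect: str = "plain",
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> str:
    """Render edges as a reply transcript in one of the phrasing dialects.

    ``plain``: "A stimulates B"; ``bulleted``: "1. A → B (stimulates)";
    ``arrow``: "A -> B: activation". Noise lines (prose, non-directional
    claims, statements about out-of-list symbols) are interleaved at seeded
    random positions.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    edges = sorted(set(edges))
    lines = [
        _statement_line(edge, dialect, i + 1, rng) for i, edge in enumerate(edges)
    ]
    in_list = sorted({e.source for e in edges} | {e.target for e in edges}) or ["NODEA"]
    noise_lines: list[str] = []
    for i in range(noise.n_prose):
        noise_lines.append(_PROSE[int(rng.integers(0, len(_PROSE)))])
    for i in range(noise.n_nondirectional):
        a, b = rng.choice(in_list, size=2)
        noise_lines.append(f"{a} interacts with {b}")
    for i in range(noise.n_out_of_list):
        a = in_list[int(rng.integers(0, len(in_list)))]
        verb = _ACT_VERBS[int(rng.integers(0, len(_ACT_VERBS)))]
        noise_lines.append(f"{a} {verb} OFFLIST{i + 1}")
    for line in noise_lines:
        pos = int(rng.integers(0, len(lines) + 1))
        lines.insert(pos, line)
    header = _PROSE[0] if not lines or lines[0] not in _PROSE else ""
    body = "\n".join(lines)
    return f"{header}\n{body}\n" if header else body + "\n"


def generate_experiments(
    gt: Network,
    n_experiments: int,
    epsilon: float = DEFAULT_EPSILON,
    seed: int = 0,
    stimulus_weight: float = 1.0,
    min_informative_frac: float = 0.5,
    max_conditions: int | None = None,
) -> list[Experiment]:
    """Simulate the ground truth to build a self-consistent experiment table.

    Samples stimulus conditions (one input node driven at ``stimulus_weight``),
    simulates the ground-truth model to steady state, and records each sampled
    output's classified response as the expected outcome — so the generating
    model scores 100% on its own table when the same epsilon is used. At least
    ``min_informative_frac`` of the rows get a non-no_change outcome where the
    network can provide them.
    """
    inputs = gt.input_nodes
    outputs = [nid for nid in gt.node_ids if nid not in inputs]
    if not inputs or not outputs:
        raise ValueError("ground truth needs >= 1 input and >= 1 non-input node")
    rng = np.random.default_rng(seed)
    model = compile_model(gt)
    baseline = SimulationConfig()
    control = integrate(model, baseline).state

    # steady states per single-stimulus condition; each yields every output
    states: dict[str, object] = {}
    order = list(rng.permutation(inputs))
    if max_conditions is not None:
        order = order[:max_conditions]
    for node in order:
        condition = SimulationConfig(inputs={node: stimulus_weight})
        result = integrate(model, condition)
        if result.state.converged:
            states[node] = result.state

    if not states:
        raise ValueError("no stimulus condition reached steady state")

    informative: list[tuple[str, str, str]] = []
    trivial: list[tuple[str, str, str]] = []
    for node, state in states.items():
        for out in outputs:
            outcome = classify_change(state[out], control[out], epsilon)
            record = (node, out, outcome)
            (informative if outcome != "no_change" else trivial).append(record)
    rng.shuffle(informative)
    rng.shuffle(trivial)

    n_informative = min(len(informative),
                        max(round(min_informative_frac * n_experiments), 0))
    chosen = informative[:n_informative]
    pool = informative[n_informative:] + trivial
    rng.shuffle(pool)
    while len(chosen) < n_experiments and pool:
        chosen.append(pool.pop())
    while len(chosen) < n_experiments:  # small networks: sample with replacement
        source = informative or trivial
        chosen.append(source[int(rng.integers(0, len(source)))])
    rng.shuffle(chosen)

    return [
        Experiment(
            id=f"EXP{i + 1:03d}",
            condition={node: stimulus_weight},
            output=out,
            expected=outcome,
            reference="synthetic",
        )
        for i, (node, out, outcome) in enumerate(chosen[:n_experiments])
    ]
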