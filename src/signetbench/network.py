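"""Canonical representation of signaling networks.

A :class:`Network` holds an ordered list of nodes and reactions. Reactions are
written as rule strings in the Netflux convention: ``"A & !B => C"`` means C is
activated by A AND NOT B; ``"=> C"`` is an input (stimulus) reaction driving C
directly with the reaction weight. Networks decompose into sets of signed
directed edges, the common currency for benchmarking a predicted network
against a curated ground truth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

__all__ = [
    "Node",
    "Reaction",
    "SignedEdge",
    "Network",
    "RuleError",
    "NetworkValidationError",
    "normalize_id",
    "parse_rule",
    "build_rule",
    "to_signed_edges",
    "network_from_edges",
]

#: transliteration of Greek letters commonly found in gene/protein symbols
#: (e.g. NFκB -> NFKB, βMHC -> BMHC) applied before case folding
_GREEK = str.maketrans(
    {
        "α": "A", "Α": "A",
        "β": "B", "Β": "B",
        "γ": "G", "Γ": "G",
        "δ": "D", "Δ": "D",
        "ε": "E",
        "κ": "K", "Κ": "K",
        "λ": "L", "Λ": "L",
        "μ": "M",
        "σ": "S", "Σ": "S",
        "ω": "W", "Ω": "W",
    }
)


def normalize_id(symbol: str) -> str:
    """Normalize a node symbol for matching: strip, transliterate Greek, uppercase.

    LLM outputs and curated node tables differ in case and typography, so all
    identity comparisons in this package go through this function.
    """
    return symbol.strip().translate(_GREEK).upper()


class RuleError(ValueError):
    """Raised for a malformed reaction rule string."""


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


def parse_rule(rule: str) -> tuple[list[str], list[str], str]:
    """Split a reaction rule into (activators, inhibitors, target).

    The left side of ``=>`` is an AND-gate of regulators separated by ``&``;
    a ``!`` prefix marks an inhibitor. An empty left side denotes an input
    reaction (no regulators). Tokens are returned verbatim (not normalized).

    >>> parse_rule("A & !B => C")
    (['A'], ['B'], 'C')
    """
    if rule.count("=>") != 1:
        raise RuleError(f"rule must contain exactly one '=>': {rule!r}")
    lhs, rhs = rule.split("=>")
    target = rhs.strip()
    if not target or re.search(r"\s", target):
        raise RuleError(f"rule must have exactly one target node: {rule!r}")
    activators: list[str] = []
    inhibitors: list[str] = []
    lhs = lhs.strip()
    if lhs:
        for token in lhs.split("&"):
            token = token.strip()
            if not token:
                raise RuleError(f"dangling '&' in rule: {rule!r}")
            if token.startswith("!"):
                inhib = token[1:].strip()
                if not inhib:
                    raise RuleError(f"'!' without a node in rule: {rule!r}")
                inhibitors.append(inhib)
            else:
                activators.append(token)
    return activators, inhibitors, target


def build_rule(activators: Iterable[str], inhibitors: Iterable[str], target: str) -> str:
    """Reconstruct a rule string; left inverse of :func:`parse_rule`."""
    terms = list(activators) + [f"!{i}" for i in inhibitors]
    lhs = " & ".join(terms)
    return f"{lhs} => {target}" if lhs else f"=> {target}"


@dataclass
class Node:
    """One signaling species with its logic-ODE state parameters.

    ``y0``/``ymax`` are normalized activities (dimensionless, in [0, 1]);
    ``tau`` is the relaxation time constant in arbitrary time units.
    """

    id: str
    label: str = ""
    y0: float = 0.0
    ymax: float = 1.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        self.id = normalize_id(self.id)
        if not self.id:
            raise NetworkValidationError("node id must be nonempty")
        if not (0.0 <= self.y0 <= self.ymax):
            raise NetworkValidationError(
                f"node {self.id}: require 0 <= y0 <= ymax, got y0={self.y0}, ymax={self.ymax}"
            )
        if self.tau <= 0:
            raise NetworkValidationError(f"node {self.id}: tau must be > 0, got {self.tau}")


@dataclass
class Reaction:
    """One reaction rule with its normalized-Hill parameters.

    Defaults (w=1, n=1.4, EC50=0.5) follow the standard Netflux convention for
    logic-based differential equation models built without measured rate
    constants.
    """

    rule: str
    weight: float = 1.0
    n: float = 1.4
    ec50: float = 0.5

    def __post_init__(self) -> None:
        self.rule = re.sub(r"\s+", " ", self.rule.strip())
        # validates syntax eagerly so a bad rule fails at construction
        parse_rule(self.rule)
        if not (0.0 <= self.weight <= 1.0):
            raise NetworkValidationError(f"reaction {self.rule!r}: weight must be in [0,1]")
        if self.n <= 0:
            raise NetworkValidationError(f"reaction {self.rule!r}: Hill n must be > 0")
        if not (0.0 < self.ec50 < 1.0):
            raise NetworkValidationError(f"reaction {self.rule!r}: EC50 must be in (0,1)")

    @property
    def parsed(self) -> tuple[list[str], list[str], str]:
        return parse_rule(self.rule)

    @property
    def target(self) -> str:
        return normalize_id(self.parsed[2])

    @property
    def regulators(self) -> list[tuple[str, int]]:
        """Normalized (regulator, sign) pairs; empty for input reactions."""
        acts, inhs, _ = self.parsed
        return [(normalize_id(a), +1) for a in acts] + [(normalize_id(i), -1) for i in inhs]

    @property
    def is_input(self) -> bool:
        acts, inhs, _ = self.parsed
        return not acts and not inhs


class SignedEdge(NamedTuple):
    """A directed signed interaction: sign +1 activation, -1 inhibition."""

    source: str
    target: str
    sign: int


@dataclass
class Network:
    """An ordered collection of nodes and reaction rules."""

    name: str = ""
    phenotype: str = ""
    nodes: list[Node] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, strict: bool = False) -> None:
        """Check structural invariants; ``strict`` additionally rejects self-loops."""
        seen: set[str] = set()
        for node in self.nodes:
            if node.id in seen:
                raise NetworkValidationError(f"duplicate node id: {node.id}")
            seen.add(node.id)
        unknown: list[str] = []
        for rxn in self.reactions:
            acts, inhs, target = rxn.parsed
            for sym in [*acts, *inhs, target]:
                if normalize_id(sym) not in seen:
                    unknown.append(sym)
            if strict:
                tgt = normalize_id(target)
                if any(normalize_id(s) == tgt for s in [*acts, *inhs]):
                    raise NetworkValidationError(f"self-loop rejected in strict mode: {rxn.rule!r}")
        if unknown:
            raise NetworkValidationError(
                "reactions reference undeclared node(s): " + ", ".join(sorted(set(unknown)))
            )

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def get_node(self, node_id: str) -> Node:
        nid = normalize_id(node_id)
        for node in self.nodes:
            if node.id == nid:
                return node
        raise KeyError(nid)

    @property
    def input_nodes(self) -> list[str]:
        """Nodes driven by an input reaction ``=> X``, in declaration order."""
        targets = {r.target for r in self.reactions if r.is_input}
        return [n.id for n in self.nodes if n.id in targets]

    def max_out_degree(self) -> int:
        """Maximum number of distinct targets regulated by any single node."""
        out: dict[str, set[str]] = {}
        for edge in to_signed_edges(self):
            out.setdefault(edge.source, set()).add(edge.target)
        return max((len(v) for v in out.values()), default=0)


def to_signed_edges(net: Network) -> set[SignedEdge]:
    """Decompose every reaction into one signed edge per regulator.

    AND-gates contribute one edge per constituent regulator; input reactions
    contribute none; duplicates collapse under set semantics.
    """
    edges: set[SignedEdge] = set()
    for rxn in net.reactions:
        target = rxn.target
        for regulator, sign in rxn.regulators:
            edges.add(SignedEdge(regulator, target, sign))
    return edges


def network_from_edges(
    edges: Iterable[SignedEdge],
    name: str = "",
    phenotype: str = "",
    node_universe: Iterable[str] | None = None,
    basal_weight: float = 0.0,
    node_params: dict[str, Node] | None = None,
) -> Network:
    """Build a network of single-regulator reactions from signed edges.

    Every node that appears gets declared (plus any in ``node_universe``);
    nodes with no incoming reaction receive an input reaction ``=> X`` with
    weight ``basal_weight`` so the resulting ODE system is well-posed.
    Node parameters can be carried over from a template via ``node_params``.
    """
    edges = sorted(set(edges))
    ids: list[str] = []
    seen: set[str] = set()
    for nid in list(node_universe or []) + [e.source for e in edges] + [e.target for e in edges]:
        nid = normalize_id(nid)
        if nid not in seen:
            seen.add(nid)
            ids.append(nid)
    nodes = []
    for nid in ids:
        if node_params and nid in node_params:
            p = node_params[nid]
            nodes.append(Node(nid, p.label, p.y0, p.ymax, p.tau))
        else:
            nodes.append(Node(nid))
    reactions = []
    targeted = {e.target for e in edges}
    for nid in ids:
        if nid not in targeted:
            reactions.append(Reaction(f"=> {nid}", weight=basal_weight))
    for e in edges:
        prefix = "" if e.sign > 0 else "!"
        reactions.append(Reaction(f"{prefix}{e.source} => {e.target}"))
    return Network(name=name, phenotype=phenotype, nodes=nodes, reactions=reactions)
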