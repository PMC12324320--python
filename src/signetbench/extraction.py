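"""Prompt construction, provider querying, and interaction-statement extraction.

The querying protocol batches a gene list (default 20 symbols per batch),
asks for directed interactions among list members in the context of a named
phenotype, and iterates with a continuation prompt until the list is
exhausted. Replies are persisted verbatim as plain-text transcripts, one file
per replicate, and mined line-by-line with regular expressions for statements
of the form "ADRB2 stimulates RAC1" (several formatting dialects are
tolerated). Only signed, directional statements whose endpoints resolve to
the gene list survive filtering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Protocol

from .network import Network, SignedEdge, network_from_edges, normalize_id

__all__ = [
    "DEFAULT_LEXICON",
    "PromptBatch",
    "RawResponse",
    "MissingBatch",
    "InteractionStatement",
    "Provider",
    "ReplayProvider",
    "ScriptedProvider",
    "chunk_genes",
    "build_prompt",
    "query_provider",
    "parse_response",
    "filter_statements",
    "statements_to_network",
    "read_transcript",
    "BATCH_SEPARATOR",
]

logger = logging.getLogger(__name__)

#: verb -> sign. The directional verbs accepted by default; configurable because
#: different models phrase interactions differently. Noun forms cover arrow
#: notations like "A -> B: inhibition".
DEFAULT_LEXICON: dict[str, int] = {
    "stimulates": +1,
    "activates": +1,
    "up-regulates": +1,
    "upregulates": +1,
    "generates": +1,
    "induces": +1,
    "promotes": +1,
    "inhibits": -1,
    "down-regulates": -1,
    "downregulates": -1,
    "suppresses": -1,
    "represses": -1,
    "blocks": -1,
    # noun forms used in parenthetical / colon annotations
    "stimulation": +1,
    "activation": +1,
    "inhibition": -1,
    "repression": -1,
}

BATCH_SEPARATOR = "### batch {index} ###"

INITIAL_TEMPLATE = (
    "For the first {batch_size} entries in this list of genes, proteins, and "
    "other signaling nodes from a {phenotype} network, please provide more "
    "than 0 but fewer than {max_connections} direct interactions with other "
    "nodes from the list supported by available literature. Simply list the "
    "input node, affected node, and if the affected node is stimulated / "
    "inhibited."
)
CONTINUATION_TEMPLATE = (
    "That looks great! Please do the same operation for the next "
    "{chunk_len} nodes! Thank you"
)
GENE_LIST_HEADER = "List of genes and other signaling nodes:"


@dataclass
class PromptBatch:
    """One step of the iterative query over a chunk of the gene list."""

    phenotype: str
    gene_chunk: list[str]
    batch_size: int = 20
    max_connections: int = 1
    step: str = "initial"  # or "continuation"

    def __post_init__(self) -> None:
        if not (1 <= len(self.gene_chunk) <= self.batch_size):
            raise ValueError("require 1 <= |gene_chunk| <= batch_size")
        if self.max_connections < 1:
            raise ValueError("max_connections must be >= 1")
        if self.step not in ("initial", "continuation"):
            raise ValueError(f"unknown step: {self.step!r}")


@dataclass
class RawResponse:
    """A verbatim provider reply for one batch."""

    text: str
    replicate_id: int = 1
    batch_index: int = 0
    provider_tag: str = ""


@dataclass
class MissingBatch:
    """Placeholder for a batch whose query failed after all retries."""

    replicate_id: int
    batch_index: int
    provider_tag: str = ""
    error: str = ""


@dataclass
class InteractionStatement:
    """One parsed (source, target, sign) claim with its provenance."""

    source: str
    target: str
    verb: str
    sign: int
    raw_line: str = ""
    replicate_id: int = 0
    batch_index: int = 0
    line_number: int = 0
    conflict: bool = False

    @property
    def edge(self) -> SignedEdge:
        return SignedEdge(self.source, self.target, self.sign)


class Provider(Protocol):
    """Synchronous text-in/text-out completion contract with conversation state."""

    def send(self, prompt: str) -> str: ...

    def reset(self) -> None: ...


class ScriptedProvider:
    """Fixture provider replaying a fixed list of replies in order."""

    def __init__(self, replies: list[str], tag: str = "scripted"):
        self.replies = list(replies)
        self.tag = tag
        self._cursor = 0
        self.history: list[str] = []

    def send(self, prompt: str) -> str:
        self.history.append(prompt)
        if self._cursor >= len(self.replies):
            raise RuntimeError("scripted provider exhausted")
        reply = self.replies[self._cursor]
        self._cursor += 1
        return reply

    def reset(self) -> None:
        self._cursor = 0
        self.history.clear()


class ReplayProvider(ScriptedProvider):
    """Replays the batch responses stored in a transcript file."""

    def __init__(self, transcript_path: str | Path, tag: str = "replay"):
        super().__init__(read_transcript(transcript_path), tag=tag)


def chunk_genes(gene_list: list[str], batch_size: int) -> list[list[str]]:
    """Partition the gene list in order into chunks of at most ``batch_size``."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if not gene_list:
        raise ValueError("gene list is empty")
    return [gene_list[i : i + batch_size] for i in range(0, len(gene_list), batch_size)]


def build_prompt(batch: PromptBatch, full_gene_list: list[str]) -> str:
    """Render the prompt text for one batch.

    The initial step carries the full gene list and the instruction with
    phenotype, batch size, and the maximum permitted out-degree interpolated;
    continuation steps only ask to repeat for the next chunk.
    """
    if batch.step == "continuation":
        return CONTINUATION_TEMPLATE.format(chunk_len=len(batch.gene_chunk))
    listing = "\n".join(full_gene_list)
    instruction = INITIAL_TEMPLATE.format(
        batch_size=batch.batch_size,
        phenotype=batch.phenotype,
        max_connections=batch.max_connections,
    )
    return f"{GENE_LIST_HEADER}\n{listing}\n\n{instruction}"


def query_provider(
    provider,
    batches: list[PromptBatch],
    full_gene_list: list[str],
    replicate_id: int = 1,
    retries: int = 0,
    transcript_path: str | Path | None = None,
) -> list[RawResponse | MissingBatch]:
    """Send every batch prompt in order, preserving conversation continuity.

    A batch whose query keeps failing after ``retries`` attempts is recorded
    as a :class:`MissingBatch` and the run continues. If ``transcript_path``
    is given the replies are persisted verbatim with batch separators.
    """
    tag = getattr(provider, "tag", provider.__class__.__name__)
    out: list[RawResponse | MissingBatch] = []
    for index, batch in enumerate(batches):
        prompt = build_prompt(batch, full_gene_list)
        reply = None
        error = ""
        for _ in range(retries + 1):
            try:
                reply = provider.send(prompt)
                break
            except Exception as exc:  # provider failures are retriable
                error = str(exc)
        if reply is None:
            logger.warning("batch %d failed after %d retries: %s", index, retries, error)
            out.append(MissingBatch(replicate_id, index, tag, error))
        else:
            out.append(RawResponse(reply, replicate_id, index, tag))
    if transcript_path is not None:
        path = Path(transcript_path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w") as fh:
            for item in out:
                fh.write(BATCH_SEPARATOR.format(index=item.batch_index) + "\n")
                if isinstance(item, RawResponse):
                    fh.write(item.text.rstrip("\n") + "\n")
    return out


def read_transcript(path: str | Path) -> list[str]:
    """Split a stored transcript back into per-batch response texts."""
    sep = re.compile(r"^### batch \d+ ###$")
    batches: list[list[str]] = []
    current: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if sep.match(line.strip()):
            current = []
            batches.append(current)
        elif current is not None:
            current.append(line)
    if not batches:  # no separators: whole file is one response
        return [Path(path).read_text()]
    return ["\n".join(b) for b in batches]


class StatementList(list):
    """List of statements that remembers how many lines were skipped."""

    n_skipped: int = 0


def _line_patterns(lexicon: dict[str, int]) -> list[re.Pattern]:
    verbs = "|".join(re.escape(v) for v in sorted(lexicon, key=len, reverse=True))
    token = r"[A-Za-zͰ-Ͽ][\w\-/\.]*"
    bullet = r"(?:\d+[.)]\s*|[-*•]\s+)?"
    return [
        # "A stimulates B" (optionally bulleted / numbered, trailing period ok)
        re.compile(
            rf"^\s*{bullet}({token})\s+({verbs})\s+({token})\s*\.?\s*$", re.IGNORECASE
        ),
        # "A -> B (stimulates)" / "A → B: inhibition"
        re.compile(
            rf"^\s*{bullet}({token})\s*(?:->|→)\s*({token})\s*"
            rf"(?:\(\s*({verbs})\s*\)|:\s*({verbs}))\s*\.?\s*$",
            re.IGNORECASE,
        ),
    ]


def parse_response(
    resp: RawResponse, lexicon: dict[str, int] | None = None
) -> StatementList:
    """Mine one reply line-by-line for directional interaction statements.

    Tolerates list bullets, numbering, and arrow notation. Lines without a
    lexicon verb or without two resolvable tokens (prose, non-directional
    claims like "A interacts with B") are skipped and counted in the returned
    list's ``n_skipped``.
    """
    if not lexicon:
        raise ValueError("lexicon must be nonempty")
    plain, arrow = _line_patterns(lexicon) if lexicon else (None, None)
    lower_lexicon = {k.lower(): v for k, v in lexicon.items()}
    statements = StatementList()
    skipped = 0
    for lineno, line in enumerate(resp.text.splitlines(), start=1):
        if not line.strip():
            continue
        m = plain.match(line) or arrow.match(line)
        if m is None:
            skipped += 1
            continue
        groups = [g for g in m.groups() if g is not None]
        source, rest = groups[0], groups[1:]
        if len(rest) == 2 and rest[0].lower() in lower_lexicon:
            verb, target = rest
        else:
            target, verb = rest[0], rest[1]
        statements.append(
            InteractionStatement(
                source=source,
                target=target,
                verb=verb.lower(),
                sign=lower_lexicon[verb.lower()],
                raw_line=line,
                replicate_id=resp.replicate_id,
                batch_index=resp.batch_index,
                line_number=lineno,
            )
        )
    statements.n_skipped = skipped
    if skipped:
        logger.info(
            "replicate %d batch %d: skipped %d non-statement line(s)",
            resp.replicate_id, resp.batch_index, skipped,
        )
    return statements


def filter_statements(
    stmts: Iterable[InteractionStatement],
    gene_list: Iterable[str],
    alias_map: dict[str, str] | None = None,
) -> list[InteractionStatement]:
    """Keep statements whose endpoints both resolve to the gene list.

    Endpoints are alias-resolved then normalized; statements mentioning
    non-relevant symbols are discarded. Identical (source, target, sign)
    duplicates collapse to the first occurrence; a pair claimed with both
    signs keeps both statements, flagged as conflicting.
    """
    aliases = {normalize_id(k): normalize_id(v) for k, v in (alias_map or {}).items()}
    universe = {normalize_id(g) for g in gene_list}

    def resolve(sym: str) -> str:
        norm = normalize_id(sym)
        return aliases.get(norm, norm)

    kept: dict[tuple[str, str, int], InteractionStatement] = {}
    for stmt in stmts:
        source, target = resolve(stmt.source), resolve(stmt.target)
        if source not in universe or target not in universe:
            continue
        key = (source, target, stmt.sign)
        if key not in kept:
            kept[key] = replace(stmt, source=source, target=target)
    result = list(kept.values())
    pairs_both_signs = {
        (s, t) for (s, t, _) in kept if (s, t, +1) in kept and (s, t, -1) in kept
    }
    for stmt in result:
        if (stmt.source, stmt.target) in pairs_both_signs:
            stmt.conflict = True
    return result


def statements_to_network(
    stmts: Iterable[InteractionStatement],
    node_universe: Iterable[str],
    phenotype: str = "",
    name: str = "",
    basal_weight: float = 0.0,
    include_universe: bool = False,
) -> Network:
    """Translate filtered statements into a simulatable network.

    Each unique statement becomes a single-regulator reaction (``A => B`` or
    ``!A => B``); nodes with no incoming reaction get an input reaction whose
    weight is the basal stimulus, so the ODE system is well-posed. Conflicting
    signs yield two reactions OR-combined downstream.
    """
    universe = {normalize_id(g) for g in node_universe}
    edges = []
    for stmt in stmts:
        source, target = normalize_id(stmt.source), normalize_id(stmt.target)
        if source not in universe or target not in universe:
            raise ValueError(f"statement endpoint outside node universe: {stmt}")
        edges.append(SignedEdge(source, target, stmt.sign))
    return network_from_edges(
        edges,
        name=name,
        phenotype=phenotype,
        node_universe=sorted(universe) if include_universe else None,
        basal_weight=basal_weight,
    )
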