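"""Prompt construction, transcript replay, and statement extraction."""

import pytest

from signetbench.extraction import (
    BATCH_SEPARATOR,
    DEFAULT_LEXICON,
    InteractionStatement,
    MissingBatch,
    PromptBatch,
    RawResponse,
    ReplayProvider,
    ScriptedProvider,
    build_prompt,
    chunk_genes,
    filter_statements,
    parse_response,
    query_provider,
    read_transcript,
    statements_to_network,
)
from signetbench.network import SignedEdge, to_signed_edges


@pytest.mark.parametrize(
    "n_genes, batch_size, sizes",
    [(106, 20, [20, 20, 20, 20, 20, 6]), (20, 20, [20]), (5, 20, [5]), (41, 10, [10, 10, 10, 10, 1])],
)
def test_chunk_genes_partitions_in_order(n_genes, batch_size, sizes):
    genes = [f"G{i}" for i in range(n_genes)]
    chunks = chunk_genes(genes, batch_size)
    assert [len(c) for c in chunks] == sizes
    assert [g for c in chunks for g in c] == genes


def test_chunk_genes_rejects_bad_args():
    with pytest.raises(ValueError):
        chunk_genes(["A"], 0)
    with pytest.raises(ValueError):
        chunk_genes([], 20)


def test_initial_prompt_interpolation():
    genes = [f"G{i}" for i in range(25)]
    batch = PromptBatch("cardiac hypertrophy", genes[:20], batch_size=20,
                        max_connections=11)
    text = build_prompt(batch, genes)
    assert text.startswith("List of genes and other signaling nodes:")
    assert all(g in text for g in genes)
    assert "fewer than 11 direct interactions" in text
    assert "first 20 entries" in text
    assert "cardiac hypertrophy network" in text
    assert "stimulated / inhibited" in text


@pytest.mark.parametrize("phenotype", ["cardiac hypertrophy", "fibroblast", "mechanosignaling"])
def test_prompt_names_phenotype(phenotype):
    batch = PromptBatch(phenotype, ["A"], max_connections=5)
    assert f"a {phenotype} network" in build_prompt(batch, ["A"])


def test_continuation_prompt():
    batch = PromptBatch("fibroblast", [f"G{i}" for i in range(6)],
                        max_connections=5, step="continuation")
    text = build_prompt(batch, [])
    assert "the next 6 nodes" in text and text.startswith("That looks great!")


def test_prompt_batch_invariants():
    with pytest.raises(ValueError):
        PromptBatch("x", [], max_connections=3)
    with pytest.raises(ValueError):
        PromptBatch("x", ["A"] * 21, batch_size=20, max_connections=3)
    with pytest.raises(ValueError):
        PromptBatch("x", ["A"], max_connections=0)


def _batches(n):
    return [
        PromptBatch("toy", [f"G{i}"], batch_size=1, max_connections=2,
                    step="initial" if i == 0 else "continuation")
        for i in range(n)
    ]


def test_query_provider_orders_batches_and_persists(tmp_path):
    provider = ScriptedProvider(["r0", "r1", "r2"], tag="fix")
    path = tmp_path / "fix_toy_rep1.txt"
    out = query_provider(provider, _batches(3), ["G0"], replicate_id=1,
                         transcript_path=path)
    assert [r.batch_index for r in out] == [0, 1, 2]
    assert [r.text for r in out] == ["r0", "r1", "r2"]
    assert read_transcript(path) == ["r0", "r1", "r2"]
    # replay provider reproduces stored responses byte-identically
    replay = ReplayProvider(path)
    assert [replay.send("") for _ in range(3)] == ["r0", "r1", "r2"]


def test_query_provider_degrades_on_failure():
    class Failing:
        tag = "broken"

        def send(self, prompt):
            raise RuntimeError("boom")

        def reset(self):
            pass

    out = query_provider(Failing(), _batches(2), ["G0"], retries=0)
    assert all(isinstance(r, MissingBatch) for r in out)
    assert out[0].error == "boom"


RESPONSE = """Here are the interactions:
1. ADRB2 stimulates RAC1
2. RAC1 stimulates MAP3K1
- PKA inhibits RAF1
MAP3K1 → JNK (activates)
AKT1 -> GSK3B: inhibition
TP53 interacts with MDM2
This line is just prose about signaling.
"""


def test_parse_response_extracts_directional_statements():
    stmts = parse_response(RawResponse(RESPONSE, 2, 1), DEFAULT_LEXICON)
    edges = [(s.source, s.target, s.sign) for s in stmts]
    assert edges == [
        ("ADRB2", "RAC1", 1),
        ("RAC1", "MAP3K1", 1),
        ("PKA", "RAF1", -1),
        ("MAP3K1", "JNK", 1),
        ("AKT1", "GSK3B", -1),
    ]
    # non-directional and prose lines are skipped and counted
    assert stmts.n_skipped == 3
    assert stmts[0].replicate_id == 2 and stmts[0].batch_index == 1
    assert stmts[0].raw_line.endswith("ADRB2 stimulates RAC1")


def test_parse_response_is_deterministic():
    resp = RawResponse(RESPONSE)
    assert parse_response(resp, DEFAULT_LEXICON) == parse_response(resp, DEFAULT_LEXICON)


def test_parse_response_requires_lexicon():
    with pytest.raises(ValueError):
        parse_response(RawResponse("x"), {})


def _stmt(source, target, sign):
    return InteractionStatement(source, target, "stimulates" if sign > 0 else "inhibits", sign)


def test_filter_discards_out_of_list_and_deduplicates():
    stmts = [
        _stmt("ADRB2", "TP53", 1),   # TP53 not in list
        _stmt("a", "b", 1),
        _stmt("A", "B", 1),          # duplicate after normalization
        _stmt("B", "C", -1),
    ]
    kept = filter_statements(stmts, ["A", "B", "C", "ADRB2"])
    assert [(s.source, s.target, s.sign) for s in kept] == [("A", "B", 1), ("B", "C", -1)]
    assert not any(s.conflict for s in kept)


def test_filter_resolves_aliases():
    kept = filter_statements([_stmt("PKB", "GSK3B", -1)], ["AKT", "GSK3B"],
                             alias_map={"PKB": "AKT"})
    assert [(s.source, s.target) for s in kept] == [("AKT", "GSK3B")]


def test_filter_keeps_and_flags_all_conflicts_on_toy_set():
    # every ordered pair of a 3-node set claimed with both signs
    nodes = ["A", "B", "C"]
    stmts = [
        _stmt(a, b, s) for a in nodes for b in nodes if a != b for s in (+1, -1)
    ]
    kept = filter_statements(stmts, nodes)
    assert len(kept) == 12  # both signs retained for all 6 ordered pairs
    assert all(s.conflict for s in kept)


def test_statements_to_network_maps_and_adds_inputs():
    stmts = [_stmt("A", "B", 1), _stmt("C", "B", -1)]
    net = statements_to_network(stmts, ["A", "B", "C"])
    rules = {r.rule for r in net.reactions}
    assert rules == {"=> A", "=> C", "A => B", "!C => B"}


def test_statements_to_network_empty_list_inputs_only():
    net = statements_to_network([], ["A", "B"], include_universe=True)
    assert {r.rule for r in net.reactions} == {"=> A", "=> B"}
    assert net.node_ids == ["A", "B"]


def test_conflict_pair_becomes_two_reactions():
    stmts = filter_statements([_stmt("A", "B", 1), _stmt("A", "B", -1)], ["A", "B"])
    net = statements_to_network(stmts, ["A", "B"])
    assert {r.rule for r in net.reactions} == {"=> A", "A => B", "!A => B"}
    # one non-input reaction per unique statement
    assert sum(not r.is_input for r in net.reactions) == len(stmts)


def test_conflict_pair_steady_state_matches_hand_built_model():
    """OR of f(x) and 1-f(x) drives the target on regardless of the source."""
    import numpy as np

    from signetbench.network import Network, Node, Reaction
    from signetbench.sim import SimulationConfig, compile_model, integrate

    stmts = filter_statements([_stmt("A", "B", 1), _stmt("A", "B", -1)], ["A", "B"])
    net = statements_to_network(stmts, ["A", "B"])
    hand = Network(
        nodes=[Node("A"), Node("B")],
        reactions=[Reaction("=> A", weight=0.0), Reaction("A => B"), Reaction("!A => B")],
    )
    for weight in (0.0, 0.5, 1.0):
        config = SimulationConfig(inputs={"A": weight})
        ours = integrate(compile_model(net), config).state
        ref = integrate(compile_model(hand), config).state
        assert np.allclose(ours.as_series()[ref.node_ids], ref.activities, atol=1e-6)
        # OR(f, 1-f) >= 3/4 keeps the target driven whatever the source does
        assert ref["B"] >= 0.75 - 1e-6
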