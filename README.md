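# signetbench

Benchmarking text-derived, logic-based models of cell signaling networks.

Large language models can be queried for directed molecular interactions
("ADRB2 stimulates RAC1") over a curated gene list, and the mined statements
assembled into a network model. How good are such models? `signetbench`
implements the full loop needed to answer that question quantitatively:

1. **Prompting** — batch a gene list (20 symbols at a time), interpolate a
   phenotype-specific instruction, and iterate until the list is exhausted;
   replies are persisted as plain-text transcripts and can be replayed.
2. **Extraction** — regular-expression mining of directional interaction
   statements (several phrasing dialects), with filtering to the gene list
   and alias resolution; non-directional and off-list claims are discarded
   and counted.
3. **Structure benchmarking** — decompose both networks into signed directed
   edges and score recall/precision against a curated ground truth, with
   one-sample t-tests over replicate runs.
4. **Simulation** — automatic translation into a logic-based differential
   equation (LDE) model and stiff-capable integration to steady state.
5. **Perturbation validation** — score the model's qualitative responses
   (increase / decrease / no change) against an experiment table.
6. **Synthetic study inputs** — seeded generators for ground-truth networks,
   corrupted predictions with exactly planted recall, fake transcripts, and
   self-consistent experiment tables, so the whole pipeline runs offline
   with no API keys.

## The model

Each node *i* has a normalized activity *yᵢ ∈ [0, ymaxᵢ]* relaxing toward a
logic-gated drive:

```
dyᵢ/dt = (Fᵢ(y) · ymaxᵢ − yᵢ) / τᵢ
```

A reaction `A & !B => C` contributes flux `w · f(y_A) · (1 − f(y_B))`, where
*f* is the normalized Hill function constrained through (0,0), (EC50, 0.5)
and (1,1):

```
f(x) = B·xⁿ / (Kⁿ + xⁿ),   B = (EC50ⁿ − 1)/(2·EC50ⁿ − 1),   Kⁿ = B − 1
```

Multiple reactions on one target combine with a probabilistic OR,
`f₁ + f₂ − f₁f₂`. Default parameters (w = 1, n = 1.4, EC50 = 0.5, τ = 1)
replace measured rate constants, so any syntactically valid reaction list
becomes a predictive model. Input reactions `=> X` carry external stimuli;
knockouts clamp `ymax := 0`.

## Worked example

```python
from signetbench import *
from signetbench.synthetic import (SyntheticSpec, generate_network,
    corrupt_network, render_llm_transcript, NoiseSpec, generate_experiments)
from signetbench.extraction import RawResponse

spec = SyntheticSpec(n_nodes=40, n_inputs=4, n_outputs=6, n_reactions=70, seed=11)
gt = generate_network(spec, name="demo", phenotype="cardiac hypertrophy")
gt_edges = to_signed_edges(gt)

corr = corrupt_network(gt, recall_target=0.5, n_spurious=8, seed=1)
text = render_llm_transcript(sorted(corr.edges), "plain", NoiseSpec(2, 2, 2), seed=1)

stmts = parse_response(RawResponse(text), DEFAULT_LEXICON)
kept = filter_statements(stmts, gt.node_ids)
result = edge_recall({s.edge for s in kept}, gt_edges)
print(f"recall {result.recall_pct:.2f}%  precision {result.precision_pct:.2f}%  "
      f"({result.n_matched}/{result.n_gt_edges} edges)")

net = statements_to_network(kept, gt.node_ids)
experiments = generate_experiments(gt, 30, seed=2)
gt_report = score_validation(compile_model(gt), experiments)
llm_report = score_validation(compile_model(net), experiments)
print(f"validation accuracy: ground truth {gt_report.accuracy_pct:.2f}%, "
      f"reconstructed {llm_report.accuracy_pct:.2f}%")
```

prints

```
recall 50.00%  precision 80.49%  (33/66 edges)
validation accuracy: ground truth 100.00%, reconstructed 53.33%
```

The corruption planted exactly half of the 66 ground-truth edges, and the
transcript round-trip recovered all of them (the 8 spurious edges lower
precision, not recall). The intact ground-truth model reproduces every
expected perturbation response in its own experiment table by construction;
the half-reconstructed model responds correctly to only 53% — degraded
structure hurts functional predictions more than edge counts suggest,
because validation probes multi-step paths from stimulus to output.

A CLI mirrors the pipeline stages (`signetbench synth | extract | build |
compare | simulate | validate | benchmark | all`), each taking a YAML
config plus `--seed`/`--out` overrides.

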