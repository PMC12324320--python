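# Methods

## Network representation

A network is an ordered list of nodes and reaction rules. Rules follow the
Netflux convention: `A & !B => C` is an AND-gate (C activated by A and not
B), `=> C` is an input reaction carrying an external stimulus whose level is
the reaction weight. For benchmarking, every reaction is decomposed into
signed directed edges, one per regulator (AND-gates therefore contribute one
edge per constituent; input reactions contribute none). This edge-level
currency is the natural one when the predicted side comes from pairwise
text statements; a stricter reaction-level metric (`reaction_recall`, all
constituent edges required) is available for AND-gated ground truths. Node
identity is compared after normalization — whitespace stripped, Greek
letters transliterated (β→B, κ→K, ...), uppercased — because text-mined
symbols and curated node tables differ in case and typography. Self-loops
are representable; a strict validation flag rejects them.

## Logic-based differential equations

Every node carries a normalized activity y ∈ [0, ymax] with

    dy_i/dt = (F_i(y) · ymax_i − y_i) / τ_i.

Within a reaction, activators enter through the normalized Hill activation
f(x) = B xⁿ/(Kⁿ + xⁿ) with B = (EC50ⁿ − 1)/(2 EC50ⁿ − 1) and Kⁿ = B − 1 —
the unique two-parameter form passing through (0,0), (EC50, 0.5), (1,1) —
and inhibitors through the complement 1 − f(x). Reactions converging on a
node combine with the probabilistic OR, 1 − Π(1 − flux), which is
commutative and associative, so crosstalk is order-independent. The
combination 2·EC50ⁿ = 1 makes the constants singular and is rejected.

Parameter defaults: w = 1, n = 1.4, EC50 = 0.5, τ = 1, ymax = 1, y0 = 0,
basal input weight 0. These are the conventional defaults for logic-based
ODE models built without measured rate constants; the formalism's purpose
is exactly that no fitting is required, so the package exposes but never
tunes them.

### Numerics

- Integration uses `scipy.integrate.solve_ivp` with LSODA (stiff-capable,
  adaptive). Steady state is declared when max|dy/dt| ≤ `ss_tol`
  (default 1e-6), implemented as a terminal event so the criterion is
  step-size independent; the fallback horizon is t_end = 40·max(τ).
- State is clamped to [0, ymax] inside the right-hand side to guard against
  solver overshoot; regulators with ymax = 0 (knockouts) are read as fully
  inactive rather than 0/0.
- An independent steady-state oracle solves y = F(y)·ymax by damped
  fixed-point iteration (damping 0.5, residual tolerance 0.1·`ss_tol`).
  On acyclic models both paths agree to better than 1e-5 per node; on
  feedback systems the oracle may flag non-convergence (oscillatory or
  multistable dynamics), in which case trajectories must be inspected.
- Stimuli override the weight of a node's input reaction; if a stimulated
  node has none, an input reaction is added and OR-combined with its
  existing regulation. Knockout clamps ymax := 0; over-expression sets
  y0 := ymax with input weight 1. Condition nodes absent from a model are
  skipped — a model lacking the species cannot respond, which is precisely
  the failure mode validation should expose.

## Extraction

The querying protocol batches the gene list (default 20 symbols), asks for
directed interactions in the context of a named phenotype with an upper
bound on per-node connections (set to the parent network's maximum
out-degree), and iterates with a fixed continuation prompt. Replies are
persisted verbatim, one transcript file per replicate with batch
separators; a replay provider makes every downstream result reproducible
from the stored files.

Statement mining is line-oriented: two anchored regular expressions accept
`SOURCE VERB TARGET` phrasing (optionally bulleted or numbered) and arrow
notation (`A → B (stimulates)`, `A -> B: inhibition`). The verb lexicon is
configurable; defaults cover common activation verbs (stimulates,
activates, up-regulates, generates, induces, promotes) and inhibition verbs
(inhibits, down-regulates, suppresses, represses, blocks). Lines without a
lexicon verb joining two tokens — prose, non-directional claims like
"A interacts with B" — are skipped and counted. Filtering keeps statements
whose alias-resolved, normalized endpoints are both in the gene list,
deduplicates identical claims, and retains contradictory sign pairs with a
conflict flag (OR semantics downstream preserve the information; majority
voting would discard it). Literature-identifier extraction is deliberately
not implemented. Each kept statement becomes one single-regulator reaction;
nodes left without regulation receive a basal input reaction so the ODE
system is well-posed.

## Benchmarking and statistics

Recall = |pred ∩ gt| / |gt| and precision = |pred ∩ gt| / |pred| over
signed-edge sets (sign-sensitive matching; empty prediction has precision
0; empty ground truth is an error). Replicate scores are summarized by
mean, sample SD (n−1), and a two-sided one-sample t-test against a
reference (100% recall for structure; the curated model's accuracy for
validation). Zero-variance replicate sets are flagged degenerate rather
than assigned a t value. No multiple-testing correction is applied, since
each network/provider pair yields a single test. Regional coverage applies
the same recall to user-annotated edge subsets (e.g. ligand-receptor vs
transcriptional regulation).

## Perturbation validation

An experiment is (condition inputs, optional knockout/over-expression,
output node, expected direction). Control and condition are both simulated
to steady state and the output's change Δ is classified with a dead-band:
increase if Δ > ε, decrease if Δ < −ε, else no change, with ε = 0.001
normalized-activity units by default (strict inequalities at the
boundary). Accuracy is the percentage of scorable experiments matched.
A model lacking the output node predicts no change and is scored against
the expectation by default ("count"); an "exclude" mode drops such rows
from the denominator instead. Non-converged simulations are unscorable and
excluded with a logged count. Within one table, steady states are cached
per unique condition, since many experiments share a stimulus.

## Synthetic study conditions

The generator emulates the shape of curated signaling models: a layered
directed graph (stimulus inputs → intermediate cascade → output genes) in
which every non-input node has at least one upstream regulator, ~25% of
edges inhibitory, single-regulator reactions by default (what pairwise
statements can express; AND-gates via `and_frac` to exercise
decomposition), optional feedback edges. Reaction counts include input
reactions, matching how curated model sizes are reported; stand-ins for
the curated benchmarks are generated at 91 nodes/134 reactions and
94 nodes/125 reactions. All generators are seed-deterministic.

Corruption keeps exactly round(recall_target · m) of the m ground-truth
edges, optionally sign-flips a fraction of them, and adds spurious edges
only between node pairs with no ground-truth interaction — so measured
recall equals the planted value exactly, which is what makes the
benchmark's arithmetic testable. Transcript rendering emits one statement
line per edge in one of three phrasing dialects, with noise lines
constructed never to place a lexicon verb between two in-list symbols.
Experiment tables are built by simulating the ground truth itself under
sampled single-stimulus conditions and recording the classified outcomes,
with at least half the rows guaranteed informative (non-no_change) where
the network provides them; the generating model therefore scores 100% on
its own table when generation and scoring use the same ε.

What the synthetic conditions do not emulate: the error structure of real
language-model output (pathway-conservation bias, paraphrase variety,
hallucinated but plausible symbols), real gene-alias ambiguity, and
multi-stimulus experimental designs. Passing tests therefore demonstrate
the correctness of the pipeline's accounting and simulation, not any claim
about how well a particular language model reconstructs biology.

## Orchestration

Replicate seeds are derived as base seed + replicate id. The end-to-end
study in `scripts/acceptance.py` uses a 106-node / 200-reaction
hypertrophy-scale ground truth, 10 replicates at planted recall 0.4 with
5% sign flips and 20 spurious edges, and a 114-row experiment table —
sizes chosen to mirror a realistic curated-model study while remaining
desk-scale. Every run writes a manifest (config snapshot, hash, outputs)
and reports are bit-reproducible from stored transcripts.

## Known limitations

- The steady-state event can in principle fire during a slow transient
  plateau; the convergence flag re-checks the derivative at the final
  state, but multistable systems report only the branch reached from y0.
- Conflicting-sign statement pairs OR-combine into a target that is driven
  whenever either claim fires; this is information-preserving but means a
  fully contradicted edge behaves like constitutive activation.
- The edge-level recall metric scores partial credit for AND-gated curated
  reactions; the reaction-level alternative is stricter. Which convention a
  published benchmark used affects comparability of absolute percentages.
- Input reactions are excluded from the recall denominator (pairwise
  statements cannot express them), which slightly inflates recall relative
  to a count over all reactions.
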