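"""Benchmarking predicted network structure against a curated ground truth.

The unit of comparison is the signed directed edge (after AND-gates are
decomposed into their constituent regulator edges); a match requires the
same source, target, and sign. Recall is the fraction of ground-truth edges
recovered, precision the fraction of predicted edges that are correct.
Replicate runs are summarized with a one-sample t-test against a reference
value (the ground-truth network scores 100% against itself by definition).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import Network, SignedEdge, to_signed_edges

__all__ = [
    "RecallResult",
    "ReplicateSummary",
    "edge_recall",
    "reaction_recall",
    "summarize_replicates",
    "regional_coverage",
]


@dataclass
class RecallResult:
    """Edge-level benchmark scores for one predicted network."""

    replicate_id: int
    n_gt_edges: int
    n_pred_edges: int
    n_matched: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_gt_edges

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_pred_edges if self.n_pred_edges else 0.0

    @property
    def recall_pct(self) -> float:
        return 100.0 * self.recall

    @property
    def precision_pct(self) -> float:
        return 100.0 * self.precision


@dataclass
class ReplicateSummary:
    """Mean/sd over replicates and a one-sample t-test vs a reference value."""

    mean: float
    sd: float
    n: int
    reference: float
    t_stat: float
    df: int
    p_value: float
    degenerate: bool = False  # sd == 0: t undefined


def edge_recall(
    pred: set[SignedEdge], gt: set[SignedEdge], replicate_id: int = 0
) -> RecallResult:
    """Score a predicted edge set against the ground truth edge set."""
    gt = set(gt)
    pred = set(pred)
    if not gt:
        raise ValueError("ground truth edge set is empty; recall undefined")
    matched = len(pred & gt)
    return RecallResult(replicate_id, len(gt), len(pred), matched)


def reaction_recall(pred: set[SignedEdge], gt: Network) -> float:
    """Stricter reaction-level metric: a ground-truth reaction counts as
    recalled only if *all* of its constituent regulator edges are predicted.

    Input reactions (no regulators) are excluded from the denominator.
    """
    pred = set(pred)
    counted = recalled = 0
    for rxn in gt.reactions:
        regulators = rxn.regulators
        if not regulators:
            continue
        counted += 1
        target = rxn.target
        if all(SignedEdge(reg, target, sign) in pred for reg, sign in regulators):
            recalled += 1
    if counted == 0:
        raise ValueError("ground truth has no non-input reactions")
    return recalled / counted


def summarize_replicates(scores: list[float], reference: float) -> ReplicateSummary:
    """One-sample two-sided t-test of replicate scores against ``reference``.

    Uses the sample standard deviation (n-1 denominator); with zero variance
    the t statistic is undefined and the summary is flagged degenerate.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 replicate scores")
    x = np.asarray(scores, dtype=float)
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        return ReplicateSummary(mean, sd, n, reference, math.nan, df, math.nan,
                                degenerate=True)
    t = (mean - reference) / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return ReplicateSummary(mean, sd, n, reference, t, df, p)


def regional_coverage(
    pred: set[SignedEdge], gt_regions: dict[str, set[SignedEdge]]
) -> dict[str, float]:
    """Per-region recall for user-annotated subsets of the ground truth.

    Regions with zero edges are omitted with a warning. Useful for asking
    which parts of a network (ligand-receptor, transcriptional, ...) a
    predicted network recovers.
    """
    out: dict[str, float] = {}
    for label, edges in gt_regions.items():
        if not edges:
            warnings.warn(f"region {label!r} has no edges; omitted", stacklevel=2)
            continue
        out[label] = edge_recall(pred, edges).recall
    return out
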