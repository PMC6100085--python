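"""Structure-recovery metrics against a ground-truth network.

Recall is the fraction of true edges recovered, precision the fraction
of inferred edges that are true, and F1 their harmonic mean.  Two
comparison modes: ``directed`` compares ordered pairs (an inferred
undirected edge earns no credit), ``skeleton`` compares unordered
adjacency only, so direction mistakes cannot hurt.  Degenerate 0/0
ratios are reported as 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .network_model import Network, PDAG

__all__ = ["MetricReport", "score_structure", "aggregate_reports"]


@dataclass(frozen=True)
class MetricReport:
    recall: float
    precision: float
    f1: float
    n_inferred: int
    n_actual: int
    n_correct: int
    mode: str


def _f1(recall: float, precision: float) -> float:
    denom = recall + precision
    return 2.0 * recall * precision / denom if denom > 0 else 0.0


def score_structure(inferred: PDAG, truth: Network, mode: str = "directed") -> MetricReport:
    """Compare an inferred partially directed graph with the true DAG."""
    if mode not in ("directed", "skeleton"):
        raise ValueError("mode must be 'directed' or 'skeleton'")
    if set(inferred.nodes) != set(truth.nodes):
        raise ValueError("node sets differ")
    if mode == "directed":
        inferred_edges: set = set(inferred.directed_edges)
        actual: set = set(truth.edges())
    else:
        inferred_edges = set(inferred.skeleton_pairs())
        actual = {frozenset(e) for e in truth.edges()}
    correct = inferred_edges & actual
    if not inferred_edges or not actual:
        warnings.warn(
            f"empty {'inferred' if not inferred_edges else 'actual'} edge set; "
            "metrics reported as 0",
            stacklevel=2,
        )
    recall = len(correct) / len(actual) if actual else 0.0
    precision = len(correct) / len(inferred_edges) if inferred_edges else 0.0
    return MetricReport(
        recall=recall,
        precision=precision,
        f1=_f1(recall, precision),
        n_inferred=len(inferred_edges),
        n_actual=len(actual),
        n_correct=len(correct),
        mode=mode,
    )


def aggregate_reports(reports: list[MetricReport]) -> dict[str, float]:
    """Best / mean / worst F1 over a list of per-seed reports."""
    if not reports:
        raise ValueError("no reports")
    f1s = [r.f1 for r in reports]
    return {
        "best": max(f1s),
        "mean": sum(f1s) / len(f1s),
        "worst": min(f1s),
    }
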