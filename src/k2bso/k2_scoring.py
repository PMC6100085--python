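"""The K2 Bayesian score and the greedy per-node parent search.

The score of node ``X_i`` with parent set ``pi_i`` is the Cooper-
Herskovits marginal likelihood of the counts under a uniform Dirichlet
prior,

    g(X_i, pi_i) = prod_j (r_i - 1)! / (N_ij + r_i - 1)! * prod_k N_ijk!

where ``j`` runs over parent configurations, ``k`` over the ``r_i``
child states, ``N_ijk`` is the count of (child state k, configuration
j) and ``N_ij = sum_k N_ijk``.  Everything here works in natural-log
space via ``gammaln`` — the literal factorials overflow beyond counts
of ~170 — so the local score is

    sum_j [ lnGamma(r_i) - lnGamma(N_ij + r_i) + sum_k lnGamma(N_ijk + 1) ].

Configurations never observed (N_ij = 0) contribute exactly 0, so only
observed configurations are materialized; a node with many parents
never allocates its full q_i-row table.  The structure score is the sum
of local scores over nodes, and the structure prior constant is
dropped: it shifts all totals equally and cannot change an argmax.

Given a topological order, K2 builds each node's parent set greedily
from its predecessors, adding the single best score-increasing
candidate until nothing improves or the parent cap ``max_parents``
(traditionally written mu) is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .network_model import Network
from .synthetic_data import DiscreteDataset

__all__ = [
    "Order",
    "ScoreCache",
    "local_log_score",
    "k2_parent_search",
    "score_order",
    "fit_cpts",
]

_GAIN_TOL = 1e-12  # additions need a strictly positive gain


@dataclass(frozen=True)
class Order:
    """A permutation of the variable names — the search state."""

    sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sequence)) != len(self.sequence):
            raise ValueError("order contains repeated names")

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self):
        return iter(self.sequence)

    def position(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.sequence)}

    @classmethod
    def random(cls, names: Sequence[str], rng: np.random.Generator) -> "Order":
        idx = rng.permutation(len(names))
        return cls(tuple(names[i] for i in idx))


@dataclass
class ScoreCache:
    """Memo of local scores keyed on (node, frozen parent set).

    Shared across every order evaluated in a run: different orders
    constantly revisit the same (node, parents) queries, and the count
    table depends on nothing else.
    """

    table: dict[tuple[str, frozenset[str]], float] = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    def get(self, data: DiscreteDataset, node: str, parents: Iterable[str]) -> float:
        key = (node, frozenset(parents))
        try:
            value = self.table[key]
            self.hits += 1
            return value
        except KeyError:
            self.misses += 1
            value = local_log_score(data, node, key[1])
            self.table[key] = value
            return value


def local_log_score(data: DiscreteDataset, node: str, parents: Iterable[str]) -> float:
    """Natural log of the K2 local score g(node, parents).

    Deterministic function of the count table alone; parent
    configurations with no observations contribute 0.
    """
    parents = sorted(parents)
    if node in parents:
        raise ValueError(f"{node!r} cannot be its own parent")
    child = data.column(node)  # raises on unknown name
    r = data.cardinality(node)
    if parents:
        cards = [data.cardinality(p) for p in parents]
        codes = np.ravel_multi_index([data.column(p) for p in parents], cards)
        # compact to observed configurations only
        _, codes = np.unique(codes, return_inverse=True)
        q_obs = int(codes.max()) + 1
    else:
        codes = np.zeros(data.n_samples, dtype=np.int64)
        q_obs = 1
    joint = np.bincount(codes * r + child, minlength=q_obs * r).reshape(q_obs, r)
    n_j = joint.sum(axis=1)
    score = float(
        np.sum(gammaln(r) - gammaln(n_j + r)) + np.sum(gammaln(joint + 1.0))
    )
    return score


def k2_parent_search(
    data: DiscreteDataset,
    order: Order,
    max_parents: int = 4,
    cache: ScoreCache | None = None,
) -> tuple[Network, float]:
    """Greedy K2 structure search under a fixed topological order.

    Candidate parents of a node are only its predecessors in ``order``.
    One candidate is added per step — the one with the largest strictly
    positive score gain, ties broken by earliest order position — until
    no addition helps or ``max_parents`` is reached.

    Returns a structure-only :class:`Network` (no CPTs; use
    :func:`fit_cpts` to attach maximum-likelihood tables) and the total
    log score, the sum of the final local scores.
    """
    if set(order.sequence) != set(data.columns):
        raise ValueError("order must cover exactly the data columns")
    if max_parents < 0:
        raise ValueError("max_parents must be >= 0")
    if cache is None:
        cache = ScoreCache()
    parent_sets: dict[str, list[str]] = {}
    total = 0.0
    for i, node in enumerate(order.sequence):
        predecessors = list(order.sequence[:i])
        parents: list[str] = []
        current = cache.get(data, node, parents)
        while len(parents) < max_parents:
            best_gain = _GAIN_TOL
            best_candidate: str | None = None
            for cand in predecessors:  # order position breaks ties
                if cand in parents:
                    continue
                gain = cache.get(data, node, parents + [cand]) - current
                if gain > best_gain:
                    best_gain = gain
                    best_candidate = cand
            if best_candidate is None:
                break
            parents.append(best_candidate)
            current += best_gain
        parent_sets[node] = parents
        total += current
    nodes = list(data.columns)
    net = Network(nodes, list(data.cardinalities), {n: parent_sets[n] for n in nodes})
    return net, total


def score_order(
    data: DiscreteDataset,
    order: Order,
    max_parents: int = 4,
    cache: ScoreCache | None = None,
) -> float:
    """Total K2 log score of the structure the greedy search builds
    under ``order`` — the fitness used by every order searcher."""
    _, total = k2_parent_search(data, order, max_parents, cache)
    return total


def fit_cpts(net: Network, data: DiscreteDataset, smoothing: float = 1.0) -> Network:
    """Attach CPTs estimated by smoothed maximum likelihood.

    Row ``j`` of node i's table is ``(N_ijk + smoothing) / (N_ij +
    r_i * smoothing)``; with the default add-one smoothing every row is
    proper even for unobserved configurations.
    """
    cpts: dict[str, np.ndarray] = {}
    for node in net.nodes:
        parents = net.parent_sets[node]
        r = net.cardinality[node]
        q = net.q(node)
        counts = np.zeros((q, r))
        child = data.column(node)
        if parents:
            cards = [net.cardinality[p] for p in parents]
            codes = np.ravel_multi_index([data.column(p) for p in parents], cards)
        else:
            codes = np.zeros(data.n_samples, dtype=np.int64)
        np.add.at(counts, (codes, child), 1.0)
        counts += smoothing
        cpts[node] = counts / counts.sum(axis=1, keepdims=True)
    return Network(net.nodes, [net.cardinality[v] for v in net.nodes], net.parent_sets, cpts)
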