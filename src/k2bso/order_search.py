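"""Metaheuristic search over topological orders.

Three searchers share the K2 order fitness (:func:`~k2bso.k2_scoring.score_order`):

* :func:`bso_search` — brain-storm optimization.  The population of
  orders is clustered under a bespoke permutation distance (equal to
  the Kendall-tau pair-disagreement count), the best-scoring member of
  each cluster acts as its "center", and new candidate orders are made
  by perturbing or fusing members/centers, with a perturbation
  magnitude that decays over iterations through a logistic schedule.
* :func:`random_search` — pure random restarts with the classic
  "10 consecutive batches without improvement" stopping rule.
* :func:`ga_search` — a genetic algorithm with order crossover (OX),
  insertion mutation, tournament selection and elitism.

All three expose an optional evaluation budget so they can be compared
at matched numbers of fitness evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .k2_scoring import Order, ScoreCache, score_order
from .synthetic_data import DiscreteDataset

__all__ = [
    "Population",
    "BSOConfig",
    "StepSize",
    "order_distance",
    "cluster_orders",
    "step_size",
    "perturb_order",
    "merge_orders",
    "bso_search",
    "random_search",
    "ga_search",
]


# ---------------------------------------------------------------------------
# Order distance and clustering
# ---------------------------------------------------------------------------


def order_distance(r1: Order, r2: Order) -> int:
    """Prefix-overlap distance between two orders.

    For each variable v, count how many variables precede v in *both*
    orders; summing over v gives the overlap — the number of variable
    pairs on whose relative order the two permutations agree.  The
    distance is ``n(n-1)/2 - overlap``: 0 for identical orders,
    ``n(n-1)/2`` for reversed ones.  It equals the Kendall-tau
    pair-disagreement count, hence is a genuine metric.
    """
    if set(r1.sequence) != set(r2.sequence):
        raise ValueError("orders must cover the same name set")
    n = len(r1)
    pos2 = r2.position()
    # map r1's sequence into r2 positions; concordant pairs are the
    # non-inversions of this array
    mapped = np.array([pos2[v] for v in r1.sequence])
    overlap = 0
    for i in range(n):
        overlap += int(np.sum(mapped[i + 1 :] > mapped[i]))
    return n * (n - 1) // 2 - overlap


@dataclass
class Population:
    """A set of orders with scores, cluster labels and per-cluster centers."""

    members: list[Order]
    scores: list[float]
    cluster_of: list[int] = field(default_factory=list)
    centers: list[int] = field(default_factory=list)  # member indices, one per cluster

    def __post_init__(self) -> None:
        if len(self.members) != len(self.scores):
            raise ValueError("members and scores must be parallel")
        if self.cluster_of and len(self.cluster_of) != len(self.members):
            raise ValueError("cluster_of must parallel members")

    @property
    def size(self) -> int:
        return len(self.members)

    def best_index(self) -> int:
        return int(np.argmax(self.scores))

    def cluster_members(self, c: int) -> list[int]:
        return [i for i, ci in enumerate(self.cluster_of) if ci == c]


def _distance_matrix(members: Sequence[Order]) -> np.ndarray:
    n = len(members)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = order_distance(members[i], members[j])
    return d


def cluster_orders(pop: Population, m: int, seed: int = 0) -> Population:
    """Partition the population into ``m`` clusters by k-medoids (PAM
    style) under :func:`order_distance`.

    Permutations have no mean, so medoids replace the k-means
    centroids.  After the partition settles, the best-*scoring* member
    of each cluster is marked as its center (the BSO "optimal
    individual" of the class), which need not be the medoid.
    """
    if m < 1:
        raise ValueError("need at least one cluster")
    if m > pop.size:
        raise ValueError("more clusters than members")
    rng = np.random.default_rng(seed)
    d = _distance_matrix(pop.members)
    n = pop.size
    medoids = list(rng.choice(n, size=m, replace=False))
    labels = np.zeros(n, dtype=int)
    for _ in range(50):
        # assignment step; ties go to the lowest cluster id
        labels = np.argmin(d[:, medoids], axis=1)
        # fix empty clusters: seed with a far point from a non-singleton donor
        for c in range(m):
            if not np.any(labels == c):
                costs = d[np.arange(n), np.array(medoids)[labels]]
                for cand in np.argsort(-costs):
                    if np.sum(labels == labels[cand]) > 1:
                        labels[int(cand)] = c
                        break
        new_medoids = []
        for c in range(m):
            idx = np.flatnonzero(labels == c)
            within = d[np.ix_(idx, idx)].sum(axis=1)
            new_medoids.append(int(idx[np.argmin(within)]))
        if new_medoids == medoids:
            break
        medoids = new_medoids
    centers = []
    for c in range(m):
        idx = np.flatnonzero(labels == c)
        centers.append(int(idx[np.argmax(np.asarray(pop.scores)[idx])]))
    return Population(
        members=list(pop.members),
        scores=list(pop.scores),
        cluster_of=[int(c) for c in labels],
        centers=centers,
    )


# ---------------------------------------------------------------------------
# BSO operators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepSize:
    """Perturbation weight in (0, 1): the logistic schedule times a
    uniform draw."""

    xi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.xi < 1.0:
            raise ValueError("step size must lie in (0, 1)")


@dataclass
class BSOConfig:
    """Knobs of the brain-storm order search.

    The four generation probabilities follow standard BSO practice:
    ``p_replace_center`` chance per iteration of re-seeding one
    cluster's center with a fresh random order; ``p_one_cluster``
    chance a candidate comes from a single cluster (vs a fused pair);
    ``p_use_center`` / ``p_use_center_pair`` chance of using the
    center(s) rather than random member(s).  Cluster choice is always
    weighted by cluster size.
    """

    pop_size: int = 50
    n_clusters: int = 5
    max_iteration: int = 100
    slope_k: float = 20.0
    p_replace_center: float = 0.2
    p_one_cluster: float = 0.8
    p_use_center: float = 0.4
    p_use_center_pair: float = 0.5
    stall_limit: int = 20
    seed: int = 0
    max_evaluations: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_replace_center", "p_one_cluster", "p_use_center", "p_use_center_pair"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_clusters < 1 or self.pop_size < self.n_clusters:
            raise ValueError("need pop_size >= n_clusters >= 1")
        if self.slope_k == 0:
            raise ValueError("slope_k must be nonzero")


def step_size(cfg: BSOConfig, current_iteration: int, rng: np.random.Generator) -> StepSize:
    """xi = logsig((0.5 * max_iteration - current_iteration) / k) * U(0,1).

    Early iterations give xi near a full uniform draw (exploration);
    past the halfway point the logistic factor decays toward zero
    (exploitation).
    """
    if cfg.slope_k == 0:
        raise ValueError("slope_k must be nonzero")
    if not 0 <= current_iteration <= cfg.max_iteration:
        raise ValueError("current_iteration out of range")
    z = (0.5 * cfg.max_iteration - current_iteration) / cfg.slope_k
    logsig = 1.0 / (1.0 + np.exp(-z))
    u = rng.random()
    # keep inside the open interval required by StepSize
    xi = float(np.clip(logsig * u, 1e-12, 1.0 - 1e-12))
    return StepSize(xi)


def perturb_order(base: Order, xi: StepSize, rng: np.random.Generator) -> Order:
    """Apply ``max(1, round(xi * n))`` random insertion moves.

    An insertion move removes one element and reinserts it at a random
    position — the discrete counterpart of adding scaled noise, with
    the number of moves playing the role of the noise magnitude.
    """
    seq = list(base.sequence)
    n = len(seq)
    moves = max(1, int(round(xi.xi * n)))
    for _ in range(moves):
        src = int(rng.integers(n))
        item = seq.pop(src)
        dst = int(rng.integers(n))
        seq.insert(dst, item)
    return Order(tuple(seq))


def merge_orders(r1: Order, r2: Order, rng: np.random.Generator) -> Order:
    """Fuse two orders by rank averaging.

    Each variable's key is the mean of its two positions plus a tiny
    uniform jitter (tie-break); the merged order sorts by key.  Merging
    an order with itself returns it unchanged.
    """
    if set(r1.sequence) != set(r2.sequence):
        raise ValueError("orders must cover the same name set")
    pos1, pos2 = r1.position(), r2.position()
    names = list(r1.sequence)
    keys = np.array([(pos1[v] + pos2[v]) / 2.0 for v in names])
    keys = keys + rng.uniform(0.0, 1e-6, size=len(names))
    return Order(tuple(names[i] for i in np.argsort(keys, kind="stable")))


# ---------------------------------------------------------------------------
# Searchers
# ---------------------------------------------------------------------------


@dataclass
class _Budget:
    """Global fitness-evaluation counter shared by a search run."""

    limit: int | None = None
    used: int = 0

    def exhausted(self) -> bool:
        return self.limit is not None and self.used >= self.limit

    def charge(self) -> None:
        self.used += 1


def _make_scorer(
    data: DiscreteDataset, max_parents: int, cache: ScoreCache, budget: _Budget
) -> Callable[[Order], float]:
    def scorer(order: Order) -> float:
        budget.charge()
        return score_order(data, order, max_parents, cache)

    return scorer


def bso_search(
    data: DiscreteDataset,
    cfg: BSOConfig,
    max_parents: int = 4,
) -> tuple[Order, float, list[dict]]:
    """Brain-storm optimization over topological orders.

    Per iteration: possibly re-seed one cluster center with a fresh
    random order; generate one candidate per member by one of four
    ways — a single cluster's center, a random member of a single
    cluster, the fusion of two clusters' centers, or the fusion of two
    random members — perturbed by insertion moves whose count follows
    the logistic step-size schedule; a candidate replaces its member
    only if strictly better (elitist), and the population is
    re-clustered every iteration.  Stops at ``max_iteration``, when the
    best score has not improved for ``stall_limit`` iterations, or when
    the evaluation budget runs out.

    Returns the best-ever order, its score, and a per-iteration trace
    (iteration, evaluations, best_score, mean_score).
    """
    if data.n_samples < 1 or data.n_variables < 1:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    cache = ScoreCache()
    budget = _Budget(cfg.max_evaluations)
    scorer = _make_scorer(data, max_parents, cache, budget)
    names = list(data.columns)

    members = [Order.random(names, rng) for _ in range(cfg.pop_size)]
    scores = [scorer(o) for o in members]
    m = min(cfg.n_clusters, cfg.pop_size)
    pop = cluster_orders(Population(members, scores), m, seed=int(rng.integers(2**31)))

    best_idx = pop.best_index()
    best_order, best_score = pop.members[best_idx], pop.scores[best_idx]
    trace: list[dict] = []
    stall = 0
    for iteration in range(cfg.max_iteration):
        if budget.exhausted():
            break
        if rng.random() < cfg.p_replace_center:
            c = int(rng.integers(m))
            fresh = Order.random(names, rng)
            center = pop.centers[c]
            pop.members[center] = fresh
            pop.scores[center] = scorer(fresh)
        sizes = np.array([len(pop.cluster_members(c)) for c in range(m)], dtype=float)
        weights = sizes / sizes.sum()
        for i in range(pop.size):
            if budget.exhausted():
                break
            if rng.random() < cfg.p_one_cluster or m == 1:
                c = int(rng.choice(m, p=weights))
                if rng.random() < cfg.p_use_center:
                    base = pop.members[pop.centers[c]]
                else:
                    base = pop.members[rng.choice(pop.cluster_members(c))]
            else:
                c1, c2 = rng.choice(m, size=2, replace=False, p=weights)
                if rng.random() < cfg.p_use_center_pair:
                    o1 = pop.members[pop.centers[c1]]
                    o2 = pop.members[pop.centers[c2]]
                else:
                    o1 = pop.members[rng.choice(pop.cluster_members(int(c1)))]
                    o2 = pop.members[rng.choice(pop.cluster_members(int(c2)))]
                base = merge_orders(o1, o2, rng)
            candidate = perturb_order(base, step_size(cfg, iteration, rng), rng)
            cand_score = scorer(candidate)
            if cand_score > pop.scores[i]:
                pop.members[i] = candidate
                pop.scores[i] = cand_score
        pop = cluster_orders(
            Population(pop.members, pop.scores), m, seed=int(rng.integers(2**31))
        )
        idx = pop.best_index()
        if pop.scores[idx] > best_score:
            best_order, best_score = pop.members[idx], pop.scores[idx]
            stall = 0
        else:
            stall += 1
        trace.append(
            {
                "iteration": iteration,
                "evaluations": budget.used,
                "best_score": best_score,
                "mean_score": float(np.mean(pop.scores)),
            }
        )
        if stall >= cfg.stall_limit:
            break
    return best_order, best_score, trace


def random_search(
    data: DiscreteDataset,
    batch: int = 50,
    max_parents: int = 4,
    seed: int = 0,
    max_evaluations: int | None = None,
) -> tuple[Order, float]:
    """Random-restart baseline.

    Scores batches of fresh random orders and keeps the best; stops
    after 10 consecutive batches fail to improve it (or at the
    evaluation budget).
    """
    if batch < 1:
        raise ValueError("batch must be >= 1")
    rng = np.random.default_rng(seed)
    cache = ScoreCache()
    budget = _Budget(max_evaluations)
    scorer = _make_scorer(data, max_parents, cache, budget)
    names = list(data.columns)
    best_order: Order | None = None
    best_score = -np.inf
    stale = 0
    while stale < 10 and not budget.exhausted():
        improved = False
        for _ in range(batch):
            if budget.exhausted():
                break
            order = Order.random(names, rng)
            s = scorer(order)
            if s > best_score:
                best_order, best_score = order, s
                improved = True
        stale = 0 if improved else stale + 1
    assert best_order is not None
    return best_order, best_score


def _order_crossover(p1: Order, p2: Order, rng: np.random.Generator) -> Order:
    """OX: copy a random slice of p1, fill the rest in p2's order."""
    n = len(p1)
    a, b = sorted(rng.choice(n, size=2, replace=False))
    slice_names = set(p1.sequence[a : b + 1])
    fill = [v for v in p2.sequence if v not in slice_names]
    child: list[str] = []
    it = iter(fill)
    for i in range(n):
        if a <= i <= b:
            child.append(p1.sequence[i])
        else:
            child.append(next(it))
    return Order(tuple(child))


def ga_search(
    data: DiscreteDataset,
    pop_size: int = 50,
    generations: int = 100,
    max_parents: int = 4,
    seed: int = 0,
    max_evaluations: int | None = None,
    crossover_prob: float = 0.9,
    mutation_prob: float = 1.0,
    tournament: int = 2,
) -> tuple[Order, float]:
    """Genetic-algorithm baseline over orders.

    Order crossover (OX) + insertion mutation, tournament selection,
    and one-elite survival per generation.  Defaults apply one random
    insertion move to every offspring and keep selection pressure
    gentle (binary tournament): order spaces are full of near-ties, and
    stronger pressure collapses the population onto one plateau.
    """
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    rng = np.random.default_rng(seed)
    cache = ScoreCache()
    budget = _Budget(max_evaluations)
    scorer = _make_scorer(data, max_parents, cache, budget)
    names = list(data.columns)
    members = [Order.random(names, rng) for _ in range(pop_size)]
    scores = [scorer(o) for o in members]
    best_i = int(np.argmax(scores))
    best_order, best_score = members[best_i], scores[best_i]

    def select() -> Order:
        idx = rng.choice(pop_size, size=min(tournament, pop_size), replace=False)
        return members[int(idx[np.argmax([scores[i] for i in idx])])]

    for _ in range(generations):
        if budget.exhausted():
            break
        new_members = [best_order]  # elitism
        new_scores = [best_score]
        while len(new_members) < pop_size and not budget.exhausted():
            if rng.random() < crossover_prob:
                child = _order_crossover(select(), select(), rng)
            else:
                child = select()
            if rng.random() < mutation_prob:
                child = perturb_order(child, StepSize(1e-9), rng)  # one insertion move
            new_members.append(child)
            new_scores.append(scorer(child))
        members = new_members
        scores = new_scores
        pop_size_now = len(members)
        best_i = int(np.argmax(scores))
        if scores[best_i] > best_score:
            best_order, best_score = members[best_i], scores[best_i]
        if pop_size_now < pop_size:  # budget ran out mid-generation
            break
    return best_order, best_score
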