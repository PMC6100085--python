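"""End-to-end pipeline: skeleton learning, split, orientation, merge.

Low-dimensional problems (fewer variables than ``threshold_k``) run one
global BSO + K2 pass; high-dimensional ones are split into per-node
neighborhood blocks over a cheap provisional skeleton, each block is
learned separately, and the per-block partially directed graphs are
merged with conflict demotion and an acyclicity repair.

Direction source depends on the data type: continuous data gets the
additive-noise orientation stage on each sub-skeleton; discrete data
keeps the directions of the K2 DAG found under the optimal order (the
ANM mechanism as fitted here is a continuous-data device).  Continuous
input is quantile-discretized for the count-based skeleton phase only;
orientation always sees the raw values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .direction_learning import split_skeleton, orient_subskeleton
from .k2_scoring import Order, k2_parent_search
from .network_model import Network, PDAG, dag_to_skeleton
from .order_search import BSOConfig, bso_search
from .synthetic_data import ContinuousDataset, DiscreteDataset

__all__ = ["FrameworkConfig", "learn_skeleton", "merge_pdags", "run", "discretize"]

logger = logging.getLogger(__name__)


@dataclass
class FrameworkConfig:
    """Configuration of the full pipeline.

    ``threshold_k`` is the dimension at which the split/merge path
    replaces the single global search; ``bso`` configures the order
    search; ``alpha`` is the significance level of the orientation
    stage.
    """

    threshold_k: int = 50
    bso: BSOConfig = field(default_factory=BSOConfig)
    max_parents: int = 4
    alpha: float = 0.05
    n_bins: int = 3  # quantile bins for continuous -> discrete skeleton phase
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_k < 2:
            raise ValueError("threshold_k must be >= 2")


def discretize(data: ContinuousDataset, n_bins: int = 3) -> DiscreteDataset:
    """Quantile-bin each column into ``n_bins`` states."""
    n, p = data.values.shape
    out = np.zeros((n, p), dtype=np.int64)
    for i in range(p):
        col = data.values[:, i]
        edges = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
        out[:, i] = np.searchsorted(edges, col, side="right")
    return DiscreteDataset(list(data.columns), out, [n_bins] * p)


def _learn_dag(
    data: DiscreteDataset, cfg: FrameworkConfig, seed: int
) -> tuple[Network, float]:
    bso_cfg = replace(cfg.bso, seed=seed)
    best_order, _, _ = bso_search(data, bso_cfg, cfg.max_parents)
    return k2_parent_search(data, best_order, cfg.max_parents)


def learn_skeleton(data: DiscreteDataset, cfg: FrameworkConfig) -> PDAG:
    """BSO order search + greedy K2 under the best order, directions
    forgotten."""
    if data.n_samples < 1:
        raise ValueError("empty dataset")
    dag, _ = _learn_dag(data, cfg, cfg.seed)
    return dag_to_skeleton(dag)


def merge_pdags(parts: list[PDAG], nodes: list[str]) -> PDAG:
    """Union per-block partially directed graphs into one.

    A pair directed in some part and undirected elsewhere stays
    directed; a pair directed both ways across parts is demoted to
    undirected (and logged).  If the union's directed subgraph acquired
    a cycle, cycle edges are demoted — fewest supporting parts first,
    ties broken against the latest-added edge — until acyclic.
    """
    node_set = set(nodes)
    support: dict[tuple[str, str], int] = {}
    added_at: dict[tuple[str, str], int] = {}
    undirected: set[frozenset] = set()
    tick = 0
    for part in parts:
        if not set(part.nodes) <= node_set:
            raise ValueError("part has nodes outside the merge node list")
        for u, v in sorted(part.directed_edges):
            support[(u, v)] = support.get((u, v), 0) + 1
            added_at.setdefault((u, v), tick)
            tick += 1
        for pair in part.undirected_edges:
            undirected.add(pair)
    out = PDAG(nodes)
    conflicting = {
        frozenset((u, v)) for (u, v) in support if (v, u) in support
    }
    for pair in conflicting:
        u, v = sorted(pair)
        logger.info("direction conflict on (%s, %s); demoted to undirected", u, v)
    for (u, v) in support:
        if frozenset((u, v)) not in conflicting:
            out.add_directed(u, v)
    for pair in undirected | conflicting:
        u, v = sorted(pair)
        out.add_undirected(u, v)
    # acyclicity repair on the directed part
    import networkx as nx

    g = out.directed_subgraph()
    while not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        u, v = min(
            ((a, b) for a, b, *_ in cycle),
            key=lambda e: (support.get(e, 0), -added_at.get(e, 0)),
        )
        logger.info("cycle after merge; demoting %s -> %s", u, v)
        out.demote(u, v)
        g.remove_edge(u, v)
    out.validate()
    return out


def _k2_directions(dag: Network) -> PDAG:
    out = PDAG(dag.nodes)
    for u, v in dag.edges():
        out.add_directed(u, v)
    return out


def run(data: DiscreteDataset | ContinuousDataset, cfg: FrameworkConfig) -> PDAG:
    """Full pipeline; returns a partially directed graph.

    * n < threshold_k, discrete input: one global search; output is the
      K2 DAG's directions.
    * n < threshold_k, continuous input: skeleton from the discretized
      data, then additive-noise orientation of every sub-skeleton,
      merged.
    * n >= threshold_k: a reduced-budget provisional skeleton defines
      per-node neighborhood blocks; the search is rerun per block and
      the block results merged.
    """
    continuous = isinstance(data, ContinuousDataset)
    disc = discretize(data, cfg.n_bins) if continuous else data
    n = disc.n_variables
    if n < cfg.threshold_k:
        dag, _ = _learn_dag(disc, cfg, cfg.seed)
        if not continuous:
            return _k2_directions(dag)
        skel = dag_to_skeleton(dag)
        parts = [
            orient_subskeleton(
                data, sub, alpha=cfg.alpha, seed=_sub_seed(cfg.seed, i)
            )
            for i, sub in enumerate(split_skeleton(skel))
        ]
        return merge_pdags(parts + [skel], list(disc.columns))
    # high-dimensional path: provisional skeleton at a reduced budget
    cheap = replace(
        cfg.bso,
        pop_size=max(cfg.bso.n_clusters, cfg.bso.pop_size // 2),
        max_iteration=max(1, cfg.bso.max_iteration // 4),
        seed=_sub_seed(cfg.seed, 0),
    )
    prov_order, _, _ = bso_search(disc, cheap, cfg.max_parents)
    prov_dag, _ = k2_parent_search(disc, prov_order, cfg.max_parents)
    prov_skel = dag_to_skeleton(prov_dag)
    parts: list[PDAG] = []
    for i, node in enumerate(disc.columns):
        block = sorted({node} | prov_skel.neighbors(node))
        if len(block) < 2:
            continue
        block_disc = disc.select(block)
        block_dag, _ = _learn_dag(block_disc, cfg, _sub_seed(cfg.seed, i + 1))
        if continuous:
            block_skel = dag_to_skeleton(block_dag)
            subs = [s for s in split_skeleton(block_skel) if s.target == node]
            for sub in subs:
                parts.append(
                    orient_subskeleton(
                        data, sub, alpha=cfg.alpha, seed=_sub_seed(cfg.seed, 1000 + i)
                    )
                )
            parts.append(block_skel)
        else:
            parts.append(_k2_directions(block_dag))
    return merge_pdags(parts, list(disc.columns))


def _sub_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(i,)).generate_state(1)[0] % (2**31))
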