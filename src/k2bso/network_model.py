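"""Graph containers for causal Bayesian networks.

A :class:`Network` is a directed acyclic graph over named discrete
variables, each carrying a cardinality ``r_i`` and, optionally, a
conditional probability table with one row per parent configuration
(``q_i`` rows, lexicographic parent-state order, last parent varying
fastest).  A :class:`PDAG` is the partially directed graph produced by
structure learning: a mix of directed edges and still-unoriented
(undirected) edges.

On-disk formats: a versioned JSON schema (canonical) and a minimal
subset of the BIF 0.15 "network/variable/probability" dialect, table
form only, since benchmark networks circulate as BIF.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "PDAG",
    "GraphStats",
    "read_network",
    "write_network",
    "graph_stats",
    "dag_to_skeleton",
]

_CPT_ROW_TOL = 1e-9


class NetworkValidationError(ValueError):
    """A network violated a structural or probabilistic invariant."""


class Network:
    """Directed acyclic graph with per-node cardinalities and optional CPTs.

    Parameters
    ----------
    nodes:
        Variable names in file/declaration order.  Node identity is by
        name; positional indices follow this order.
    cardinalities:
        Number of discrete states ``r_i >= 2`` per node, aligned with
        ``nodes``.
    parent_sets:
        Mapping from node name to its (ordered) list of parent names.
    cpts:
        Optional mapping from node name to an array of shape
        ``(q_i, r_i)`` where ``q_i`` is the product of the parent
        cardinalities.  Rows are ordered lexicographically by parent
        state, last parent fastest-varying, and each row sums to one.
        ``None`` marks a structure-only network (e.g. a learned DAG
        before parameter fitting).
    states:
        Optional mapping from node name to state labels; defaults to
        ``s0..s{r-1}``.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        cardinalities: Sequence[int],
        parent_sets: dict[str, list[str]],
        cpts: dict[str, np.ndarray] | None = None,
        states: dict[str, list[str]] | None = None,
    ) -> None:
        self.nodes: list[str] = list(nodes)
        self.cardinality: dict[str, int] = {
            name: int(r) for name, r in zip(self.nodes, cardinalities, strict=True)
        }
        self.parent_sets: dict[str, list[str]] = {
            name: list(parent_sets.get(name, [])) for name in self.nodes
        }
        self.cpts: dict[str, np.ndarray] | None = None
        if cpts is not None:
            self.cpts = {name: np.asarray(cpts[name], dtype=float) for name in self.nodes}
        self.states: dict[str, list[str]] = states or {
            name: [f"s{k}" for k in range(self.cardinality[name])] for name in self.nodes
        }
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edges(self) -> Iterator[tuple[str, str]]:
        """Yield directed edges as (parent, child) pairs."""
        for child in self.nodes:
            for parent in self.parent_sets[child]:
                yield (parent, child)

    @property
    def n_edges(self) -> int:
        return sum(len(ps) for ps in self.parent_sets.values())

    def q(self, node: str) -> int:
        """Number of parent configurations of ``node`` (1 if parentless)."""
        q = 1
        for p in self.parent_sets[node]:
            q *= self.cardinality[p]
        return q

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    def topological_order(self) -> list[str]:
        # stable: break ties by declaration order
        return list(nx.lexicographical_topological_sort(self.to_digraph(), key=self.nodes.index))

    def validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkValidationError("duplicate node names")
        for name, r in self.cardinality.items():
            if r < 2:
                raise NetworkValidationError(f"node {name!r} has cardinality {r} < 2")
        for child, parents in self.parent_sets.items():
            if child in parents:
                raise NetworkValidationError(f"node {child!r} is its own parent")
            unknown = set(parents) - set(self.nodes)
            if unknown:
                raise NetworkValidationError(f"unknown parents {unknown} of {child!r}")
            if len(set(parents)) != len(parents):
                raise NetworkValidationError(f"duplicate parents of {child!r}")
        if not nx.is_directed_acyclic_graph(self.to_digraph()):
            raise NetworkValidationError("parent relation contains a directed cycle")
        if self.cpts is not None:
            for name in self.nodes:
                cpt = self.cpts[name]
                q, r = self.q(name), self.cardinality[name]
                if cpt.shape != (q, r):
                    raise NetworkValidationError(
                        f"CPT of {name!r} has shape {cpt.shape}, expected {(q, r)}"
                    )
                bad = np.abs(cpt.sum(axis=1) - 1.0) > _CPT_ROW_TOL
                if bad.any():
                    raise NetworkValidationError(
                        f"CPT rows of {name!r} do not sum to 1: rows {np.flatnonzero(bad)}"
                    )

    # -- comparison --------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        if self.nodes != other.nodes or self.cardinality != other.cardinality:
            return False
        if {k: sorted(v) for k, v in self.parent_sets.items()} != {
            k: sorted(v) for k, v in other.parent_sets.items()
        }:
            return False
        if (self.cpts is None) != (other.cpts is None):
            return False
        if self.cpts is not None:
            assert other.cpts is not None
            for name in self.nodes:
                if not np.allclose(self.cpts[name], other.cpts[name], atol=1e-12, rtol=0):
                    return False
        return True

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges}, cpts={self.cpts is not None})"


class PDAG:
    """Partially directed acyclic graph.

    Directed and undirected edge sets are disjoint as unordered pairs;
    the directed subgraph stays acyclic.  Adding a directed copy of a
    pair already present undirected upgrades it to directed
    (information-preserving merge); the reverse downgrade never happens
    implicitly.
    """

    def __init__(self, nodes: Iterable[str]) -> None:
        self.nodes: list[str] = list(nodes)
        self._node_set = set(self.nodes)
        if len(self._node_set) != len(self.nodes):
            raise NetworkValidationError("duplicate node names")
        self.directed_edges: set[tuple[str, str]] = set()
        self.undirected_edges: set[frozenset[str]] = set()

    def _check_pair(self, u: str, v: str) -> None:
        if u == v:
            raise NetworkValidationError(f"self-loop on {u!r}")
        if u not in self._node_set or v not in self._node_set:
            raise NetworkValidationError(f"unknown endpoint in ({u!r}, {v!r})")

    def add_directed(self, u: str, v: str) -> None:
        """Add u -> v; upgrades an existing undirected u - v."""
        self._check_pair(u, v)
        self.undirected_edges.discard(frozenset((u, v)))
        self.directed_edges.add((u, v))

    def add_undirected(self, u: str, v: str) -> None:
        """Add u - v unless the pair is already directed."""
        self._check_pair(u, v)
        if (u, v) in self.directed_edges or (v, u) in self.directed_edges:
            return
        self.undirected_edges.add(frozenset((u, v)))

    def demote(self, u: str, v: str) -> None:
        """Forget the direction of u -> v, leaving u - v."""
        self.directed_edges.discard((u, v))
        self.undirected_edges.add(frozenset((u, v)))

    def has_pair(self, u: str, v: str) -> bool:
        return (
            (u, v) in self.directed_edges
            or (v, u) in self.directed_edges
            or frozenset((u, v)) in self.undirected_edges
        )

    @property
    def n_edges(self) -> int:
        return len(self.directed_edges) + len(self.undirected_edges)

    def skeleton_pairs(self) -> set[frozenset[str]]:
        """All adjacent pairs, directions forgotten."""
        return {frozenset(e) for e in self.directed_edges} | set(self.undirected_edges)

    def neighbors(self, node: str) -> set[str]:
        out: set[str] = set()
        for u, v in self.directed_edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        for pair in self.undirected_edges:
            if node in pair:
                out.add(next(iter(pair - {node})))
        return out

    def directed_subgraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_edges)
        return g

    def validate(self) -> None:
        directed_pairs = {frozenset(e) for e in self.directed_edges}
        if directed_pairs & self.undirected_edges:
            raise NetworkValidationError("pair present both directed and undirected")
        for u, v in self.directed_edges:
            self._check_pair(u, v)
            if (v, u) in self.directed_edges:
                raise NetworkValidationError(f"both directions present for ({u!r}, {v!r})")
        for pair in self.undirected_edges:
            if len(pair) != 2:
                raise NetworkValidationError("self-loop in undirected edges")
        if not nx.is_directed_acyclic_graph(self.directed_subgraph()):
            raise NetworkValidationError("directed subgraph contains a cycle")

    def copy(self) -> "PDAG":
        out = PDAG(self.nodes)
        out.directed_edges = set(self.directed_edges)
        out.undirected_edges = set(self.undirected_edges)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PDAG):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and self.directed_edges == other.directed_edges
            and self.undirected_edges == other.undirected_edges
        )

    def __repr__(self) -> str:
        return (
            f"PDAG(n_nodes={len(self.nodes)}, directed={len(self.directed_edges)}, "
            f"undirected={len(self.undirected_edges)})"
        )


@dataclass(frozen=True)
class GraphStats:
    """Summary statistics of a directed network's structure."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    max_in_degree: int


def graph_stats(net: Network) -> GraphStats:
    """Node/edge counts, average (total) degree and maximum in-degree.

    Average degree counts each edge once at each endpoint, i.e.
    ``2 * n_edges / n_nodes``.
    """
    n_edges = net.n_edges
    in_degrees = [len(net.parent_sets[v]) for v in net.nodes]
    return GraphStats(
        n_nodes=net.n_nodes,
        n_edges=n_edges,
        avg_degree=2.0 * n_edges / net.n_nodes if net.n_nodes else 0.0,
        max_in_degree=max(in_degrees, default=0),
    )


def dag_to_skeleton(net: Network) -> PDAG:
    """Forget edge directions: every DAG edge becomes an undirected pair."""
    skel = PDAG(net.nodes)
    for u, v in net.edges():
        skel.add_undirected(u, v)
    return skel


# ---------------------------------------------------------------------------
# I/O: JSON (canonical) and a minimal BIF subset
# ---------------------------------------------------------------------------

_JSON_SCHEMA_VERSION = 1


def write_network(net: Network, path: str | Path, format: str = "json") -> None:
    """Serialize a network; ``read_network`` inverts it field-for-field."""
    path = Path(path)
    if format == "json":
        payload = {
            "schema_version": _JSON_SCHEMA_VERSION,
            "nodes": [
                {
                    "name": name,
                    "states": net.states[name],
                    "parents": net.parent_sets[name],
                    "cpt": net.cpts[name].tolist() if net.cpts is not None else None,
                }
                for name in net.nodes
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    elif format == "bif":
        if net.cpts is None:
            raise ValueError("BIF output requires CPTs")
        path.write_text(_to_bif(net))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path: str | Path, format: str = "json") -> Network:
    """Read a network from the JSON schema or the BIF table subset."""
    path = Path(path)
    text = path.read_text()
    if format == "json":
        payload = json.loads(text)
        names = [entry["name"] for entry in payload["nodes"]]
        cards = [len(entry["states"]) for entry in payload["nodes"]]
        parents = {entry["name"]: list(entry["parents"]) for entry in payload["nodes"]}
        states = {entry["name"]: list(entry["states"]) for entry in payload["nodes"]}
        raw_cpts = {entry["name"]: entry["cpt"] for entry in payload["nodes"]}
        cpts = None
        if all(v is not None for v in raw_cpts.values()):
            cpts = {k: np.asarray(v, dtype=float) for k, v in raw_cpts.items()}
        elif any(v is not None for v in raw_cpts.values()):
            raise NetworkValidationError("mixed present/absent CPTs in file")
        return Network(names, cards, parents, cpts, states)
    if format == "bif":
        return _from_bif(text)
    raise ValueError(f"unknown format {format!r}")


def _to_bif(net: Network) -> str:
    lines = ["network unknown {", "}"]
    for name in net.nodes:
        r = net.cardinality[name]
        state_list = ", ".join(net.states[name])
        lines += [
            f"variable {name} {{",
            f"  type discrete [ {r} ] {{ {state_list} }};",
            "}",
        ]
    assert net.cpts is not None
    for name in net.nodes:
        parents = net.parent_sets[name]
        cpt = net.cpts[name]
        if not parents:
            values = ", ".join(repr(float(v)) for v in cpt[0])
            lines += [f"probability ( {name} ) {{", f"  table {values};", "}"]
        else:
            head = ", ".join(parents)
            lines.append(f"probability ( {name} | {head} ) {{")
            cards = [net.cardinality[p] for p in parents]
            # np.ndindex varies the last axis fastest — matches row order
            for j, config in enumerate(np.ndindex(*cards)):
                labels = ", ".join(net.states[p][k] for p, k in zip(parents, config))
                values = ", ".join(repr(float(v)) for v in cpt[j])
                lines.append(f"  ( {labels} ) {values};")
            lines.append("}")
    return "\n".join(lines) + "\n"


_BIF_VARIABLE = re.compile(
    r"variable\s+(?P<name>\S+)\s*\{\s*type\s+discrete\s*\[\s*(?P<r>\d+)\s*\]\s*"
    r"\{\s*(?P<states>[^}]*?)\s*\}\s*;\s*\}",
    re.DOTALL,
)
_BIF_PROBABILITY = re.compile(
    r"probability\s*\(\s*(?P<head>[^)|]+?)\s*(?:\|\s*(?P<parents>[^)]+?)\s*)?\)\s*"
    r"\{(?P<body>.*?)\}",
    re.DOTALL,
)


def _from_bif(text: str) -> Network:
    names: list[str] = []
    states: dict[str, list[str]] = {}
    for m in _BIF_VARIABLE.finditer(text):
        name = m.group("name")
        labels = [s.strip() for s in m.group("states").split(",")]
        if len(labels) != int(m.group("r")):
            raise NetworkValidationError(f"state count mismatch for {name!r}")
        names.append(name)
        states[name] = labels
    parents: dict[str, list[str]] = {n: [] for n in names}
    cpts: dict[str, np.ndarray] = {}
    for m in _BIF_PROBABILITY.finditer(text):
        child = m.group("head").strip()
        if child not in states:
            raise NetworkValidationError(f"probability block for unknown variable {child!r}")
        plist = (
            [p.strip() for p in m.group("parents").split(",")] if m.group("parents") else []
        )
        parents[child] = plist
        r = len(states[child])
        body = m.group("body")
        if not plist:
            tab = re.search(r"table\s+([^;]+);", body)
            if tab is None:
                raise NetworkValidationError(f"no table row for root {child!r}")
            row = [float(x) for x in tab.group(1).split(",")]
            cpts[child] = np.asarray([row], dtype=float)
        else:
            cards = [len(states[p]) for p in plist]
            q = int(np.prod(cards))
            cpt = np.full((q, r), np.nan)
            label_index = {
                p: {lab: k for k, lab in enumerate(states[p])} for p in plist
            }
            strides = np.cumprod([1] + cards[::-1][:-1])[::-1]  # last parent fastest
            for entry in re.finditer(r"\(\s*([^)]+?)\s*\)\s*([^;]+);", body):
                labels = [s.strip() for s in entry.group(1).split(",")]
                row = [float(x) for x in entry.group(2).split(",")]
                j = sum(
                    label_index[p][lab] * int(s)
                    for p, lab, s in zip(plist, labels, strides)
                )
                cpt[j] = row
            if np.isnan(cpt).any():
                raise NetworkValidationError(f"missing CPT rows for {child!r}")
            cpts[child] = cpt
    missing = [n for n in names if n not in cpts]
    if missing:
        raise NetworkValidationError(f"no probability block for {missing}")
    return Network(names, [len(states[n]) for n in names], parents, cpts, states)
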