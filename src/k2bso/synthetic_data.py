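"""Synthetic ground truth and data generators.

Everything structure learning needs is generated in-process: random
DAGs with Dirichlet CPTs, discrete samples by ancestral (forward)
sampling, and continuous additive-noise-model samples with smooth
nonlinear mechanisms and non-Gaussian noise.  All randomness flows
through one ``numpy`` generator per call, seeded explicitly; there is
no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network_model import Network

__all__ = [
    "DiscreteDataset",
    "ContinuousDataset",
    "random_dag",
    "forward_sample",
    "anm_sample",
]


@dataclass
class DiscreteDataset:
    """N x n matrix of categorical state indices.

    ``values[:, i]`` holds integers in ``[0, cardinalities[i])``; column
    order matches the paired :class:`~k2bso.network_model.Network` when
    one exists.
    """

    columns: list[str]
    values: np.ndarray  # (N, n) int
    cardinalities: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count mismatch")
        if len(self.cardinalities) != len(self.columns):
            raise ValueError("cardinality count mismatch")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one sample")
        for i, r in enumerate(self.cardinalities):
            col = self.values[:, i]
            if col.min() < 0 or col.max() >= r:
                raise ValueError(f"column {self.columns[i]!r} outside [0, {r})")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def cardinality(self, name: str) -> int:
        return self.cardinalities[self.columns.index(name)]

    def select(self, names: Sequence[str]) -> "DiscreteDataset":
        idx = [self.columns.index(n) for n in names]
        return DiscreteDataset(
            list(names), self.values[:, idx], [self.cardinalities[i] for i in idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, sep: str = ",", cardinalities: Sequence[int] | None = None
    ) -> "DiscreteDataset":
        """Read integer-coded samples; cardinalities default to max+1 per column."""
        df = pd.read_csv(path, sep=sep)
        values = df.to_numpy(dtype=np.int64)
        if cardinalities is None:
            cards = [max(int(values[:, i].max()) + 1, 2) for i in range(values.shape[1])]
        else:
            cards = list(cardinalities)
        return cls(list(df.columns), values, cards)


@dataclass
class ContinuousDataset:
    """N x n real-valued matrix with named columns."""

    columns: list[str]
    values: np.ndarray  # (N, n) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values/columns shape mismatch")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one sample")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "ContinuousDataset":
        df = pd.read_csv(path, sep=sep)
        return cls(list(df.columns), df.to_numpy(dtype=float))


def random_dag(
    n_nodes: int,
    max_parents: int = 4,
    edge_prob: float = 0.3,
    seed: int = 0,
    cardinality: int | Sequence[int] = 2,
) -> Network:
    """Random DAG with Dirichlet(1, ..., 1) CPTs.

    Edges only run from earlier to later nodes in a hidden random
    permutation, so acyclicity holds by construction; the in-degree is
    capped at ``max_parents``.  Node names are ``X0 .. X{n-1}`` in
    declaration (not permutation) order.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"X{i}" for i in range(n_nodes)]
    if isinstance(cardinality, int):
        cards = [cardinality] * n_nodes
    else:
        cards = list(cardinality)
    perm = rng.permutation(n_nodes)  # hidden topological order
    parent_sets: dict[str, list[str]] = {n: [] for n in names}
    for j_pos in range(1, n_nodes):
        child = names[perm[j_pos]]
        for i_pos in range(j_pos):
            if len(parent_sets[child]) >= max_parents:
                break
            if rng.random() < edge_prob:
                parent_sets[child].append(names[perm[i_pos]])
    cpts: dict[str, np.ndarray] = {}
    for i, name in enumerate(names):
        r = cards[i]
        q = 1
        for p in parent_sets[name]:
            q *= cards[names.index(p)]
        cpts[name] = rng.dirichlet(np.ones(r), size=q)
    return Network(names, cards, parent_sets, cpts)


def forward_sample(net: Network, n_samples: int, seed: int = 0) -> DiscreteDataset:
    """Ancestral sampling: visit nodes in topological order, draw each
    node from its CPT row given the already-sampled parent states."""
    if net.cpts is None:
        raise ValueError("network has no CPTs to sample from")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    col_of = {name: i for i, name in enumerate(net.nodes)}
    values = np.zeros((n_samples, n), dtype=np.int64)
    for name in net.topological_order():
        parents = net.parent_sets[name]
        cpt = net.cpts[name]
        if parents:
            cards = [net.cardinality[p] for p in parents]
            cols = [values[:, col_of[p]] for p in parents]
            # row index: lexicographic in parent states, last parent fastest
            rows = np.ravel_multi_index(cols, cards)
        else:
            rows = np.zeros(n_samples, dtype=np.int64)
        cum = np.cumsum(cpt, axis=1)
        u = rng.random(n_samples)
        values[:, col_of[name]] = (u[:, None] > cum[rows]).sum(axis=1)
    return DiscreteDataset(list(net.nodes), values, [net.cardinality[v] for v in net.nodes])


def anm_sample(
    dag: Network,
    n_samples: int,
    noise: str = "uniform",
    seed: int = 0,
    noise_amplitude: tuple[float, float] = (0.5, 1.0),
) -> ContinuousDataset:
    """Continuous additive-noise samples from a DAG's structure.

    Root nodes are pure noise draws.  Every other node is
    ``f(parents) + noise`` with ``f`` a sum of per-parent cubic-plus-
    linear terms, ``a_p * z^3 + b_p * z`` with ``z`` the parent column
    standardized to unit variance and coefficients ``a_p, b_p`` drawn
    uniformly from [0.5, 1.5] per seed.  Noise is non-Gaussian:
    ``uniform`` means amplitude * U(-1, 1); ``laplace`` means a Laplace
    draw scaled to the same variance (amplitude^2 / 3).  Amplitudes are
    drawn per node from ``noise_amplitude``.

    The CPTs of ``dag`` are ignored; only its structure matters.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if noise not in ("uniform", "laplace"):
        raise ValueError("noise must be 'uniform' or 'laplace'")
    rng = np.random.default_rng(seed)
    n = dag.n_nodes
    col_of = {name: i for i, name in enumerate(dag.nodes)}
    values = np.zeros((n_samples, n), dtype=float)
    lo, hi = noise_amplitude
    for name in dag.topological_order():
        amplitude = rng.uniform(lo, hi)
        if noise == "uniform":
            eps = amplitude * rng.uniform(-1.0, 1.0, size=n_samples)
        else:
            # Laplace(0, b) has variance 2 b^2; match U(-1,1)*a variance a^2/3
            eps = rng.laplace(0.0, amplitude / np.sqrt(6.0), size=n_samples)
        parents = dag.parent_sets[name]
        signal = np.zeros(n_samples)
        for p in parents:
            z = values[:, col_of[p]]
            scale = z.std()
            if scale > 0:
                z = z / scale
            a, b = rng.uniform(0.5, 1.5, size=2)
            signal += a * z**3 + b * z
        values[:, col_of[name]] = signal + eps
    return ContinuousDataset(list(dag.nodes), values)
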