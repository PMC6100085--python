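"""Shared fixtures: small hand-built networks and datasets.

Everything is generated in-process; no fixture files on disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from k2bso import Network, forward_sample


@pytest.fixture
def one_node_net() -> Network:
    return Network(["A"], [2], {"A": []}, {"A": np.array([[0.5, 0.5]])})


@pytest.fixture
def collider_net() -> Network:
    """A -> C <- B with a noisy-OR mechanism for C.

    The noisy-OR (rather than XOR) keeps every single-parent dependence
    strong, so greedy score-based search can see it.
    """
    cpts = {
        "A": np.array([[0.5, 0.5]]),
        "B": np.array([[0.5, 0.5]]),
        # rows: (A,B) = 00, 01, 10, 11 (last parent fastest)
        "C": np.array([[0.95, 0.05], [0.1, 0.9], [0.1, 0.9], [0.02, 0.98]]),
    }
    return Network(["A", "B", "C"], [2, 2, 2], {"A": [], "B": [], "C": ["A", "B"]}, cpts)


@pytest.fixture
def xor_collider_net() -> Network:
    """A -> C <- B with C = XOR(A, B) deterministically."""
    cpts = {
        "A": np.array([[0.5, 0.5]]),
        "B": np.array([[0.5, 0.5]]),
        "C": np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [1.0, 0.0]]),
    }
    return Network(["A", "B", "C"], [2, 2, 2], {"A": [], "B": [], "C": ["A", "B"]}, cpts)


@pytest.fixture
def chain5_net() -> Network:
    """X0 -> X1 -> X2 -> X3 -> X4 with strongly dependent links."""
    root = np.array([[0.5, 0.5]])
    link = np.array([[0.85, 0.15], [0.15, 0.85]])
    names = [f"X{i}" for i in range(5)]
    parents = {names[0]: []}
    cpts = {names[0]: root}
    for i in range(1, 5):
        parents[names[i]] = [names[i - 1]]
        cpts[names[i]] = link
    return Network(names, [2] * 5, parents, cpts)


@pytest.fixture
def chain5_data(chain5_net):
    return forward_sample(chain5_net, 500, seed=7)
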