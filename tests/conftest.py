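"""Shared fixtures and hand-built network helpers."""

from __future__ import annotations

import numpy as np
import pytest

from coexpredict.network_builder import CoexpressionNetwork, EdgeModel


def make_edge(u: str, v: str, b1: float = 1.0, b0: float = 0.0, r: float = 0.9,
              n: int = 100) -> EdgeModel:
    """Edge whose two orientations are exact affine inverses.

    ``b1``/``b0`` predict ``v`` from ``u``; the reverse orientation is the
    inverse map, so chained prediction is exactly consistent both ways.
    """
    a, b = sorted((u, v))
    if (a, b) == (u, v):
        b1_ba, b0_ba = b1, b0
    else:
        b1_ba, b0_ba = 1.0 / b1, -b0 / b1
    return EdgeModel(
        gene_a=a, gene_b=b, r=r, n=n,
        b1_ab=1.0 / b1_ba, b0_ab=-b0_ba / b1_ba,
        b1_ba=b1_ba, b0_ba=b0_ba,
    )


def make_network(
    edges: list[tuple],
    threshold: float = 0.0,
) -> CoexpressionNetwork:
    """Network from (u, v[, b1, b0[, r]]) tuples with identity defaults."""
    net = CoexpressionNetwork(threshold=threshold)
    for spec in edges:
        u, v = spec[0], spec[1]
        b1 = spec[2] if len(spec) > 2 else 1.0
        b0 = spec[3] if len(spec) > 3 else 0.0
        r = spec[4] if len(spec) > 4 else 0.9
        net.add_edge(make_edge(u, v, b1, b0, r))
    return net


@pytest.fixture
def chain_net():
    """A - B - C - D - E - F chain with identity edges."""
    return make_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F")])


@pytest.fixture
def layered_net():
    """Layered topology: source S, two middle layers of two, target T,
    fully connected between consecutive layers, plus one layer-skip edge
    A1 - T.  Five simple paths of length <= 3 connect S to T."""
    return make_network([
        ("S", "A1"), ("S", "A2"),
        ("A1", "B1"), ("A1", "B2"), ("A2", "B1"), ("A2", "B2"),
        ("B1", "T"), ("B2", "T"),
        ("A1", "T"),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
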