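"""Shared helpers for the test suite: small random trees and alignments."""

from __future__ import annotations

import numpy as np
import pytest

from lbasim.trees import Tree


def random_tree(labels, rng, max_length: float = 0.5) -> Tree:
    """Uniform-attachment random binary unrooted tree over ``labels``."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    t = Tree()
    hub = t.add_node()
    for lab in labels[:3]:
        t.connect(hub, t.add_node(lab), rng.uniform(0.01, max_length))
    for lab in labels[3:]:
        edges = list(t.edges())
        u, v, ln = edges[rng.integers(len(edges))]
        t.disconnect(u, v)
        mid = t.add_node()
        split = rng.uniform(0.0, 1.0)
        t.connect(u, mid, ln * split)
        t.connect(mid, v, ln * (1.0 - split))
        t.connect(mid, t.add_node(lab), rng.uniform(0.01, max_length))
    return t


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
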