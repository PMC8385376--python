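"""Shared fixtures: random topologies with independent depth oracles,
star-tree helpers, and fast chain settings for functional tests."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from nodecount.pglmm import ChainSettings, PhyloCovariance

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

#: short chains for functional (non-statistical) tests
FAST_CHAIN = ChainSettings(iterations=1500, burn_in=400, thin=2)


class _Node:
    __slots__ = ("children", "parent", "label", "length")

    def __init__(self, label=None, length=1.0):
        self.children: list[_Node] = []
        self.parent: _Node | None = None
        self.label = label
        self.length = length


def random_topology(rng: np.random.Generator, n_tips: int, labels=None):
    """Random binary topology built by sequential leaf splitting.

    Returns ``(newick, depths, clade_sizes)`` where ``depths[label]`` is the
    number of internal nodes (root included) above each tip and
    ``clade_sizes`` lists the tip count under every internal node — both
    computed on this independent node structure, not via the package.
    """
    if labels is None:
        labels = [f"t{i}" for i in range(n_tips)]
    assert len(labels) == n_tips and n_tips >= 2
    root = _Node()
    first, second = _Node(labels[0]), _Node(labels[1])
    for c in (first, second):
        c.parent = root
        root.children.append(c)
    leaves = [first, second]
    for lbl in labels[2:]:
        target = leaves[rng.integers(len(leaves))]
        inner = _Node(length=target.length)
        inner.parent = target.parent
        inner.parent.children[inner.parent.children.index(target)] = inner
        target.parent = inner
        target.length = float(rng.uniform(0.5, 5.0))
        new = _Node(lbl, float(rng.uniform(0.5, 5.0)))
        new.parent = inner
        inner.children = [target, new]
        leaves.append(new)
    for lf in leaves:
        lf.length = float(rng.uniform(0.5, 5.0))

    depths: dict[str, int] = {}
    for lf in leaves:
        d, node = 0, lf
        while node.parent is not None:  # parent-pointer walk: count internals
            d += 1
            node = node.parent
        depths[lf.label] = d

    clade_sizes: list[int] = []

    def _newick(node: _Node) -> str:
        if not node.children:
            return f"{node.label}:{node.length:.6f}"
        inner = ",".join(_newick(c) for c in node.children)
        clade_sizes.append(sum(1 for lf in leaves if _is_descendant(lf, node)))
        if node.parent is None:
            return f"({inner});"
        return f"({inner}):{node.length:.6f}"

    def _is_descendant(leaf: _Node, anc: _Node) -> bool:
        node = leaf
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    return _newick(root), depths, clade_sizes


def star_newick(n: int, length: float = 1.0) -> str:
    return "(" + ",".join(f"T{i}:{length:g}" for i in range(n)) + ");"


def star_cov(labels) -> PhyloCovariance:
    n = len(labels)
    return PhyloCovariance(
        matrix=np.eye(n), raw=np.eye(n), labels=list(labels), depth=1.0
    )


def star_table(rng: np.random.Generator, n: int, eta_fn, group: str = "All") -> pd.DataFrame:
    """Independent-observation Poisson response table on a star phylogeny."""
    t = rng.uniform(0.0, 150.0, n)
    y = np.maximum(rng.poisson(np.exp(eta_fn(t))), 1)
    return pd.DataFrame(
        {
            "tip_label": [f"T{i}" for i in range(n)],
            "n_nodes": y,
            "time": t,
            "group": group,
            "n_occ": 1,
            "log_n_occ": 0.0,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
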