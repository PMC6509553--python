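"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

import phylostruct as ps
from phylostruct.tree import _node_name, normalize_name

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree():
    return ps.parse_newick(TOY_NEWICK)


@pytest.fixture
def toy_dm(toy_tree):
    return toy_tree.patristic_distances()


@pytest.fixture(scope="session")
def small_dataset():
    """A 20-species pool run end to end; small enough for R cross-checks."""
    cfg = ps.GeneratorConfig(
        seed=17, pool_size=20, richness_schedule=(8, 6, 5, 4, 3), n_families=4
    )
    return ps.generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    return ps.generate_dataset(ps.GeneratorConfig(seed=1))


# ---------------------------------------------------------------------------
# random tree construction (independent of the package's writers)

def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary topology with uniform branch lengths, as Newick text."""
    clades = [f"T{i + 1}" for i in range(n_tips)]
    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        b = clades.pop(j)
        a = clades.pop(i)
        la, lb = rng.uniform(0.1, 5.0, size=2)
        clades.append(f"({a}:{la:.9f},{b}:{lb:.9f})")
    return clades[0] + ";"


def random_undated_tree(rng: np.random.Generator, n_tips: int):
    """Random topology with named internals and a consistent full age map.

    Returns (Phylogeny without branch lengths, dict of all internal ages).
    Internal ages decay multiplicatively from the root, so any subset of
    them (always including the root) is internally consistent.
    """
    counter = [0]

    def label():
        counter[0] += 1
        return f"N{counter[0]}"

    clades = [(f"T{i + 1}", 0.0) for i in range(n_tips)]
    ages = {}
    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        (tb, ab) = clades.pop(j)
        (ta, aa) = clades.pop(i)
        name = label()
        age = max(aa, ab) + rng.uniform(0.5, 3.0)
        ages[name] = age
        clades.append((f"({ta},{tb}){name}", age))
    text, root_age = clades[0]
    tree = ps.parse_newick(text + ";")
    root_label = _node_name(tree.root)
    return tree, ages, root_label


# ---------------------------------------------------------------------------
# brute-force oracles (deliberately different algorithms from the package)

def brute_patristic(tree: ps.Phylogeny, a: str, b: str) -> float:
    """Path-walk distance: climb from each tip to the MRCA, summing edges."""
    nodes = {normalize_name(_node_name(l)): l for l in tree.tips}
    na, nb = nodes[normalize_name(a)], nodes[normalize_name(b)]
    up_a = {}
    node, total = na, 0.0
    while node is not None:
        up_a[id(node)] = total
        total += node.edge.length or 0.0
        node = node.parent_node
    node, total = nb, 0.0
    while id(node) not in up_a:
        total += node.edge.length
        node = node.parent_node
    return total + up_a[id(node)]


def brute_pd(tree: ps.Phylogeny, taxa) -> float:
    """Edge scan: an edge counts iff its subtree holds a sampled taxon."""
    wanted = {normalize_name(t) for t in taxa}
    total = 0.0
    for node in tree._tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = {
            normalize_name(_node_name(l)) for l in node.leaf_iter()
        }
        if leaves & wanted:
            total += node.edge.length
    return total


def brute_mpd(tree: ps.Phylogeny, taxa) -> float:
    taxa = sorted(set(taxa))
    dists = [
        brute_patristic(tree, a, b)
        for i, a in enumerate(taxa)
        for b in taxa[i + 1:]
    ]
    return sum(dists) / len(dists)


def brute_mntd(tree: ps.Phylogeny, taxa) -> float:
    taxa = sorted(set(taxa))
    nearest = []
    for a in taxa:
        nearest.append(
            min(brute_patristic(tree, a, b) for b in taxa if b != a)
        )
    return sum(nearest) / len(nearest)
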