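import numpy as np
import pandas as pd
import pytest

import dendropy

from ganokit import key as keymod
from ganokit import morpho


@pytest.fixture(scope="session")
def reference_profiles():
    return morpho.load_reference_profiles()


@pytest.fixture(scope="session")
def us_key():
    return keymod.load_key()


def random_binary_tree(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random unrooted binary topology with random branch lengths, built by
    sequential random joins (independent of the package's own generators)."""
    tns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_tips):
        taxon = dendropy.Taxon(label=f"t{i + 1}")
        tns.add_taxon(taxon)
        nodes.append(dendropy.Node(taxon=taxon))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.05, 1.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    center = dendropy.Node()
    for node in nodes:
        center.add_child(node)
        node.edge.length = float(rng.uniform(0.05, 1.0))
    tree = dendropy.Tree(seed_node=center, taxon_namespace=tns)
    tree.is_rooted = False
    return tree


def path_length_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Additive (patristic) distance matrix of a tree, via dendropy."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    data = [
        [0.0 if a == b else pdm.distance(taxa[a], taxa[b]) for b in labels]
        for a in labels
    ]
    return pd.DataFrame(data, index=labels, columns=labels)


def split_set(tree: dendropy.Tree) -> set[frozenset]:
    """Canonical non-trivial splits of an (unrooted) dendropy tree."""
    all_tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = min(all_tips)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        out.add(all_tips - side if ref in side else side)
    return out
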