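"""Summaries of support-annotated phylogenies.

Reads Newick trees whose internal-node labels carry bootstrap support,
reports the fraction of maximally supported nodes, tests clade monophyly
after outgroup rooting, and computes Robinson-Foulds distances from first
principles (bipartition symmetric difference).
"""

from __future__ import annotations

from pathlib import Path

import dendropy


def load_tree(source: str | Path | dendropy.Tree) -> dendropy.Tree:
    """Parse a Newick tree from a string, file path, or pass through a Tree."""
    if isinstance(source, dendropy.Tree):
        return source
    text = str(source)
    if "(" not in text and Path(text).exists():
        text = Path(text).read_text()
    return dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )


def _node_support(node: dendropy.Node) -> float | None:
    label = node.label
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        return None


def fraction_max_support(tree: str | Path | dendropy.Tree, max_value: float = 100) -> float:
    """Percent of supported internal (non-root) nodes at exactly ``max_value``.

    Nodes without a numeric support label are excluded from the denominator;
    leaves and the root never count.
    """
    tree = load_tree(tree)
    supported = maxed = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        s = _node_support(node)
        if s is None:
            continue
        supported += 1
        if s == max_value:
            maxed += 1
    if supported == 0:
        raise ValueError("tree has no internal support values")
    return 100.0 * maxed / supported


def is_monophyletic(
    tree: str | Path | dendropy.Tree,
    taxa: set[str],
    outgroup: set[str] | None = None,
) -> bool:
    """True iff ``taxa`` form an exact clade after rooting on the outgroup."""
    tree = load_tree(tree).clone(depth=1)
    tree.is_rooted = True
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    taxa = set(taxa)
    outgroup = set(outgroup or ())
    unknown = (taxa | outgroup) - leaves
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if taxa & outgroup:
        raise ValueError("outgroup must be disjoint from the query taxa")
    if outgroup:
        mrca_taxa = [t for t in tree.taxon_namespace if t.label in outgroup]
        if len(mrca_taxa) == 1:
            node = tree.find_node_with_taxon_label(mrca_taxa[0].label)
        else:
            node = tree.mrca(taxa=mrca_taxa)
        if node.parent_node is not None:
            tree.reroot_at_edge(node.edge, update_bipartitions=False)
    if taxa == leaves:
        return True
    query = [t for t in tree.taxon_namespace if t.label in taxa]
    mrca = tree.mrca(taxa=query)
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    return clade == taxa


def bipartitions(tree: str | Path | dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial unrooted splits, each named by the side excluding a reference leaf."""
    tree = load_tree(tree)
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    all_set = frozenset(leaves)
    n = len(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def rf_distance(
    t1: str | Path | dendropy.Tree, t2: str | Path | dendropy.Tree
) -> int:
    """Unrooted Robinson-Foulds distance: splits present in exactly one tree."""
    t1, t2 = load_tree(t1), load_tree(t2)
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))
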