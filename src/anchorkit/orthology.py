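"""K-mer distance orthology assignment.

Assembled consensus sequences from all samples at one target locus are
compared by the overlap of their 20-mer sets, a neighbor-joining tree is
built from the resulting distances, and the tree is cut into orthologous
sets containing at most one sequence per species.  Sparse sets covering too
few species are dropped to limit missing data downstream.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._seq import kmer_set


def kmer_similarity(a: str, b: str, k: int = 20) -> float:
    """Fraction of distinct k-mers shared between two sequences (Jaccard).

    ``|K(a) & K(b)| / |K(a) | K(b)|`` over sets of distinct k-mers; the
    corresponding distance is one minus this value.
    """
    if len(a) < k or len(b) < k:
        raise ValueError(f"sequences must be at least {k} bp")
    ka, kb = kmer_set(a, k), kmer_set(b, k)
    union = ka | kb
    if not union:
        return 0.0
    return len(ka & kb) / len(union)


def kmer_distance(a: str, b: str, k: int = 20) -> float:
    return 1.0 - kmer_similarity(a, b, k)


@dataclass
class KmerDistanceMatrix:
    ids: list[str]
    species: dict[str, str]  # sequence id -> species label
    values: np.ndarray
    k: int = 20

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("distances must lie in [0, 1]")


def build_distance_matrix(
    consensi: list[tuple[str, str, str]], k: int = 20
) -> KmerDistanceMatrix:
    """All-pairs k-mer distances for ``(id, species, sequence)`` records."""
    if len(consensi) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [c[0] for c in consensi]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    consensi = [consensi[i] for i in order]
    ids = [c[0] for c in consensi]
    species = {cid: sp for cid, sp, _ in consensi}
    ksets = [kmer_set(seq, k) for _, _, seq in consensi]
    for cid, ks in zip(ids, ksets):
        if not ks:
            raise ValueError(f"{cid}: shorter than k or no valid k-mers")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = ksets[i] | ksets[j]
            sim = len(ksets[i] & ksets[j]) / len(union) if union else 0.0
            d[i, j] = d[j, i] = 1.0 - sim
    return KmerDistanceMatrix(ids=ids, species=species, values=d, k=k)


@dataclass
class OrthologCluster:
    """A putatively orthologous set: at most one sequence per species."""

    locus: str
    members: list[str]
    species: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be non-empty")
        if len(self.species) != len(self.members):
            raise ValueError("cluster holds two sequences from one species")


def _nj_tree(matrix: KmerDistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from the distance matrix (dendropy backend)."""
    buf = _io.StringIO()
    buf.write("," + ",".join(matrix.ids) + "\n")
    for i, name in enumerate(matrix.ids):
        buf.write(name + "," + ",".join(f"{v:.10f}" for v in matrix.values[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    return pdm.nj_tree()


def cluster_orthologs(
    matrix: KmerDistanceMatrix, locus: str = "locus"
) -> list[OrthologCluster]:
    """Cut the NJ tree into the fewest species-unique clades.

    The NJ tree is rooted on its longest edge (paralog copies are the deepest
    split when between-copy distances dominate), then traversed top-down: a
    clade with at most one sequence per species becomes one cluster; a clade
    violating the constraint is split at its root and the children are
    visited.  Every sequence lands in exactly one cluster.
    """
    n = len(matrix.ids)
    if n == 1:
        cid = matrix.ids[0]
        return [OrthologCluster(locus, [cid], {matrix.species[cid]})]
    if n == 2:
        a, b = matrix.ids
        if matrix.species[a] != matrix.species[b]:
            return [OrthologCluster(locus, [a, b], {matrix.species[a], matrix.species[b]})]
        return [
            OrthologCluster(locus, [a], {matrix.species[a]}),
            OrthologCluster(locus, [b], {matrix.species[b]}),
        ]
    all_species = [matrix.species[i] for i in matrix.ids]
    if len(set(all_species)) == len(all_species):
        return [OrthologCluster(locus, sorted(matrix.ids), set(all_species))]
    tree = _nj_tree(matrix)
    # adjacency view of the unrooted NJ tree; leaves keep their sequence ids
    adj: dict[int, list[tuple[int, float]]] = {}
    label_of: dict[int, str] = {}
    ids_of: dict[int, int] = {}
    counter = 0

    def nid(node: dendropy.Node) -> int:
        nonlocal counter
        if id(node) not in ids_of:
            ids_of[id(node)] = counter
            if node.is_leaf():
                label_of[counter] = node.taxon.label
            counter += 1
        return ids_of[id(node)]

    for node in tree.preorder_node_iter():
        u = nid(node)
        adj.setdefault(u, [])
        for child in node.child_nodes():
            v = nid(child)
            adj.setdefault(v, [])
            w = child.edge.length or 0.0
            adj[u].append((v, w))
            adj[v].append((u, w))

    leafset_memo: dict[tuple[int, int], list[str]] = {}

    def leafset(node: int, parent: int) -> list[str]:
        key = (node, parent)
        if key not in leafset_memo:
            kids = [x for x, _w in adj[node] if x != parent]
            if not kids:
                out = [label_of[node]]
            else:
                out = [l for c in kids for l in leafset(c, node)]
            leafset_memo[key] = out
        return leafset_memo[key]

    def decompose(node: int, parent: int) -> list[list[str]]:
        leaves = leafset(node, parent)
        specs = [matrix.species[l] for l in leaves]
        if len(set(specs)) == len(specs):
            return [leaves]
        return [
            grp
            for c, _w in adj[node]
            if c != parent
            for grp in decompose(c, node)
        ]

    # the NJ tree is unrooted: choose the rooting edge that decomposes it
    # into the fewest species-unique clades (ties: longest edge, then first
    # in a deterministic edge order)
    best: tuple[int, float, list[list[str]]] | None = None
    edges = sorted(
        (u, v, w) for u in adj for v, w in adj[u] if u < v
    )
    for u, v, w in edges:
        groups = decompose(u, v) + decompose(v, u)
        cand = (len(groups), -w, groups)
        if best is None or cand[:2] < best[:2]:
            best = cand
    clusters = [
        OrthologCluster(locus, sorted(g), {matrix.species[l] for l in g})
        for g in best[2]
    ]
    clusters.sort(key=lambda c: c.members[0])
    return clusters


def filter_clusters_by_occupancy(
    clusters: list[OrthologCluster],
    min_taxa: float,
    n_species_universe: int | None = None,
) -> list[OrthologCluster]:
    """Keep clusters covering at least ``min_taxa`` species.

    ``min_taxa`` may be an absolute count, or a fraction in (0, 1] of the
    species universe (``n_species_universe`` then required).  A cluster with
    129 species is dropped at min_taxa=130; one with 130 is kept.
    """
    if 0 < min_taxa <= 1 and isinstance(min_taxa, float):
        if n_species_universe is None:
            raise ValueError("fractional min_taxa needs n_species_universe")
        threshold = min_taxa * n_species_universe
    else:
        threshold = min_taxa
    return [c for c in clusters if len(c.species) >= threshold]
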