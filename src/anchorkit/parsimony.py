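"""Fitch parsimony machinery for morphological matrices.

Implements unordered-state (Fitch) tree length with missing data, replicated
heuristic search with random-addition starting trees and SPR branch swapping,
tree-island accounting (an island is a maximal connected set of equally
parsimonious trees under single swap moves), strict consensus, exhaustive
search as an oracle for small taxon counts, and exact mapping of unambiguous
character changes onto branches.

Internally unrooted binary trees are adjacency maps: leaves are integers
``0..n-1`` in matrix taxon order, internal nodes ``n..``.  Tree length and
change mapping use the unit-cost Sankoff recursion, which equals Fitch length
on binary trees and stays exact on polytomies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .sim import MorphMatrix

INF = 10**6


# ---------------------------------------------------------------------------
# matrix handling


def read_nexus_morph(path: str | Path) -> MorphMatrix:
    """Read a NEXUS DATA/CHARACTERS block of standard (discrete) characters."""
    cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    taxa, rows = [], []
    max_state = 1
    for taxon in cm:
        taxa.append(taxon.label)
        row = []
        for cell in cm[taxon]:
            sym = cell.symbol
            if sym in ("?", "-"):
                row.append(-1)
            else:
                row.append(int(sym))
                max_state = max(max_state, int(sym))
        rows.append(row)
    return MorphMatrix(taxa=taxa, states=np.array(rows), n_states=max_state + 1)


def _encode(matrix: MorphMatrix) -> np.ndarray:
    """Bitmask per cell: observed state bit, or all bits for missing."""
    k = matrix.n_states
    full = (1 << k) - 1
    masks = np.where(matrix.states < 0, full, 1 << np.maximum(matrix.states, 0))
    return masks.astype(np.int64)


# ---------------------------------------------------------------------------
# adjacency-tree utilities

Adj = dict[int, list[int]]


def _copy(adj: Adj) -> Adj:
    return {u: list(vs) for u, vs in adj.items()}


def _edges(adj: Adj) -> list[tuple[int, int]]:
    return sorted((u, v) for u in adj for v in adj[u] if u < v)


def canonical_key(adj: Adj) -> str:
    """Rooted-at-smallest-leaf canonical string; equal iff same unrooted topology."""
    root_leaf = min(u for u in adj if len(adj[u]) <= 1)
    if len(adj) == 1:
        return f"L{root_leaf}"

    def rec(node: int, parent: int) -> str:
        kids = [x for x in adj[node] if x != parent]
        if not kids:
            return f"L{node}"
        return "(" + ",".join(sorted(rec(c, node) for c in kids)) + ")"

    return f"L{root_leaf}|" + rec(adj[root_leaf][0], root_leaf)


def _postorder(adj: Adj, root_leaf: int) -> list[tuple[int, int]]:
    """(node, parent) pairs, children before parents, starting below ``root_leaf``."""
    if len(adj) == 1:
        return []
    start = adj[root_leaf][0]
    out: list[tuple[int, int]] = []
    stack = [(start, root_leaf)]
    while stack:
        node, parent = stack.pop()
        out.append((node, parent))
        for x in adj[node]:
            if x != parent:
                stack.append((x, node))
    out.reverse()
    return out


def adj_to_newick(adj: Adj, taxa: list[str]) -> str:
    if len(adj) == 1:
        return f"{taxa[min(adj)]};"
    root_leaf = min(u for u in adj if len(adj[u]) == 1)

    def rec(node: int, parent: int) -> str:
        kids = [x for x in adj[node] if x != parent]
        if not kids:
            return taxa[node]
        return "(" + ",".join(rec(c, node) for c in kids) + ")"

    inner = rec(adj[root_leaf][0], root_leaf)
    if inner.startswith("("):
        inner = inner[1:-1]
    return f"({taxa[root_leaf]},{inner});"


def _tree_to_adj(tree: dendropy.Tree, taxa: list[str]) -> Adj:
    """Convert a dendropy tree to an unrooted adjacency map on matrix indices."""
    idx = {t: i for i, t in enumerate(taxa)}
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaf_labels != set(taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    adj: Adj = {}
    next_internal = len(taxa)
    node_id: dict[int, int] = {}

    def get_id(node: dendropy.Node) -> int:
        nonlocal next_internal
        key = id(node)
        if key not in node_id:
            if node.is_leaf():
                node_id[key] = idx[node.taxon.label]
            else:
                node_id[key] = next_internal
                next_internal += 1
        return node_id[key]

    for node in tree.preorder_node_iter():
        u = get_id(node)
        adj.setdefault(u, [])
        for child in node.child_nodes():
            v = get_id(child)
            adj.setdefault(v, [])
            adj[u].append(v)
            adj[v].append(u)
    # suppress degree-2 nodes (e.g. a rooted tree's root) to unroot
    for u in [u for u, vs in adj.items() if len(vs) == 2]:
        a, b = adj.pop(u)
        adj[a] = [x if x != u else b for x in adj[a]]
        adj[b] = [x if x != u else a for x in adj[b]]
    return adj


# ---------------------------------------------------------------------------
# tree length


def _m_of(cost: np.ndarray) -> np.ndarray:
    """min_t(cost(t) + [s != t]) for every s: pay one change unless staying."""
    return np.minimum(cost, cost.min(axis=0)[None, :] + 1)


def _leaf_cost(u: int, masks: np.ndarray, state_bits: np.ndarray) -> np.ndarray:
    allowed = (masks[u][None, :] & state_bits[:, None]) != 0
    return np.where(allowed, 0, INF).astype(np.int64)


def _length_masks(adj: Adj, masks: np.ndarray, per_char: bool = False):
    """Unit-cost Sankoff length summed over characters (exact Fitch length)."""
    n_chars = masks.shape[1]
    k = int(masks.max()).bit_length()
    state_bits = 1 << np.arange(k, dtype=np.int64)
    if len(adj) <= 1:
        z = np.zeros(n_chars, dtype=np.int64)
        return z if per_char else 0
    root_leaf = min(u for u in adj if len(adj[u]) == 1)
    cost: dict[int, np.ndarray] = {}
    for node, parent in _postorder(adj, root_leaf):
        kids = [x for x in adj[node] if x != parent]
        if not kids:
            cost[node] = _leaf_cost(node, masks, state_bits)
            continue
        total = np.zeros((k, n_chars), dtype=np.int64)
        for c in kids:
            total += _m_of(cost[c])
        cost[node] = total
    top = adj[root_leaf][0]
    final = cost[top] + _m_of(_leaf_cost(root_leaf, masks, state_bits))
    lengths = final.min(axis=0)
    return lengths if per_char else int(lengths.sum())


def fitch_length(tree: str | Path | dendropy.Tree | Adj, matrix: MorphMatrix) -> int:
    """Minimum unordered state changes of ``matrix`` on ``tree``.

    Missing cells ('?') may take any state.  Invariant and all-missing
    characters contribute zero.  The value is invariant under re-rooting.
    """
    masks = _encode(matrix)
    if isinstance(tree, dict):
        adj = tree
    else:
        from .treestats import load_tree

        adj = _tree_to_adj(load_tree(tree), matrix.taxa)
    return _length_masks(adj, masks)


# ---------------------------------------------------------------------------
# topology generation and rearrangement


def _insert_on_edge(adj: Adj, u: int, v: int, leaf: int, internal: int) -> Adj:
    new = _copy(adj)
    new[u] = [x if x != v else internal for x in new[u]]
    new[v] = [x if x != u else internal for x in new[v]]
    new[internal] = [u, v, leaf]
    new[leaf] = [internal]
    return new


def all_topologies(n_taxa: int):
    """Yield every unrooted binary topology on ``n_taxa`` leaves ((2n-5)!! trees)."""
    if n_taxa > 9:
        raise ValueError("exhaustive enumeration capped at 9 taxa")
    if n_taxa == 1:
        yield {0: []}
        return
    if n_taxa == 2:
        yield {0: [1], 1: [0]}
        return
    base: Adj = {0: [n_taxa], 1: [n_taxa], 2: [n_taxa], n_taxa: [0, 1, 2]}

    def grow(adj: Adj, next_leaf: int, next_internal: int):
        if next_leaf == n_taxa:
            yield adj
            return
        for u, v in _edges(adj):
            yield from grow(
                _insert_on_edge(adj, u, v, next_leaf, next_internal),
                next_leaf + 1,
                next_internal + 1,
            )

    yield from grow(base, 3, n_taxa + 1)


def spr_neighbors(adj: Adj, n_leaves: int | None = None) -> dict[str, Adj]:
    """All distinct topologies one subtree-prune-regraft move away."""
    out: dict[str, Adj] = {}
    self_key = canonical_key(adj)
    for u in sorted(adj):
        if len(adj[u]) != 3:
            continue
        for v in sorted(adj[u]):  # prune the subtree on the v side of edge (u, v)
            a, b = [x for x in adj[u] if x != v]
            rem = _copy(adj)
            del rem[u]
            rem[a] = [x if x != u else b for x in rem[a]]
            rem[b] = [x if x != u else a for x in rem[b]]
            # restrict regrafting to the component that does not hold the
            # pruned subtree
            comp = {a}
            stack = [a]
            while stack:
                x = stack.pop()
                for y in rem.get(x, ()):
                    if y not in comp and y != v:
                        comp.add(y)
                        stack.append(y)
            for x, y in sorted((p, q) for p in comp for q in rem[p] if p < q and q in comp):
                if {x, y} == {a, b}:
                    continue
                new = _copy(rem)
                new[x] = [z if z != y else u for z in new[x]]
                new[y] = [z if z != x else u for z in new[y]]
                new[u] = [x, y, v]
                key = canonical_key(new)
                if key != self_key:
                    out.setdefault(key, new)
    return out


def nni_neighbors(adj: Adj, n_leaves: int | None = None) -> dict[str, Adj]:
    """The two nearest-neighbor interchanges per internal edge."""
    out: dict[str, Adj] = {}
    self_key = canonical_key(adj)
    for u, v in _edges(adj):
        if len(adj[u]) != 3 or len(adj[v]) != 3:
            continue
        x1, _x2 = [x for x in adj[u] if x != v]
        for y in [y for y in adj[v] if y != u]:
            new = _copy(adj)
            x = x1
            new[u] = [z if z != x else y for z in new[u]]
            new[v] = [z if z != y else x for z in new[v]]
            new[x] = [z if z != u else v for z in new[x]]
            new[y] = [z if z != v else u for z in new[y]]
            key = canonical_key(new)
            if key != self_key:
                out.setdefault(key, new)
    return out


# ---------------------------------------------------------------------------
# searches


@dataclass
class TreeIsland:
    """A maximal connected set of equally parsimonious trees."""

    island_id: int
    trees: list[str]  # newick
    length: int
    hits: int  # replicates that settled on this island


@dataclass
class SearchResult:
    best_length: int
    islands: list[TreeIsland]
    n_replicates: int

    @property
    def mpts(self) -> list[str]:
        return [t for isl in self.islands for t in isl.trees]


def _random_addition_tree(
    masks: np.ndarray, order: list[int], next_internal: int
) -> Adj:
    adj: Adj = {
        order[0]: [next_internal],
        order[1]: [next_internal],
        order[2]: [next_internal],
        next_internal: [order[0], order[1], order[2]],
    }
    next_internal += 1
    for leaf in order[3:]:
        best = None
        for u, v in _edges(adj):
            cand = _insert_on_edge(adj, u, v, leaf, next_internal)
            L = _length_masks(cand, masks)
            if best is None or L < best[0]:
                best = (L, cand)
        adj = best[1]
        next_internal += 1
    return adj


def _descend(adj: Adj, masks: np.ndarray, neighbor_fn) -> tuple[Adj, int]:
    """Steepest-descent branch swapping to a local optimum (ties by key)."""
    cur, cur_len = adj, _length_masks(adj, masks)
    while True:
        best = None  # (length, key, adj)
        for key, nb in sorted(neighbor_fn(cur).items()):
            L = _length_masks(nb, masks)
            if best is None or (L, key) < best[:2]:
                best = (L, key, nb)
        if best is None or best[0] >= cur_len:
            return cur, cur_len
        cur, cur_len = best[2], best[0]


def _island_closure(
    adj: Adj, length: int, masks: np.ndarray, neighbor_fn, max_trees: int
) -> dict[str, Adj]:
    """BFS over equally parsimonious single-swap moves; bounded by max_trees."""
    seen = {canonical_key(adj): adj}
    frontier = [adj]
    while frontier and len(seen) < max_trees:
        cur = frontier.pop()
        for key, nb in sorted(neighbor_fn(cur).items()):
            if key in seen:
                continue
            if _length_masks(nb, masks) == length:
                seen[key] = nb
                frontier.append(nb)
                if len(seen) >= max_trees:
                    break
    return seen


def heuristic_search(
    matrix: MorphMatrix,
    n_reps: int = 1000,
    seed: int = 0,
    swap: str = "spr",
    max_trees: int = 2000,
) -> SearchResult:
    """Replicated heuristic parsimony search with island accounting.

    Each replicate builds a random-addition starting tree, branch-swaps (SPR
    by default, NNI optional) to a local optimum, then collects the full set
    of equally parsimonious trees connected to it by single swap moves.  Each
    such maximal connected set is one tree island; the replicate hit count
    records how often the search settled on each island.  Only islands at the
    globally best length are returned.  Deterministic given ``seed``.
    """
    n = len(matrix.taxa)
    masks = _encode(matrix)
    neighbor_fn = {"spr": spr_neighbors, "nni": nni_neighbors}[swap]
    if n < 4:
        adj = next(all_topologies(n))
        length = _length_masks(adj, masks)
        isl = TreeIsland(0, [adj_to_newick(adj, matrix.taxa)], length, n_reps)
        return SearchResult(length, [isl], n_reps)
    rng = np.random.default_rng(seed)
    islands: list[dict] = []
    key_to_island: dict[str, int] = {}
    for _rep in range(n_reps):
        order = [int(x) for x in rng.permutation(n)]
        start = _random_addition_tree(masks, order, n)
        opt, opt_len = _descend(start, masks, neighbor_fn)
        opt_key = canonical_key(opt)
        if opt_key in key_to_island:
            islands[key_to_island[opt_key]]["hits"] += 1
            continue
        closure = _island_closure(opt, opt_len, masks, neighbor_fn, max_trees)
        joined = next((key_to_island[key] for key in closure if key in key_to_island), None)
        if joined is not None:
            islands[joined]["hits"] += 1
            for key, a in closure.items():
                if key not in key_to_island:
                    key_to_island[key] = joined
                    islands[joined]["adjs"][key] = a
            continue
        idx = len(islands)
        islands.append({"adjs": dict(closure), "length": opt_len, "hits": 1})
        for key in closure:
            key_to_island[key] = idx
    best = min(isl["length"] for isl in islands)
    out = []
    for isl in sorted(
        (i for i in islands if i["length"] == best), key=lambda i: -i["hits"]
    ):
        trees = [adj_to_newick(a, matrix.taxa) for _key, a in sorted(isl["adjs"].items())]
        out.append(TreeIsland(len(out), trees, best, isl["hits"]))
    return SearchResult(best, out, n_reps)


def exhaustive_search(matrix: MorphMatrix) -> tuple[int, list[str]]:
    """All most-parsimonious trees by complete enumeration (<= 9 taxa)."""
    n = len(matrix.taxa)
    if n > 9:
        raise ValueError("exhaustive search refuses more than 9 taxa")
    masks = _encode(matrix)
    best_len: int | None = None
    best: list[str] = []
    for adj in all_topologies(n):
        L = _length_masks(adj, masks)
        if best_len is None or L < best_len:
            best_len, best = L, [adj_to_newick(adj, matrix.taxa)]
        elif L == best_len:
            best.append(adj_to_newick(adj, matrix.taxa))
    return int(best_len), best


# ---------------------------------------------------------------------------
# consensus


def strict_consensus(trees: list) -> dendropy.Tree:
    """Tree containing exactly the bipartitions common to every input tree."""
    from .treestats import bipartitions, load_tree

    parsed = [load_tree(t) for t in trees]
    leaf_sets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in parsed]
    if len(set(leaf_sets)) != 1:
        raise ValueError("trees have different leaf sets")
    leaves = sorted(leaf_sets[0])
    common = set.intersection(*(bipartitions(t) for t in parsed))

    def build(members: list[str], splits: list[frozenset[str]]) -> str:
        maximal = [s for s in splits if not any(s < t for t in splits if t != s)]
        used: set[str] = set().union(*maximal) if maximal else set()
        parts = [
            build(sorted(s), [t for t in splits if t < s])
            for s in sorted(maximal, key=sorted)
        ]
        parts += [m for m in members if m not in used]
        return "(" + ",".join(parts) + ")"

    newick = build(leaves, sorted(common, key=sorted)) + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


# ---------------------------------------------------------------------------
# character-change mapping


@dataclass
class ChangeMap:
    """Unambiguous character changes per branch.

    Branches are keyed by the frozenset of taxa on their far side (away from
    the first matrix taxon).  Tokens follow the ``<character>:<state>``
    convention with characters numbered from 1; a change whose derived state
    differs among reconstructions carries no token but is still counted.
    """

    branch_tokens: dict[frozenset[str], list[str]]
    branch_changes: dict[frozenset[str], int]
    homoplasious: set[int] = field(default_factory=set)
    taxa: list[str] = field(default_factory=list)

    def supporting_characters(self, clade: set[str]) -> list[str]:
        clade = frozenset(clade)
        other = frozenset(self.taxa) - clade
        return self.branch_tokens.get(clade, self.branch_tokens.get(other, []))

    @property
    def total_unambiguous_changes(self) -> int:
        return sum(self.branch_changes.values())


def map_character_changes(
    tree: str | Path | dendropy.Tree | Adj, matrix: MorphMatrix
) -> ChangeMap:
    """Exact per-branch unambiguous changes via unit-cost Sankoff up/down passes.

    A branch carries a change for a character only when every most-
    parsimonious reconstruction places a change on it: the minimum tree
    length with both branch endpoints forced to the same state exceeds the
    character's unconstrained length.  The derived-state token is emitted
    when the child's state is identical across all reconstructions.
    """
    masks = _encode(matrix)
    if isinstance(tree, dict):
        adj = tree
    else:
        from .treestats import load_tree

        adj = _tree_to_adj(load_tree(tree), matrix.taxa)
    if len(adj) <= 2:
        return ChangeMap({}, {}, set(), list(matrix.taxa))
    n_chars = masks.shape[1]
    k = matrix.n_states
    state_bits = 1 << np.arange(k, dtype=np.int64)
    root_leaf = min(u for u in adj if len(adj[u]) == 1)
    post = _postorder(adj, root_leaf)
    parent_of = {node: parent for node, parent in post}
    parent_of[root_leaf] = None

    down: dict[int, np.ndarray] = {}
    for node, parent in post:
        kids = [x for x in adj[node] if x != parent]
        if not kids:
            down[node] = _leaf_cost(node, masks, state_bits)
            continue
        total = np.zeros((k, n_chars), dtype=np.int64)
        for c in kids:
            total += _m_of(down[c])
        down[node] = total
    top = adj[root_leaf][0]
    rl_cost = _leaf_cost(root_leaf, masks, state_bits)
    char_len = (down[top] + _m_of(rl_cost)).min(axis=0)

    # araw[v](s): min cost of everything outside subtree(v), with v's parent
    # forced to state s; out[v] additionally pays for the (parent, v) edge.
    araw: dict[int, np.ndarray] = {top: rl_cost}
    out: dict[int, np.ndarray] = {top: _m_of(rl_cost)}
    for node, parent in reversed(post):  # preorder: parents before children
        if node == top:
            continue
        a = out[parent].copy()
        for sib in adj[parent]:
            if sib in (node, parent_of[parent]):
                continue
            a += _m_of(down[sib])
        araw[node] = a
        out[node] = _m_of(a)

    n_obs = np.array(
        [len({s for s in matrix.states[:, c] if s >= 0}) for c in range(n_chars)]
    )
    homoplasious = {
        c + 1 for c in range(n_chars) if char_len[c] > max(int(n_obs[c]) - 1, 0)
    }

    def clade_of(node: int, parent: int) -> frozenset[str]:
        found = set()
        stack = [(node, parent)]
        while stack:
            x, p = stack.pop()
            if len(adj[x]) == 1:
                found.add(matrix.taxa[x])
            for y in adj[x]:
                if y != p:
                    stack.append((y, x))
        return frozenset(found)

    all_taxa = frozenset(matrix.taxa)
    branch_tokens: dict[frozenset[str], list[str]] = {}
    branch_changes: dict[frozenset[str], int] = {}
    for node, parent in post:
        no_change = (araw[node] + down[node]).min(axis=0)
        near = out[node] + down[node]  # MPR scores of the node-side endpoint
        far = araw[node] + _m_of(down[node])  # ... of the parent-side endpoint
        changed = no_change > char_len
        if not changed.any():
            continue
        clade = clade_of(node, parent)
        # an unrooted branch reads in both directions: the derived state on
        # each side is that side's endpoint state, when unique over all MPRs
        tokens_near, tokens_far = [], []
        n_changes = 0
        for c in np.nonzero(changed)[0]:
            n_changes += 1
            s_near = np.nonzero(near[:, c] == char_len[c])[0]
            s_far = np.nonzero(far[:, c] == char_len[c])[0]
            if s_near.size == 1:
                tokens_near.append(f"{c + 1}:{int(s_near[0])}")
            if s_far.size == 1:
                tokens_far.append(f"{c + 1}:{int(s_far[0])}")
        branch_tokens[clade] = tokens_near
        branch_tokens[all_taxa - clade] = tokens_far
        branch_changes[clade] = n_changes
    return ChangeMap(branch_tokens, branch_changes, homoplasious, list(matrix.taxa))
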