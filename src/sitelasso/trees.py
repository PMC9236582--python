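"""Unrooted phylogenetic trees: Newick I/O, random and parsimony stepwise
addition, branch-length sampling and SPR neighborhood enumeration.

Trees are stored as an undirected adjacency structure with non-negative branch
lengths. Likelihood code roots them virtually at an arbitrary internal node;
all likelihood values are required (and tested) to be invariant to that choice
(the pulley principle for reversible models).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import ValidationError
from .msa_io import ambiguity_map, states_for


class PhyloTree:
    """An unrooted tree over named leaves.

    ``adj[u][v]`` is the length of edge (u, v); ``names`` maps leaf ids to
    taxon names. Internal nodes of a binary unrooted tree have degree 3
    (degree-2 nodes are never created except transiently).
    """

    __slots__ = ("adj", "names", "_next_id", "parsimony_score", "bl_converged")

    def __init__(self, adj=None, names=None):
        self.adj: dict[int, dict[int, float]] = adj if adj is not None else {}
        self.names: dict[int, str] = names if names is not None else {}
        self._next_id = max(self.adj, default=-1) + 1
        self.parsimony_score = None
        self.bl_converged = True

    # -- basic structure -------------------------------------------------
    def new_node(self) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = {}
        return nid

    def add_edge(self, u: int, v: int, length: float = 0.0) -> None:
        self.adj.setdefault(u, {})[v] = length
        self.adj.setdefault(v, {})[u] = length
        self._next_id = max(self._next_id, u + 1, v + 1)

    def remove_edge(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def set_length(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def length(self, u: int, v: int) -> float:
        return self.adj[u][v]

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    def is_leaf(self, v: int) -> bool:
        return len(self.adj[v]) == 1

    @property
    def leaves(self) -> list[int]:
        return sorted(v for v in self.adj if self.is_leaf(v))

    @property
    def taxa(self) -> list[str]:
        return sorted(self.names[v] for v in self.leaves)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def edges(self) -> list[tuple[int, int]]:
        """All edges as (u, v) with u < v, sorted for determinism."""
        return sorted((u, v) for u in self.adj for v in self.adj[u] if u < v)

    def total_length(self) -> float:
        return sum(l for u, v, l in self.iter_edges())

    def iter_edges(self):
        for u, v in self.edges():
            yield u, v, self.adj[u][v]

    def copy(self) -> "PhyloTree":
        t = PhyloTree({u: dict(nbrs) for u, nbrs in self.adj.items()}, dict(self.names))
        t._next_id = self._next_id
        return t

    def leaf_by_name(self, name: str) -> int:
        for v, nm in self.names.items():
            if nm == name:
                return v
        raise KeyError(name)

    # -- traversal -------------------------------------------------------
    def rooted_view(self, root: int | None = None):
        """Root the tree at ``root`` (default: a deterministic internal node).

        Returns (root, parent, children, postorder) where ``postorder`` lists
        every node with children before parents.
        """
        if root is None:
            internals = sorted(v for v in self.adj if not self.is_leaf(v))
            root = internals[0] if internals else min(self.adj)
        parent: dict[int, int | None] = {root: None}
        children: dict[int, list[int]] = {v: [] for v in self.adj}
        order = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            for w in sorted(self.adj[v]):
                if w != parent[v]:
                    parent[w] = v
                    children[v].append(w)
                    stack.append(w)
        return root, parent, children, order[::-1]

    def subtree_nodes(self, v: int, avoid: int) -> set[int]:
        """Nodes on ``v``'s side of the edge (avoid, v)."""
        seen = {v}
        stack = [v]
        while stack:
            x = stack.pop()
            for y in self.adj[x]:
                if y != avoid and y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    def validate(self) -> None:
        degs = {self.degree(v) for v in self.adj if v not in self.names}
        if self.n_leaves >= 3 and degs - {3}:
            raise ValidationError(f"internal nodes must have degree 3, got degrees {degs}")
        if set(self.names) != set(self.leaves):
            raise ValidationError("leaf ids and name map disagree")

    def __repr__(self):
        return f"PhyloTree(n_leaves={self.n_leaves}, n_edges={len(self.edges())})"


# -- Newick I/O (dendropy-backed parsing) --------------------------------

def to_newick(tree: PhyloTree, precision: int = 17) -> str:
    """Serialize with branch lengths at full float precision (>= 10
    significant digits; 17 makes the round trip exact)."""
    root, _, children, _ = tree.rooted_view()

    def fmt(v, parent):
        if tree.is_leaf(v) and v != root:
            core = tree.names[v]
        else:
            kids = [w for w in sorted(tree.adj[v]) if w != parent]
            core = "(" + ",".join(fmt(w, v) for w in kids) + ")"
        if parent is None:
            return core
        return f"{core}:{tree.adj[v][parent]:.{precision}g}"

    return fmt(root, None) + ";"


def from_newick(newick: str) -> PhyloTree:
    """Parse a Newick string (missing branch lengths become 0)."""
    dtree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree = PhyloTree()
    ids: dict = {}
    for nd in dtree.preorder_node_iter():
        ids[nd] = tree.new_node()
        if nd.taxon is not None:
            tree.names[ids[nd]] = nd.taxon.label
        if nd.parent_node is not None:
            bl = nd.edge.length if nd.edge.length is not None else 0.0
            tree.add_edge(ids[nd.parent_node], ids[nd], float(bl))
    # splice out degree-2 nodes (artificial roots from rooted Newick strings)
    for v in [v for v in list(tree.adj) if tree.degree(v) == 2 and v not in tree.names]:
        (a, la), (b, lb) = tree.adj[v].items()
        tree.remove_edge(v, a)
        tree.remove_edge(v, b)
        del tree.adj[v]
        tree.add_edge(a, b, la + lb)
    tree.validate()
    return tree


def read_trees(path) -> list[PhyloTree]:
    """Read a multi-tree file, one Newick per line."""
    with open(path) as fh:
        return [from_newick(line) for line in fh if line.strip()]


def write_trees(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(to_newick(t) + "\n")


# -- topology comparison -------------------------------------------------

def _splits(tree: PhyloTree) -> frozenset:
    order = {name: i for i, name in enumerate(tree.taxa)}
    full = (1 << len(order)) - 1
    out = set()
    for u, v in tree.edges():
        if tree.is_leaf(u) or tree.is_leaf(v):
            continue
        mask = 0
        for x in tree.subtree_nodes(v, u):
            if tree.is_leaf(x):
                mask |= 1 << order[tree.names[x]]
        out.add(min(mask, full ^ mask))
    return frozenset(out)


def topology_key(tree: PhyloTree) -> frozenset:
    """Hashable label-aware topology identifier (set of non-trivial splits)."""
    return _splits(tree)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: number of non-trivial splits unique to one tree."""
    if t1.taxa != t2.taxa:
        raise ValidationError("trees are over different taxon sets")
    return len(_splits(t1) ^ _splits(t2))


# -- tree generation -----------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_stepwise_topology(taxa, rng_seed) -> PhyloTree:
    """Random topology by sequential stepwise addition.

    Taxa are inserted in a uniformly shuffled order, each onto a uniformly
    chosen existing edge; all branch lengths are left at 0.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValidationError("need at least 3 taxa")
    rng = _as_rng(rng_seed)
    order = list(rng.permutation(len(taxa)))
    tree = PhyloTree()
    hub = tree.new_node()
    for i in order[:3]:
        leaf = tree.new_node()
        tree.names[leaf] = taxa[i]
        tree.add_edge(hub, leaf, 0.0)
    for i in order[3:]:
        edges = tree.edges()
        u, v = edges[rng.integers(len(edges))]
        _attach_leaf(tree, taxa[i], u, v)
    tree.validate()
    return tree


def _attach_leaf(tree: PhyloTree, name: str, u: int, v: int, half: bool = False):
    """Split edge (u, v) with a new node and hang a new leaf from it."""
    length = tree.adj[u][v]
    tree.remove_edge(u, v)
    mid = tree.new_node()
    if half:
        tree.add_edge(u, mid, length / 2)
        tree.add_edge(mid, v, length / 2)
    else:
        tree.add_edge(u, mid, length)
        tree.add_edge(mid, v, 0.0)
    leaf = tree.new_node()
    tree.names[leaf] = name
    tree.add_edge(mid, leaf, 0.0)
    return mid, leaf


def draw_branch_lengths(tree: PhyloTree, mean: float = 0.1, rng_seed=None) -> PhyloTree:
    """New tree with i.i.d. exponential branch lengths (default mean 0.1)."""
    if mean <= 0:
        raise ValidationError("exponential mean must be > 0")
    rng = _as_rng(rng_seed)
    out = tree.copy()
    for u, v in out.edges():
        out.set_length(u, v, float(rng.exponential(mean)))
    return out


def random_tree(taxa, rng_seed, bl_mean: float = 0.1) -> PhyloTree:
    """Random stepwise topology with exponential branch lengths, one seed."""
    rng = _as_rng(rng_seed)
    return draw_branch_lengths(random_stepwise_topology(taxa, rng), bl_mean, rng)


# -- Fitch parsimony -----------------------------------------------------

def _tip_state_sets(aln):
    """(n_taxa, p, n_states) boolean state sets over compressed patterns."""
    from .msa_io import compress_patterns

    pat = compress_patterns(aln)
    states = states_for(aln.alphabet)
    amb = ambiguity_map(aln.alphabet)
    lut = {ch: np.array([s in compat for s in states]) for ch, compat in amb.items()}
    sets = np.zeros((aln.n_taxa, pat.n_patterns, len(states)), dtype=bool)
    for i in range(aln.n_taxa):
        for j in range(pat.n_patterns):
            sets[i, j] = lut[pat.patterns[i, j]]
    return sets, pat.pattern_weights


def fitch_score(tree: PhyloTree, aln, _cache=None) -> float:
    """Weighted Fitch parsimony score of a tree on an alignment."""
    if _cache is None:
        sets, weights = _tip_state_sets(aln)
    else:
        sets, weights = _cache
    name_to_row = {t: i for i, t in enumerate(aln.taxa)}
    # root on an edge so every traversal node is binary: pick the first edge
    u0, v0 = tree.edges()[0]
    cost = np.zeros(len(weights))

    def down(v, parent):
        if tree.is_leaf(v):
            return sets[name_to_row[tree.names[v]]]
        acc = None
        for w in sorted(tree.adj[v]):
            if w == parent:
                continue
            child = down(w, v)
            if acc is None:
                acc = child
            else:
                inter = acc & child
                empty = ~inter.any(axis=1)
                cost[empty] += weights[empty]
                acc = np.where(empty[:, None], acc | child, inter)
        return acc

    left = down(u0, v0)
    right = down(v0, u0)
    inter = left & right
    empty = ~inter.any(axis=1)
    cost[empty] += weights[empty]
    return float(cost.sum())


def parsimony_stepwise_tree(aln, rng_seed) -> PhyloTree:
    """Stepwise-addition tree under the Fitch parsimony criterion.

    Taxa are added in a random order; each is attached to the edge that
    minimizes the Fitch score of the grown tree (ties broken by edge order).
    The final score is stored on ``tree.parsimony_score``.
    """
    if aln.n_taxa < 3:
        raise ValidationError("need at least 3 taxa")
    rng = _as_rng(rng_seed)
    cache = _tip_state_sets(aln)
    order = [aln.taxa[i] for i in rng.permutation(aln.n_taxa)]
    tree = PhyloTree()
    hub = tree.new_node()
    for name in order[:3]:
        leaf = tree.new_node()
        tree.names[leaf] = name
        tree.add_edge(hub, leaf, 0.0)
    for name in order[3:]:
        best = None
        for u, v in tree.edges():
            cand = tree.copy()
            _attach_leaf(cand, name, u, v)
            s = fitch_score(cand, aln, cache)
            if best is None or s < best[0]:
                best = (s, cand)
        tree = best[1]
        tree.parsimony_score = best[0]
    if tree.parsimony_score is None:  # exactly 3 taxa: single topology
        tree.parsimony_score = fitch_score(tree, aln, cache)
    tree.validate()
    return tree


# -- SPR -----------------------------------------------------------------

@dataclass(frozen=True)
class SprMove:
    """A subtree prune-and-regraft move.

    ``pruned_edge`` = (u, v): the subtree on the v side is detached (u is its
    attachment point, which dissolves). ``regraft_edge`` is split in half and
    the subtree rehung there. ``distance`` counts edges between the dissolved
    attachment point and the regraft edge (1 = NNI-equivalent move).
    """

    pruned_edge: tuple
    regraft_edge: tuple
    distance: int


def apply_spr(tree: PhyloTree, move: SprMove) -> PhyloTree:
    """Apply a lazy SPR move: the regraft edge is split in half, the pruned
    subtree keeps its branch length, and the two edges merged by pruning are
    summed — total tree length is unchanged."""
    u, v = move.pruned_edge
    out = tree.copy()
    a, b = (x for x in out.adj[u] if x != v)
    la, lb = out.adj[u][a], out.adj[u][b]
    lv = out.adj[u][v]
    for x in (a, b, v):
        out.remove_edge(u, x)
    del out.adj[u]
    out.add_edge(a, b, la + lb)
    x, y = move.regraft_edge
    lf = out.adj[x][y]
    out.remove_edge(x, y)
    mid = out.new_node()
    out.add_edge(x, mid, lf / 2)
    out.add_edge(mid, y, lf / 2)
    out.add_edge(mid, v, lv)
    return out


def spr_neighbors(tree: PhyloTree, max_distance: int | None = None):
    """Enumerate all distinct SPR neighbor topologies within a rearrangement
    radius.

    Returns a list of (SprMove, PhyloTree) pairs. Moves are enumerated with a
    deterministic preorder over pruned edges and breadth-first order over
    regraft edges; neighbors that reproduce an already-seen topology (or the
    input topology itself) are dropped.
    """
    if tree.n_leaves < 4:
        return []
    base = topology_key(tree)
    seen = {base}
    results = []
    root, parent, children, post = tree.rooted_view()
    preorder = post[::-1]
    directed = []
    for v in preorder:
        if parent[v] is not None:
            directed.append((parent[v], v))  # prune the subtree below v
            directed.append((v, parent[v]))  # prune the complement side
    for u, v in directed:
        if tree.degree(u) != 3:
            continue  # pruning at a leaf end does not define a move
        a, b = sorted(x for x in tree.adj[u] if x != v)
        pruned = tree.subtree_nodes(v, u)
        # BFS node distances in the remaining tree from the merged edge (a, b)
        dist = {a: 0, b: 0}
        queue = deque([a, b])
        while queue:
            x = queue.popleft()
            for y in sorted(tree.adj[x]):
                if y == u or y in pruned or y in dist:
                    continue
                dist[y] = dist[x] + 1
                queue.append(y)
        # regraft edges ordered by distance then node ids
        cands = []
        for x in dist:
            for y in sorted(tree.adj[x]):
                if y == u or y in pruned or {x, y} == {a, b}:
                    continue
                if (y, x) in [c[1] for c in cands]:
                    continue
                d = min(dist[x], dist.get(y, dist[x])) + 1
                if max_distance is None or d <= max_distance:
                    cands.append((d, (x, y)))
        cands.sort(key=lambda c: (c[0], c[1]))
        for d, (x, y) in cands:
            move = SprMove((u, v), (x, y), d)
            nb = apply_spr(tree, move)
            key = topology_key(nb)
            if key not in seen:
                seen.add(key)
                results.append((move, nb))
    return results
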