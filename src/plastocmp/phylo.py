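"""Maximum-parsimony phylogenetics on plastome alignments.

Characters are unordered nucleotide states weighted equally; gaps and N are
missing data.  Tree length is Fitch parsimony length; search is exact
enumeration (optionally branch-and-bound pruned) for small taxon sets and
random-addition + tree-bisection-reconnection (TBR) otherwise.  Consistency
and retention indices, nonparametric bootstrap and a neighbor-joining
cross-check on distance matrices complete the toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import TreeError

_STATE_BITS = {65: 1, 67: 2, 71: 4, 84: 8}  # A C G T
MISSING = 15

SITE_CONSTANT = 0
SITE_UNINFORMATIVE = 1
SITE_INFORMATIVE = 2


# ---------------------------------------------------------------------------
# Character matrix


@dataclass
class CharacterMatrix:
    """Taxa x sites state table compressed to site patterns.

    ``masks`` holds one 4-bit state set per taxon per unique pattern
    (A=1, C=2, G=4, T=8, missing=15); ``weights`` are pattern multiplicities.
    """

    taxa: list[str]
    masks: np.ndarray  # (n_taxa, n_patterns) uint8
    weights: np.ndarray  # (n_patterns,) int64
    pattern_class: np.ndarray  # (n_patterns,) int8
    n_columns: int

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def class_counts(self) -> dict[str, int]:
        out = {}
        for name, code in (
            ("constant", SITE_CONSTANT),
            ("variable_uninformative", SITE_UNINFORMATIVE),
            ("parsimony_informative", SITE_INFORMATIVE),
        ):
            out[name] = int(self.weights[self.pattern_class == code].sum())
        return out

    # per-pattern parsimony bounds -----------------------------------------
    def min_steps(self) -> np.ndarray:
        """Minimum steps per pattern on any tree: observed states - 1."""
        n_states = np.zeros(self.masks.shape[1], dtype=np.int64)
        for bit in (1, 2, 4, 8):
            obs = ((self.masks & bit) > 0) & (self.masks != MISSING)
            n_states += obs.any(axis=0)
        return np.maximum(n_states - 1, 0)

    def max_steps(self) -> np.ndarray:
        """Steps per pattern on a star tree: non-missing taxa minus the
        largest single-state class (missing taxa never change state)."""
        nonmissing = (self.masks != MISSING).sum(axis=0)
        best = np.zeros(self.masks.shape[1], dtype=np.int64)
        for bit in (1, 2, 4, 8):
            cnt = ((self.masks == bit)).sum(axis=0)
            best = np.maximum(best, cnt)
        out = nonmissing - best
        return np.where(nonmissing > 0, np.maximum(out, 0), 0)

    def resampled(self, rng: np.random.Generator) -> "CharacterMatrix":
        """Bootstrap pseudoreplicate: resample columns with replacement to
        the original length (multinomial over patterns)."""
        p = self.weights / self.weights.sum()
        w = rng.multinomial(self.n_columns, p)
        return CharacterMatrix(
            taxa=self.taxa,
            masks=self.masks,
            weights=w.astype(np.int64),
            pattern_class=self.pattern_class,
            n_columns=self.n_columns,
        )

    def subset_informative(self) -> "CharacterMatrix":
        keep = self.pattern_class == SITE_INFORMATIVE
        return CharacterMatrix(
            taxa=self.taxa,
            masks=self.masks[:, keep],
            weights=self.weights[keep],
            pattern_class=self.pattern_class[keep],
            n_columns=int(self.weights[keep].sum()),
        )


def build_character_matrix(source) -> CharacterMatrix:
    """Build a :class:`CharacterMatrix` from an AlignmentMatrix or a
    ``{taxon: aligned_row}`` mapping.  Gaps and N map to missing."""
    if hasattr(source, "ids") and hasattr(source, "rows"):
        taxa = list(source.ids)
        rows = [source.rows[t] for t in taxa]
    elif isinstance(source, dict):
        taxa = list(source)
        rows = [source[t] for t in taxa]
    else:
        raise TreeError(f"cannot build character matrix from {type(source)}")
    if len(taxa) < 3:
        raise TreeError("need at least 3 taxa")
    if len({len(r) for r in rows}) != 1:
        raise TreeError("rows differ in length")
    arr = np.vstack([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    codes = np.full(arr.shape, MISSING, dtype=np.uint8)
    for byte, bit in _STATE_BITS.items():
        codes[arr == byte] = bit
    # pattern compression
    patterns, inverse = np.unique(codes, axis=1, return_inverse=True)
    weights = np.bincount(inverse, minlength=patterns.shape[1]).astype(np.int64)
    pclass = _classify_patterns(patterns)
    return CharacterMatrix(
        taxa=taxa,
        masks=patterns,
        weights=weights,
        pattern_class=pclass,
        n_columns=arr.shape[1],
    )


def _classify_patterns(masks: np.ndarray) -> np.ndarray:
    P = masks.shape[1]
    counts = np.zeros((4, P), dtype=np.int64)
    for i, bit in enumerate((1, 2, 4, 8)):
        counts[i] = (masks == bit).sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    n_doubletons = (counts >= 2).sum(axis=0)
    out = np.full(P, SITE_UNINFORMATIVE, dtype=np.int8)
    out[n_states <= 1] = SITE_CONSTANT
    out[(n_states >= 2) & (n_doubletons >= 2)] = SITE_INFORMATIVE
    return out


# ---------------------------------------------------------------------------
# Trees

_BIP = frozenset


@dataclass
class Tree:
    """A (usually unrooted) binary tree carried as a Newick string, with
    optional per-bipartition bootstrap supports (percent)."""

    newick: str
    rooted: bool = False
    supports: dict[frozenset, float] = field(default_factory=dict)

    def _dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick,
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
            rooting="default-rooted" if self.rooted else "default-unrooted",
        )

    def leaves(self) -> list[str]:
        t = self._dendropy()
        return sorted(l.taxon.label for l in t.leaf_node_iter())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each encoded as the frozenset of leaf
        labels on one side (the side not containing the alphabetically first
        leaf, so complements collapse)."""
        adj, labels = _adjacency_from_newick(self.newick)
        return _bipartitions(adj, labels)

    def newick_with_supports(self) -> str:
        if not self.supports:
            return self.newick
        t = self._dendropy()
        all_leaves = frozenset(l.taxon.label for l in t.leaf_node_iter())
        anchor = min(all_leaves)
        for node in t.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            key = below if anchor not in below else all_leaves - below
            if key in self.supports:
                node.label = f"{self.supports[key]:.1f}"
        return t.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def _adjacency_from_newick(newick: str):
    t = dendropy.Tree.get(
        data=newick, schema="newick", rooting="default-unrooted",
        preserve_underscores=True,
    )
    t.deroot()
    adj: dict[int, set[int]] = {}
    labels: dict[int, str] = {}
    ids: dict = {}

    def nid(node):
        if id(node) not in ids:
            ids[id(node)] = len(ids)
            adj[ids[id(node)]] = set()
            if node.is_leaf():
                labels[ids[id(node)]] = node.taxon.label
        return ids[id(node)]

    for edge in t.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        u, v = nid(edge.tail_node), nid(edge.head_node)
        adj[u].add(v)
        adj[v].add(u)
    return adj, labels


def _bipartitions(adj, labels) -> set[frozenset]:
    all_leaves = frozenset(labels.values())
    anchor = min(all_leaves)
    out = set()
    for u in adj:
        for v in adj[u]:
            if u > v:
                continue
            side = _component_leaves(adj, v, u, labels)
            if 1 < len(side) < len(all_leaves) - 1:
                key = frozenset(side)
                if anchor in key:
                    key = all_leaves - key
                out.add(key)
    return out


def _component_leaves(adj, start, blocked, labels):
    stack, seen, out = [start], {blocked, start}, []
    while stack:
        n = stack.pop()
        if n in labels:
            out.append(labels[n])
        for m in adj[n]:
            if m not in seen:
                seen.add(m)
                stack.append(m)
    return out


# -- internal unrooted tree on integer leaf indices -------------------------
# Adjacency dict: leaves are 0..n-1, internal nodes are larger ints.


def _utree_from_tuple(sub, root_leaf, next_id):
    """Build adjacency from a nested-tuple subtree hanging off ``root_leaf``."""
    adj = {root_leaf: set()}

    def walk(node):
        nonlocal next_id
        if isinstance(node, int):
            adj.setdefault(node, set())
            return node
        me = next_id
        next_id += 1
        adj[me] = set()
        for child in node:
            c = walk(child)
            adj[me].add(c)
            adj[c].add(me)
        return me

    top = walk(sub)
    adj[root_leaf].add(top)
    adj[top].add(root_leaf)
    return adj


def _utree_newick(adj, labels: list[str]) -> str:
    # root at leaf 0's neighbor for output
    root = next(iter(adj[0]))

    def walk(node, parent):
        kids = [m for m in adj[node] if m != parent]
        if not kids:
            return labels[node]
        return "(" + ",".join(walk(k, node) for k in kids) + ")"

    kids = [m for m in adj[root] if True]
    return "(" + ",".join(walk(k, root) for k in kids) + ");"


def _utree_bipartitions(adj, n_leaves) -> frozenset:
    out = []
    for u in adj:
        for v in adj[u]:
            if u > v:
                continue
            side = frozenset(
                x for x in _component_nodes(adj, v, u) if x < n_leaves
            )
            if 1 < len(side) < n_leaves - 1:
                if 0 in side:
                    side = frozenset(range(n_leaves)) - side
                out.append(side)
    return frozenset(out)


def _component_nodes(adj, start, blocked):
    stack, seen = [start], {blocked, start}
    while stack:
        n = stack.pop()
        yield n
        for m in adj[n]:
            if m not in seen:
                seen.add(m)
                stack.append(m)


def _fitch_steps_adj(adj, leaf_masks, weights, per_pattern=False):
    """Fitch length of an unrooted binary tree given as adjacency.

    ``leaf_masks``: (n_leaves, P) uint8.  Missing contributes the full state
    set and never forces a step.
    """
    P = leaf_masks.shape[1]
    n_leaves = leaf_masks.shape[0]
    root_leaf = 0
    start = next(iter(adj[root_leaf]))
    steps = np.zeros(P, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    # iterative postorder
    stack = [(start, root_leaf, False)]
    while stack:
        node, parent, done = stack.pop()
        if node < n_leaves:
            sets[node] = leaf_masks[node]
            continue
        kids = [m for m in adj[node] if m != parent]
        if not done:
            stack.append((node, parent, True))
            for k in kids:
                stack.append((k, node, False))
            continue
        acc = sets[kids[0]]
        for k in kids[1:]:
            inter = acc & sets[k]
            empty = inter == 0
            acc = np.where(empty, acc | sets[k], inter)
            steps += empty
        sets[node] = acc
    # the root edge to leaf 0
    inter = sets[start] & leaf_masks[root_leaf]
    steps += inter == 0
    if per_pattern:
        return steps
    return int((steps * weights).sum())


def fitch_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Fitch parsimony length of ``tree`` on ``matrix`` (all sites)."""
    adj, labels = _adjacency_from_newick(tree.newick)
    order = {t: i for i, t in enumerate(matrix.taxa)}
    if sorted(labels.values()) != sorted(matrix.taxa):
        raise TreeError("tree leaves do not match matrix taxa")
    remap = {}
    next_internal = matrix.n_taxa
    for n in adj:
        if n in labels:
            remap[n] = order[labels[n]]
        else:
            remap[n] = next_internal
            next_internal += 1
    adj2 = {remap[u]: {remap[v] for v in vs} for u, vs in adj.items()}
    return _fitch_steps_adj(adj2, matrix.masks, matrix.weights)


# ---------------------------------------------------------------------------
# Search


@dataclass
class ParsimonyResult:
    best_trees: list[Tree]
    tree_length: int
    ci: float
    ri: float
    ci_excluding_uninformative: float
    n_topologies_evaluated: int = 0

    @property
    def best(self) -> Tree:
        return self.best_trees[0]


def _tuple_insertions(node, x):
    yield (node, x)
    if isinstance(node, tuple):
        for l2 in _tuple_insertions(node[0], x):
            yield (l2, node[1])
        for r2 in _tuple_insertions(node[1], x):
            yield (node[0], r2)


def _tuple_to_adj(sub, n_leaves):
    return _utree_from_tuple(sub, 0, n_leaves)


def _finish_result(best_adjs, length, matrix, labels, n_eval) -> ParsimonyResult:
    seen = set()
    trees = []
    for adj in best_adjs:
        key = _utree_bipartitions(adj, len(labels))
        if key in seen:
            continue
        seen.add(key)
        trees.append(Tree(newick=_utree_newick(adj, labels)))
    trees.sort(key=lambda t: t.newick)
    ci, ri, ci_ex = _indices_for_length(best_adjs[0], matrix, length)
    return ParsimonyResult(
        best_trees=trees,
        tree_length=length,
        ci=ci,
        ri=ri,
        ci_excluding_uninformative=ci_ex,
        n_topologies_evaluated=n_eval,
    )


def exhaustive_search(matrix: CharacterMatrix, prune: bool = True) -> ParsimonyResult:
    """Exact maximum parsimony by stepwise topology enumeration.

    With ``prune=True`` (default) partial trees whose length already exceeds
    the incumbent are abandoned (branch-and-bound; adding a leaf never
    shortens a tree, so the optimum is unchanged).  With ``prune=False``
    every one of the (2n-5)!! unrooted topologies is scored.
    """
    n = matrix.n_taxa
    if n > 9:
        raise TreeError(
            f"{n} taxa would require {_double_factorial(2 * n - 5):,} "
            "topologies; use heuristic_search"
        )
    if n < 4:
        raise TreeError("need at least 4 taxa for tree search")
    masks, weights = matrix.masks, matrix.weights
    var = matrix.pattern_class != SITE_CONSTANT
    vmasks, vweights = masks[:, var], weights[var]
    best_len = None
    best: list = []
    n_eval = 0
    if prune:
        # incumbent from one greedy addition pass
        greedy = _stepwise_addition(list(range(n)), vmasks, vweights)
        best_len = _fitch_steps_adj(_tuple_to_adj(greedy, n), vmasks, vweights)
        best = [greedy]

    def recurse(sub, next_taxon):
        nonlocal best_len, best, n_eval
        if next_taxon == n:
            n_eval += 1
            ln = _fitch_steps_adj(_tuple_to_adj(sub, n), vmasks, vweights)
            if best_len is None or ln < best_len:
                best_len, best = ln, [sub]
            elif ln == best_len and sub not in best:
                best.append(sub)
            return
        for cand in _tuple_insertions(sub, next_taxon):
            if prune and best_len is not None:
                partial = _fitch_steps_adj(
                    _tuple_to_adj(cand, n), vmasks, vweights
                )
                if partial > best_len:
                    continue
            recurse(cand, next_taxon + 1)

    recurse((1, 2), 3)
    adjs = [_tuple_to_adj(s, n) for s in best]
    return _finish_result(adjs, best_len, matrix, matrix.taxa, n_eval)


def _double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def _stepwise_addition(order, masks, weights):
    """Greedy stepwise addition following ``order`` (first taxon is the
    representation root; ties broken by first-found)."""
    relabel = {t: i for i, t in enumerate(order)}
    # work in a relabelled space where the root leaf is 0
    m = masks[order]
    sub = (1, 2)
    for nxt in range(3, len(order)):
        best_sub, best_len = None, None
        for cand in _tuple_insertions(sub, nxt):
            ln = _fitch_steps_adj(
                _utree_from_tuple(cand, 0, len(order)), m[: nxt + 1], weights
            )
            if best_len is None or ln < best_len:
                best_sub, best_len = cand, ln
        sub = best_sub
    # map back to original taxon indices
    inv = {i: t for t, i in relabel.items()}

    def back(node):
        if isinstance(node, int):
            return inv[node]
        return (back(node[0]), back(node[1]))

    mapped = back(sub)
    root = inv[0]
    # re-express rooted at leaf 0 via adjacency round-trip
    adj = _utree_from_tuple(mapped, root, len(order))
    return _adj_to_tuple(adj, len(order))


def _adj_to_tuple(adj, n_leaves):
    start = next(iter(adj[0]))

    def walk(node, parent):
        if node < n_leaves:
            return node
        kids = [m for m in adj[node] if m != parent]
        return (walk(kids[0], node), walk(kids[1], node))

    return walk(start, 0)


def _tbr_neighbors(adj, n_leaves):
    """All TBR rearrangements: bisect at an edge, then reconnect every edge
    of one fragment to every edge of the other."""
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    seen = set()
    for u, v in edges:
        a1 = {k: set(s) for k, s in adj.items()}
        a1[u].discard(v)
        a1[v].discard(u)
        comp_u = set(_component_nodes(a1, u, -1))
        comp_v = set(_component_nodes(a1, v, -1))
        for comp, att in ((comp_u, u), (comp_v, v)):
            _suppress(a1, att)
        frag_u = {k: set(a1[k]) for k in a1 if k in comp_u}
        frag_v = {k: set(a1[k]) for k in a1 if k in comp_v}
        for eu in _fragment_attachments(frag_u, u):
            for ev in _fragment_attachments(frag_v, v):
                cand = _reconnect(frag_u, frag_v, eu, ev, max(adj) + 1)
                key = _utree_bipartitions(cand, n_leaves)
                if key not in seen:
                    seen.add(key)
                    yield cand


def _suppress(adj, node):
    """Remove a degree-2 node left behind by edge deletion."""
    if node in adj and len(adj[node]) == 2:
        a, b = adj[node]
        adj[a].discard(node)
        adj[b].discard(node)
        adj[a].add(b)
        adj[b].add(a)
        del adj[node]


def _fragment_attachments(frag, old_attach):
    """Attachment points of a fragment: its edges (as pairs) or, for a
    single-node fragment, the node itself."""
    if not frag:
        return
    if len(frag) == 1:
        yield (next(iter(frag)), None)
        return
    for u in frag:
        for v in frag[u]:
            if u < v:
                yield (u, v)


def _reconnect(frag_a, frag_b, ea, eb, fresh):
    adj = {k: set(s) for k, s in frag_a.items()}
    for k, s in frag_b.items():
        adj[k] = set(s)

    def attach(edge):
        nonlocal fresh
        u, v = edge
        if v is None:
            return u
        mid = fresh
        fresh += 1
        adj[u].discard(v)
        adj[v].discard(u)
        adj[mid] = {u, v}
        adj[u].add(mid)
        adj[v].add(mid)
        return mid

    pa = attach(ea)
    pb = attach(eb)
    adj[pa].add(pb)
    adj[pb].add(pa)
    return adj


def heuristic_search(
    matrix: CharacterMatrix,
    n_additions: int = 10,
    seed: int | np.random.Generator = 0,
) -> ParsimonyResult:
    """Random-addition-sequence stepwise addition followed by TBR branch
    swapping to local optimality, repeated ``n_additions`` times;
    deterministic given ``seed``."""
    if n_additions < 1:
        raise TreeError("n_additions must be >= 1")
    n = matrix.n_taxa
    if n < 4:
        raise TreeError("need at least 4 taxa for tree search")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    var = matrix.pattern_class != SITE_CONSTANT
    vmasks, vweights = matrix.masks[:, var], matrix.weights[var]
    best_len = None
    best_adjs: list = []
    best_keys: set = set()
    n_eval = 0
    for _ in range(n_additions):
        order = [int(x) for x in rng.permutation(n)]
        sub = _stepwise_addition(order, vmasks, vweights)
        adj = _tuple_to_adj(sub, n)
        ln = _fitch_steps_adj(adj, vmasks, vweights)
        improved = True
        while improved:
            improved = False
            for cand in _tbr_neighbors(adj, n):
                n_eval += 1
                cl = _fitch_steps_adj(cand, vmasks, vweights)
                if cl < ln:
                    adj, ln = cand, cl
                    improved = True
                    break
        key = _utree_bipartitions(adj, n)
        if best_len is None or ln < best_len:
            best_len, best_adjs, best_keys = ln, [adj], {key}
        elif ln == best_len and key not in best_keys:
            best_adjs.append(adj)
            best_keys.add(key)
    return _finish_result(best_adjs, best_len, matrix, matrix.taxa, n_eval)


# ---------------------------------------------------------------------------
# Indices


def _indices_for_length(adj, matrix: CharacterMatrix, length: int):
    per = _fitch_steps_adj(adj, matrix.masks, matrix.weights, per_pattern=True)
    return _consistency_from_per_site(per, matrix)


def _consistency_from_per_site(per_pattern_steps, matrix: CharacterMatrix):
    w = matrix.weights
    m = matrix.min_steps()
    g = matrix.max_steps()
    s = per_pattern_steps
    Sm, Ss, Sg = int((m * w).sum()), int((s * w).sum()), int((g * w).sum())
    ci = 1.0 if Ss == 0 else Sm / Ss
    if Sg == Sm:
        warnings.warn("retention index undefined (max steps equal min steps); using 1")
        ri = 1.0
    else:
        ri = (Sg - Ss) / (Sg - Sm)
    keep = matrix.pattern_class == SITE_INFORMATIVE
    Sm_i = int((m[keep] * w[keep]).sum())
    Ss_i = int((s[keep] * w[keep]).sum())
    ci_ex = 1.0 if Ss_i == 0 else Sm_i / Ss_i
    return ci, ri, ci_ex


def consistency_indices(tree: Tree, matrix: CharacterMatrix):
    """(CI, RI, CI excluding parsimony-uninformative sites) for one tree.

    CI = sum(m)/sum(s); RI = (sum(g)-sum(s))/(sum(g)-sum(m)) with m the
    minimum, s the observed and g the star-tree maximum steps per site.
    """
    adj, labels = _adjacency_from_newick(tree.newick)
    order = {t: i for i, t in enumerate(matrix.taxa)}
    if sorted(labels.values()) != sorted(matrix.taxa):
        raise TreeError("tree leaves do not match matrix taxa")
    remap = {}
    nxt = matrix.n_taxa
    for nnode in adj:
        if nnode in labels:
            remap[nnode] = order[labels[nnode]]
        else:
            remap[nnode] = nxt
            nxt += 1
    adj2 = {remap[u]: {remap[v] for v in vs} for u, vs in adj.items()}
    per = _fitch_steps_adj(adj2, matrix.masks, matrix.weights, per_pattern=True)
    return _consistency_from_per_site(per, matrix)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    matrix: CharacterMatrix,
    n_reps: int,
    seed: int | np.random.Generator = 0,
    search_fn=None,
    best_tree: Tree | None = None,
) -> Tree:
    """Nonparametric bootstrap: support of each bipartition of the full-data
    best tree = percent of column-resampled replicates whose best tree
    contains it."""
    if n_reps < 1:
        raise TreeError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if search_fn is None:
        search_fn = lambda mat, r: heuristic_search(mat, n_additions=1, seed=r)
    if best_tree is None:
        best_tree = search_fn(matrix, rng).best
    target = best_tree.bipartitions()
    hits = {b: 0 for b in target}
    for _ in range(n_reps):
        rep = matrix.resampled(rng)
        rep_best = search_fn(rep, rng).best
        found = rep_best.bipartitions()
        for b in target:
            if b in found:
                hits[b] += 1
    supports = {b: 100.0 * h / n_reps for b, h in hits.items()}
    return Tree(newick=best_tree.newick, supports=supports)


# ---------------------------------------------------------------------------
# Neighbor joining & rooting


def neighbor_joining(distance_df) -> Tree:
    """Canonical neighbor joining (Q-criterion agglomeration) on a symmetric
    distance matrix (pandas DataFrame, zero diagonal); negative branch
    lengths are clamped to zero with a warning."""
    import pandas as pd
    from skbio import DistanceMatrix
    from skbio.tree import nj

    df = distance_df
    if not np.allclose(df.values, df.values.T):
        raise TreeError("distance matrix is not symmetric")
    if not np.allclose(np.diag(df.values), 0):
        raise TreeError("distance matrix diagonal is not zero")
    dm = DistanceMatrix(df.values.astype(float), ids=list(df.index))
    t = nj(dm)
    clamped = False
    for node in t.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0")
    return Tree(newick=str(t).strip())


def root_with_outgroup(tree: Tree, outgroup_label: str) -> Tree:
    """Root on the outgroup's pendant edge; ingroup bipartitions unchanged."""
    t = tree._dendropy()
    node = None
    for leaf in t.leaf_node_iter():
        if leaf.taxon.label == outgroup_label:
            node = leaf
            break
    if node is None:
        raise TreeError(f"outgroup {outgroup_label!r} is not a leaf of the tree")
    if node.edge.length is None:
        t.reroot_at_edge(node.edge, update_bipartitions=False)
    else:
        t.reroot_at_edge(
            node.edge, length1=node.edge.length / 2, length2=node.edge.length / 2,
            update_bipartitions=False,
        )
    return Tree(
        newick=t.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip(),
        rooted=True,
        supports=dict(tree.supports),
    )


# ---------------------------------------------------------------------------
# Export


def to_phylip(matrix_rows: dict[str, str]) -> str:
    n = len(matrix_rows)
    L = len(next(iter(matrix_rows.values())))
    lines = [f" {n} {L}"]
    for t, row in matrix_rows.items():
        lines.append(f"{t[:30]:<32}{row}")
    return "\n".join(lines) + "\n"


def to_nexus(matrix_rows: dict[str, str]) -> str:
    n = len(matrix_rows)
    L = len(next(iter(matrix_rows.values())))
    out = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={n} NCHAR={L};",
        "  FORMAT DATATYPE=DNA MISSING=? GAP=-;",
        "  MATRIX",
    ]
    for t, row in matrix_rows.items():
        out.append(f"    {t}  {row}")
    out += ["  ;", "END;"]
    return "\n".join(out) + "\n"
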