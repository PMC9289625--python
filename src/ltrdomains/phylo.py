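"""Distance phylogenetics for RT and 2-ODD domain placement.

The domain region is extracted from a consensus via its profile hit, aligned
with labeled references, converted to a Poisson-corrected amino-acid distance
matrix, and a neighbor-joining tree with column-resampling bootstrap supports
places query domains among the references.  This is a desk-scale distance
substitute for maximum-likelihood inference: its claims are qualitative
placement, not likelihoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusRecord
from .pssm import DomainProfile, scan_profiles, six_frame_translate

SATURATION_CAP = 5.0


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; branch length is to the parent edge."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick_node() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6f}"


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class PlacementReport:
    query: str
    group: str | None  # smallest monophyletic reference group holding the query
    sister: str | None
    support: float | None
    resolved: bool


def extract_domain_region(record: ConsensusRecord, profile: DomainProfile) -> str:
    """Translated aa sequence of the max-score hit of *profile* on a consensus."""
    hits = scan_profiles(record.seq, [profile])
    if not hits:
        raise ValueError(f"no {profile.label} hit on {record.consensus_id}")
    best = max(hits, key=lambda h: h.score)
    frames = six_frame_translate(record.seq)
    frame = next(f for f in frames if f.strand == best.strand and f.offset == best.frame_offset)
    return frame.aa[best.aa_start : best.aa_end]


def build_distance_matrix(seqs: list[tuple[str, str]]) -> DistanceMatrix:
    """Poisson-corrected aa distance: d = -19/20 ln(1 - 20p/19).

    p is the mismatch fraction over columns where both rows are non-gap;
    saturated pairs (p >= 19/20) are capped at 5.0 and flagged.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    lengths = {len(s) for _, s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    labels = [sid for sid, _ in seqs]
    rows = [np.frombuffer(s.encode(), dtype="S1") for _, s in seqs]
    gap = np.array([b"-"])[0]
    n = len(rows)
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            both = (rows[i] != gap) & (rows[j] != gap)
            total = int(both.sum())
            if total == 0:
                raise ValueError(f"no comparable sites between {labels[i]} and {labels[j]}")
            p = float((rows[i][both] != rows[j][both]).mean())
            arg = 1.0 - p * 20.0 / 19.0
            if arg <= 0:
                dist = SATURATION_CAP
                saturated.append((labels[i], labels[j]))
            else:
                dist = min(-math.log(arg) * 19.0 / 20.0, SATURATION_CAP)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=labels, matrix=d, saturated_pairs=saturated)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining; deterministic, Q ties to the smallest pair."""
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: dict[int, TreeNode] = {i: TreeNode(name=labels[i]) for i in range(n)}
    D = dm.matrix.astype(float).copy()
    active = list(range(n))
    index = {i: i for i in active}  # node id -> row in D
    next_id = n
    while len(active) > 3:
        m = len(active)
        rows = [index[a] for a in active]
        sub = D[np.ix_(rows, rows)]
        totals = sub.sum(axis=1)
        Q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (round(float(Q[a, b]), 10), a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        i_id, j_id = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (totals[a] - totals[b]) / (2 * (m - 2))
        lj = dij - li
        ni, nj_ = nodes.pop(i_id), nodes.pop(j_id)
        ni.length = max(li, 0.0)
        nj_.length = max(lj, 0.0)
        parent = TreeNode(children=[ni, nj_])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (sub[a, :] + sub[b, :] - dij)
        r_new = index[i_id]  # reuse row of i
        for c, other in enumerate(active):
            if other in (i_id, j_id):
                continue
            D[r_new, index[other]] = D[index[other], r_new] = new_row[c]
        nodes[next_id] = parent
        index[next_id] = r_new
        active = [x for x in active if x not in (i_id, j_id)] + [next_id]
        next_id += 1
    # final three-way join (unrooted trifurcation), three-point formulas
    a_id, b_id, c_id = active
    ra, rb, rc = index[a_id], index[b_id], index[c_id]
    dab, dac, dbc = D[ra, rb], D[ra, rc], D[rb, rc]
    na, nb, nc = nodes[a_id], nodes[b_id], nodes[c_id]
    na.length = max(0.5 * (dab + dac - dbc), 0.0)
    nb.length = max(0.5 * (dab + dbc - dac), 0.0)
    nc.length = max(0.5 * (dac + dbc - dab), 0.0)
    return TreeNode(children=[na, nb, nc])


def tree_splits(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Non-trivial bipartitions, keyed by the leaf set not containing the
    alphabetically first leaf (a canonical side)."""
    all_leaves = tree.leaf_names()
    anchor = min(all_leaves)
    splits: dict[frozenset[str], TreeNode] = {}

    def walk(node: TreeNode) -> None:
        for c in node.children:
            names = c.leaf_names()
            if 1 < len(names) < len(all_leaves) - 1:
                side = names if anchor not in names else all_leaves - names
                splits[frozenset(side)] = c
            walk(c)

    walk(tree)
    return splits


def bootstrap_support(
    seqs: list[tuple[str, str]],
    n_replicates: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ point-estimate tree with column-resampling bootstrap supports.

    Columns of the alignment are resampled with replacement, the tree is
    rebuilt per replicate, and each internal edge of the point-estimate tree
    is annotated with the percentage of replicates recovering its bipartition.
    """
    tree = nj_tree(build_distance_matrix(seqs))
    if n_replicates <= 0:
        return tree
    rng = np.random.default_rng(seed)
    splits = tree_splits(tree)
    counts = {s: 0 for s in splits}
    ncol = len(seqs[0][1])
    ids = [sid for sid, _ in seqs]
    mats = np.array([list(s) for _, s in seqs])
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = ["".join(row) for row in mats[:, cols]]
        try:
            rep_tree = nj_tree(build_distance_matrix(list(zip(ids, resampled))))
        except ValueError:
            continue
        rep_splits = set(tree_splits(rep_tree))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for s, node in splits.items():
        node.support = 100.0 * counts[s] / n_replicates
    return tree


def place_query(
    tree: TreeNode,
    query_label: str,
    reference_groups: dict[str, set[str]],
    outgroup: str,
    min_support: float = 50.0,
) -> PlacementReport:
    """Smallest monophyletic reference group containing the query.

    The unrooted tree is rooted at the declared outgroup leaf; walking from
    the query toward the root, the first ancestor whose other leaves all
    belong to one reference group gives the placement; the sister group is
    read off the next ancestor.  Placement is flagged unresolved when the
    supporting edge has bootstrap < ``min_support`` (if supports are present).
    """
    leaves = tree.leaf_names()
    if query_label not in leaves:
        raise ValueError(f"query {query_label} not in tree")
    if outgroup not in leaves:
        raise ValueError(f"outgroup {outgroup} not in tree")

    rooted = _root_at(tree, outgroup)

    def label_of(name: str) -> str | None:
        for g, members in reference_groups.items():
            if name in members:
                return g
        return None

    # path from query leaf to the root
    path: list[TreeNode] = []

    def find(node: TreeNode, trail: list[TreeNode]) -> bool:
        trail.append(node)
        if not node.children and node.name == query_label:
            return True
        for c in node.children:
            if find(c, trail):
                return True
        trail.pop()
        return False

    find(rooted, path)
    path.reverse()  # leaf first
    group = None
    support = None
    sister = None
    for k, anc in enumerate(path[1:], start=1):
        others = anc.leaf_names() - {query_label}
        if not others:
            continue
        labels = {label_of(x) for x in others}
        if None not in labels and len(labels) == 1:
            group = labels.pop()
            support = anc.support
            if k + 1 < len(path):
                nxt = path[k + 1]
                sisters = nxt.leaf_names() - anc.leaf_names()
                sister_labels = {label_of(x) for x in sisters} - {None}
                sister = sorted(sister_labels)[0] if len(sister_labels) == 1 else None
        else:
            break
    resolved = group is not None and (support is None or support >= min_support)
    return PlacementReport(
        query=query_label, group=group, sister=sister, support=support, resolved=resolved
    )


def _root_at(tree: TreeNode, outgroup: str) -> TreeNode:
    """Reroot the tree at the declared outgroup leaf.

    The tree is decomposed into an undirected edge graph (each edge carrying
    the child's branch length and support) and rebuilt oriented away from the
    outgroup, so every internal node's subtree is a clade relative to the
    outgroup rooting.
    """
    # collect nodes and undirected edges
    node_key: dict[int, TreeNode] = {}
    adjacency: dict[int, list[tuple[int, float, float | None]]] = {}

    def collect(node: TreeNode) -> None:
        node_key[id(node)] = node
        adjacency.setdefault(id(node), [])
        for c in node.children:
            adjacency.setdefault(id(c), [])
            adjacency[id(node)].append((id(c), c.length, c.support))
            adjacency[id(c)].append((id(node), c.length, c.support))
            collect(c)

    collect(tree)
    og_id = next(
        k for k, v in node_key.items() if not v.children and v.name == outgroup
    )

    def rebuild(nid: int, parent: int | None, length: float, support: float | None) -> TreeNode:
        orig = node_key[nid]
        fresh = TreeNode(name=orig.name, length=length, support=support)
        for cid, clen, csup in adjacency[nid]:
            if parent is not None and cid == parent:
                continue
            fresh.children.append(rebuild(cid, nid, clen, csup))
        # suppress pass-through nodes created by removing the old root
        fresh.children = [
            c if len(c.children) != 1 else _merge_unary(c) for c in fresh.children
        ]
        return fresh

    return rebuild(og_id, None, 0.0, None)


def _merge_unary(node: TreeNode) -> TreeNode:
    child = node.children[0]
    child.length += node.length
    if child.support is None:
        child.support = node.support
    return child
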