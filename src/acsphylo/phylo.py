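"""Distance-based tree reconstruction and topology comparison.

Neighbor-joining (Saitou & Nei) on a symmetric distance matrix, Newick
serialization, and the Robinson-Foulds symmetric-difference distance over
nontrivial bipartitions.  Unrooted trees are stored with an arbitrary
trifurcating root, the convention NJ naturally produces.

NJ here is the textbook algorithm: at each step join the pair (p, q)
minimizing Q(p, q) = (r - 2) d(p, q) - sum_p - sum_q, assign limb lengths by
the usual split formula, and reduce the matrix with the average rule
d(new, x) = (d(p, x) + d(q, x) - d(p, q)) / 2.  Ties are broken toward the
lowest (row, column) index pair, so results are deterministic.  On additive
matrices the source tree (topology and branch lengths) is recovered
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional, Set, Tuple

import numpy as np

from .errors import InvalidInputError, NewickParseError
from .distance import DistanceMatrix

__all__ = [
    "TreeNode",
    "PhyloTree",
    "neighbor_joining",
    "tree_bipartitions",
    "rf_distance",
    "write_newick",
    "parse_newick",
    "path_length_matrix",
]


@dataclass(eq=False)  # identity semantics: nodes are places in a tree, not values
class TreeNode:
    """A node of a rooted representation; ``length`` is the edge to the parent."""

    name: Optional[str] = None
    length: Optional[float] = None
    children: List["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    """Leaf-labeled tree, nominally unrooted (trifurcating root by convention)."""

    root: TreeNode

    def leaves(self) -> List[TreeNode]:
        return [node for node in self.root.walk() if node.is_leaf]

    def leaf_names(self) -> List[str]:
        names = [leaf.name or "" for leaf in self.leaves()]
        if len(set(names)) != len(names) or "" in names:
            raise InvalidInputError("tree leaves must carry unique non-empty labels")
        return names

    def __len__(self) -> int:
        return len(self.leaves())


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(m: DistanceMatrix, negative_branches: str = "keep") -> PhyloTree:
    """Reconstruct an unrooted tree from a symmetric distance matrix.

    Parameters
    ----------
    m : DistanceMatrix
        Symmetric, zero-diagonal, at least 3 taxa.  Negative off-diagonal
        entries are permitted (ACS-style distances can dip below zero).
    negative_branches : {"keep", "transfer"}
        "keep" reports limb lengths as computed; "transfer" zeroes a
        negative limb and moves its length onto the sister limb (the sum
        across the joined pair is preserved), the common convention when a
        downstream consumer rejects negative branch lengths.
    """
    if negative_branches not in ("keep", "transfer"):
        raise InvalidInputError("negative_branches must be 'keep' or 'transfer'")
    d = np.array(m.d, dtype=float)
    r = d.shape[0]
    if r < 3:
        raise InvalidInputError("neighbor joining needs at least 3 taxa")
    if not np.isfinite(d).all():
        raise InvalidInputError("distance matrix contains non-finite entries")
    if not np.allclose(d, d.T, atol=1e-9):
        raise InvalidInputError("distance matrix must be symmetric")

    nodes: List[TreeNode] = [TreeNode(name=t) for t in m.taxa]
    while len(nodes) > 3:
        r = len(nodes)
        sums = d.sum(axis=1)
        q = (r - 2) * d - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        p_i, q_i = divmod(int(np.argmin(q)), r)  # row-major argmin = lowest (row, col)
        if p_i > q_i:
            p_i, q_i = q_i, p_i
        dpq = d[p_i, q_i]
        la = 0.5 * dpq + (sums[p_i] - sums[q_i]) / (2.0 * (r - 2))
        lb = dpq - la
        la, lb = _settle_negative(la, lb, negative_branches)
        joined = TreeNode(children=[nodes[p_i], nodes[q_i]])
        nodes[p_i].length, nodes[q_i].length = la, lb

        fresh = 0.5 * (d[p_i] + d[q_i] - dpq)
        keep = [i for i in range(r) if i not in (p_i, q_i)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = fresh[keep]
        nodes = [nodes[i] for i in keep] + [joined]

    da, db, dc = d[0, 1], d[0, 2], d[1, 2]
    limbs = [0.5 * (da + db - dc), 0.5 * (da + dc - db), 0.5 * (db + dc - da)]
    if negative_branches == "transfer":
        limbs = _settle_negative_triple(limbs)
    for node, limb in zip(nodes, limbs):
        node.length = limb
    return PhyloTree(TreeNode(children=nodes))


def _settle_negative(la: float, lb: float, mode: str) -> Tuple[float, float]:
    if mode == "transfer":
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
    return la, lb


def _settle_negative_triple(limbs: List[float]) -> List[float]:
    out = list(limbs)
    for i, v in enumerate(out):
        if v < 0:
            out[(i + 1) % 3] += v / 2
            out[(i + 2) % 3] += v / 2
            out[i] = 0.0
    return out


# ---------------------------------------------------------------------------
# Bipartitions and Robinson-Foulds
# ---------------------------------------------------------------------------

def tree_bipartitions(t: PhyloTree) -> Set[FrozenSet[str]]:
    """Nontrivial splits of an unrooted tree, one per internal edge.

    Each split is canonicalized as the side *not* containing the
    lexicographically smallest leaf (for equal leaf sets this makes split
    sets directly comparable).  Trivial splits (one leaf on a side) are
    excluded, so a fully resolved n-leaf tree yields n - 3 splits.
    """
    names = t.leaf_names()
    total = len(names)
    anchor = min(names)
    splits: Set[FrozenSet[str]] = set()

    def below(node: TreeNode) -> Set[str]:
        if node.is_leaf:
            return {node.name}
        mine: Set[str] = set()
        for child in node.children:
            sub = below(child)
            if 2 <= len(sub) <= total - 2:
                side = frozenset(sub) if anchor not in sub else frozenset(set(names) - sub)
                splits.add(side)
            mine |= sub
        return mine

    below(t.root)
    return splits


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unnormalized Robinson-Foulds distance (symmetric-difference count).

    Counts the nontrivial bipartitions present in exactly one of the two
    trees; 0 iff the unrooted topologies are identical.  Branch lengths are
    ignored.
    """
    n1, n2 = set(t1.leaf_names()), set(t2.leaf_names())
    if n1 != n2:
        raise InvalidInputError(
            f"trees have different leaf sets ({sorted(n1 ^ n2)[:5]} ... differ)"
        )
    return len(tree_bipartitions(t1) ^ tree_bipartitions(t2))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = set(" ()[]{}:;,'\"")


def _format_label(label: str) -> str:
    if any(c in _NEEDS_QUOTE for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(t: PhyloTree) -> str:
    """Serialize a tree to a Newick string (';'-terminated)."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            body = _format_label(node.name or "")
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += _format_label(node.name)
        if node.length is not None:
            body += f":{node.length:.10g}"
        return body

    return fmt(t.root) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; raises NewickParseError with the failure offset."""
    s = text.strip()
    pos = 0

    def error(msg: str) -> NewickParseError:
        return NewickParseError(msg, pos)

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1

    def read_label() -> str:
        nonlocal pos
        skip_ws()
        if peek() == "'":
            pos += 1
            out = []
            while True:
                if pos >= len(s):
                    raise error("unterminated quoted label")
                ch = s[pos]
                if ch == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(ch)
                pos += 1
        start = pos
        while pos < len(s) and s[pos] not in "();,:[]" and not s[pos].isspace():
            pos += 1
        return s[start:pos]

    def read_length() -> Optional[float]:
        nonlocal pos
        skip_ws()
        if peek() != ":":
            return None
        pos += 1
        skip_ws()
        start = pos
        while pos < len(s) and (s[pos] in "+-.eE" or s[pos].isdigit()):
            pos += 1
        try:
            return float(s[start:pos])
        except ValueError:
            raise error("expected branch length after ':'") from None

    def read_subtree() -> TreeNode:
        nonlocal pos
        skip_ws()
        if peek() == "(":
            pos += 1
            children = [read_subtree()]
            skip_ws()
            while peek() == ",":
                pos += 1
                children.append(read_subtree())
                skip_ws()
            if peek() != ")":
                raise error("expected ')' or ','")
            pos += 1
            node = TreeNode(children=children)
            label = read_label()
            if label:
                node.name = label
        else:
            label = read_label()
            if not label:
                raise error("expected a leaf label")
            node = TreeNode(name=label)
        node.length = read_length()
        return node

    root = read_subtree()
    skip_ws()
    if peek() != ";":
        raise error("expected ';' terminator")
    pos += 1
    skip_ws()
    if pos != len(s):
        raise error("trailing characters after ';'")
    tree = PhyloTree(root)
    tree.leaf_names()  # validates label uniqueness
    return tree


# ---------------------------------------------------------------------------
# Path lengths (additive matrix of a tree)
# ---------------------------------------------------------------------------

def path_length_matrix(t: PhyloTree, taxa: Optional[List[str]] = None) -> DistanceMatrix:
    """Leaf-to-leaf path-length (additive) matrix of a tree.

    Useful for round-trip checks: neighbor_joining applied to this matrix
    reconstructs the tree exactly.  Taxa default to sorted leaf names.
    """
    names = t.leaf_names()
    if taxa is None:
        taxa = sorted(names)
    elif set(taxa) != set(names):
        raise InvalidInputError("taxa do not match the tree's leaves")

    adjacency: Dict[int, List[Tuple[int, float]]] = {}
    leaf_of: Dict[str, int] = {}
    counter = 0

    def build(node: TreeNode) -> int:
        nonlocal counter
        me = counter
        counter += 1
        adjacency[me] = []
        if node.is_leaf:
            leaf_of[node.name] = me
        for child in node.children:
            if child.length is None:
                raise InvalidInputError("path lengths need branch lengths on every edge")
            cid = build(child)
            adjacency[me].append((cid, child.length))
            adjacency[cid].append((me, child.length))
        return me

    build(t.root)
    size = len(taxa)
    d = np.zeros((size, size))
    for i, name in enumerate(taxa):
        dist = {leaf_of[name]: 0.0}
        stack = [leaf_of[name]]
        while stack:
            u = stack.pop()
            for v, w in adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, other in enumerate(taxa):
            d[i, j] = dist[leaf_of[other]]
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(list(taxa), d, method="path")
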