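"""Poisson-corrected distances, neighbour joining, bootstrap supports, cherries.

The tree-building route mirrors the classic distance workflow for protein
families: per-pair proportion of differing sites under pairwise gap deletion,
Poisson correction d = -ln(1 - p), Saitou–Nei neighbour joining, and bootstrap
supports obtained by resampling alignment columns and mapping each replicate's
bipartitions back onto the full-data tree. Sister gene pairs are the cherries
whose subtending edge exceeds a support cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: p-distances at or above this are treated as saturated (Poisson correction
#: would blow up); bootstrap replicates containing one are skipped and counted.
SATURATION_P = 0.99

_GAP = ord("-")
_NEWICK_META = set("()[]{}:;,'\" \t\n")


# ---------------------------------------------------------------------------
# Alignment and distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped protein sequences (residues + ``-``)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate ids in alignment")
        if not self.rows:
            raise ValueError("empty alignment")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise ValueError("alignment rows must all have the same length")

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def encoded(self) -> np.ndarray:
        """Rows as a (n_taxa, n_columns) uint8 matrix of character codes."""
        return np.array([np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in self.rows])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: columns resampled with replacement."""
        idx = rng.integers(0, self.n_columns, size=self.n_columns)
        rows = tuple("".join(row[i] for i in idx) for row in self.rows)
        return Alignment(self.ids, rows)


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA (residues + '-')."""
    ids: list[str] = []
    rows: list[str] = []
    current: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    rows.append("".join(current))
                ids.append(line[1:].split()[0])
                current = []
            elif current is not None:
                current.append(line.upper())
    if current is not None:
        rows.append("".join(current))
    return Alignment(tuple(ids), tuple(rows))


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, row in zip(aln.ids, aln.rows):
            fh.write(f">{name}\n{row}\n")


def p_distance(row_i: str, row_j: str) -> float:
    """Proportion of differing sites, with pairwise deletion of gap columns."""
    if len(row_i) != len(row_j):
        raise ValueError("aligned rows must have equal length")
    compared = 0
    diff = 0
    for a, b in zip(row_i, row_j):
        if a == "-" or b == "-":
            continue
        compared += 1
        if a != b:
            diff += 1
    if compared == 0:
        raise ValueError("zero comparable sites after pairwise gap deletion")
    return diff / compared


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p); requires 0 <= p < 1."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p must be in [0, 1), got {p} (saturated)")
    return -math.log1p(-p)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must be (n_ids, n_ids)")
        if not np.isfinite(m).all():
            raise ValueError("distances must be finite")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric: d(i,j) != d(j,i)")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.ids)


def _poisson_from_encoded(enc: np.ndarray) -> np.ndarray:
    """Pairwise Poisson distances from an encoded alignment (vectorised).

    Raises on any pair with zero comparable sites or a saturated p-distance.
    """
    valid = enc != _GAP
    pair_valid = valid[:, None, :] & valid[None, :, :]
    neq = (enc[:, None, :] != enc[None, :, :]) & pair_valid
    compared = pair_valid.sum(axis=-1)
    np.fill_diagonal(compared, 1)  # diagonal p is 0 regardless
    if (compared == 0).any():
        raise ValueError("zero comparable sites after pairwise gap deletion")
    p = neq.sum(axis=-1) / compared
    if (p >= SATURATION_P).any():
        raise ValueError("saturated p-distance (p >= 0.99)")
    return -np.log1p(-p)


def poisson_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise Poisson-corrected distances for an alignment.

    Raises on any saturated pair (p >= 0.99); the bootstrap handles saturation
    by skipping the replicate instead.
    """
    return DistanceMatrix(aln.ids, _poisson_from_encoded(aln.encoded()))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an unrooted tree stored rooted at an arbitrary internal node."""

    name: str | None = None  # leaf label; internal nodes unnamed
    length: float = 0.0  # length of the edge to the parent
    support: float | None = None  # % support of the edge to the parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class SupportTree:
    """Unrooted tree (root = trifurcation) with optional bootstrap supports."""

    root: TreeNode
    negative_branches_clamped: int = 0
    bootstrap_replicates: int = 0
    skipped_replicates: int = 0

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(leaf.name for leaf in self.root.leaves())  # type: ignore[misc]

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Internal edges as canonical leaf splits.

        Each internal (non-root, non-leaf) node represents the edge above it;
        the bipartition is canonicalised as the side NOT containing the
        lexicographically smallest leaf, so it is rooting-invariant.
        """
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        out: dict[frozenset[str], TreeNode] = {}

        def walk(node: TreeNode, is_root: bool) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])  # type: ignore[list-item]
            below = frozenset().union(*(walk(c, False) for c in node.children))
            if not is_root and 1 < len(below) < len(all_leaves) - 1:
                side = all_leaves - below if anchor in below else below
                out[side] = node
            return below

        walk(self.root, True)
        return out

    def cherries(self) -> list[tuple[str, str, float | None]]:
        """All leaf pairs adjacent to the same internal node, with the support
        of the edge subtending the pair (None if unsupported, e.g. n = 3)."""
        result = []
        stack = [(self.root, True)]
        n_leaves = len(self.leaf_names)
        while stack:
            node, is_root = stack.pop()
            leaf_children = [c for c in node.children if c.is_leaf]
            # in the unrooted sense the node's degree counts the parent edge
            degree = len(node.children) + (0 if is_root else 1)
            if not is_root and len(leaf_children) == 2 and degree == 3:
                a, b = sorted(c.name for c in leaf_children)  # type: ignore[arg-type]
                result.append((a, b, node.support))
            elif is_root and len(leaf_children) == 2 and n_leaves == 4:
                # 4-taxon unrooted tree: the two leaves at the trifurcation
                # form a cherry whose edge is the single internal edge
                internal = [c for c in node.children if not c.is_leaf]
                a, b = sorted(c.name for c in leaf_children)  # type: ignore[arg-type]
                result.append((a, b, internal[0].support if internal else None))
            for c in node.children:
                stack.append((c, False))
        return sorted(result)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> SupportTree:
    """Saitou–Nei neighbour joining on the Q-criterion.

    Recovers additive matrices exactly; negative branch lengths are clamped to
    zero with a count recorded on the returned tree. Deterministic: ties on Q
    are broken by first occurrence in (i, j) index order.
    """
    n = dm.n
    if n < 3:
        raise ValueError("need >= 3 taxa for neighbour joining")
    d = dm.matrix.copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin visits the upper triangle of a tie first
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        vi_raw = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj_raw = d[i, j] - vi_raw
        nodes[i].length = clamp(float(vi_raw))
        nodes[j].length = clamp(float(vj_raw))
        new_node = TreeNode(children=[nodes[i], nodes[j]])
        d_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = d_new[keep]
        nodes = [nodes[k] for k in keep] + [new_node]

    a, b, c = nodes
    a.length = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    b.length = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    c.length = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    root = TreeNode(children=[a, b, c])
    return SupportTree(root=root, negative_branches_clamped=clamped)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(aln: Alignment, n_reps: int = 1000, seed: int = 0) -> SupportTree:
    """NJ tree of the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times (one block of
    column indices per replicate, in replicate order, from
    ``numpy.random.default_rng(seed)``); each replicate's tree contributes to
    the support of every full-data bipartition it contains. Support is the
    percentage of usable replicates; a replicate whose distances saturate
    (p >= 0.99) or lose all comparable sites is skipped and counted.
    """
    if aln.n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    if n_reps < 1:
        raise ValueError("need >= 1 bootstrap replicate")
    enc = aln.encoded()
    full_tree = neighbor_joining(DistanceMatrix(aln.ids, _poisson_from_encoded(enc)))
    splits = full_tree.bipartitions()
    counts = {split: 0 for split in splits}
    rng = np.random.default_rng(seed)
    skipped = 0
    used = 0
    for _ in range(n_reps):
        idx = rng.integers(0, aln.n_columns, size=aln.n_columns)
        try:
            d = _poisson_from_encoded(enc[:, idx])
        except ValueError:
            skipped += 1
            continue
        rep_tree = neighbor_joining(DistanceMatrix(aln.ids, d))
        used += 1
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    denom = max(used, 1)
    for split, node in splits.items():
        node.support = 100.0 * counts[split] / denom
    full_tree.bootstrap_replicates = used
    full_tree.skipped_replicates = skipped
    return full_tree


def find_sister_pairs(tree: SupportTree, support_min: float = 90.0) -> list[tuple[str, str]]:
    """Cherries whose subtending edge support is strictly above ``support_min``."""
    pairs = []
    for a, b, support in tree.cherries():
        if support is not None and support > support_min:
            pairs.append((a, b))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def _quote(name: str) -> str:
    if set(name) & _NEWICK_META:
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: SupportTree) -> str:
    """Newick string with branch lengths and integer supports as internal labels."""

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            return f"{_quote(node.name)}:{node.length:.6g}"  # type: ignore[arg-type]
        inner = ",".join(fmt(c, False) for c in node.children)
        label = "" if node.support is None else str(int(round(node.support)))
        if is_root:
            return f"({inner}){label}"
        return f"({inner}){label}:{node.length:.6g}"

    return fmt(tree.root, True) + ";"


def write_newick(tree: SupportTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(tree) + "\n")


def parse_newick(text: str) -> SupportTree:
    """Parse the Newick dialect written by :func:`to_newick` (round-trip stable)."""
    pos = 0
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    body = text[:-1]

    def read_label() -> str:
        nonlocal pos
        if pos < len(body) and body[pos] == "'":
            pos += 1
            out = []
            while True:
                if body[pos] == "'":
                    if pos + 1 < len(body) and body[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                    else:
                        pos += 1
                        break
                else:
                    out.append(body[pos])
                    pos += 1
            return "".join(out)
        start = pos
        while pos < len(body) and body[pos] not in ":,()":
            pos += 1
        return body[start:pos]

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if body[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while body[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if body[pos] != ")":
                raise ValueError(f"expected ')' at position {pos}")
            pos += 1
            label = read_label()
            if label:
                node.support = float(label)
        else:
            node.name = read_label()
        if pos < len(body) and body[pos] == ":":
            pos += 1
            start = pos
            while pos < len(body) and body[pos] not in ",()":
                pos += 1
            node.length = float(body[start:pos])
        return node

    root = parse_node()
    if pos != len(body):
        raise ValueError(f"trailing characters after position {pos}")
    return SupportTree(root=root)
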