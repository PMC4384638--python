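"""Rooted phylogenies and the covariance structure they induce on traits.

A time-like rooted tree with branch lengths implies, under Brownian-motion
trait evolution, a covariance between any two species equal to the branch
length they share on the path from the root to their most recent common
ancestor.  This module wraps :mod:`dendropy` for Newick I/O and pruning and
builds the phylogenetic variance--covariance (VCV) matrix, including Pagel's
lambda transform (off-diagonals scaled by lambda in [0, 1]).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "NewickParseError",
    "TreeError",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "phylo_vcv",
    "lambda_transform",
    "is_ultrametric",
]


class NewickParseError(ValueError):
    """Malformed Newick input (position of the offending token included)."""


class TreeError(ValueError):
    """Structurally invalid tree or invalid tree operation."""


def _prevalidate_newick(text: str) -> None:
    # dendropy is permissive; enforce the stricter contract here with
    # character positions so transcription errors are easy to locate.
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty Newick string")
    semi = stripped.find(";")
    if semi == -1:
        raise NewickParseError(
            f"missing terminal semicolon (string ends at position {len(stripped)})"
        )
    body = stripped[:semi]
    # strip bracketed comments before structural checks
    body = re.sub(r"\[[^\]]*\]", "", body)
    depth = 0
    for pos, ch in enumerate(body):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses: {depth} '(' unclosed at position {semi}"
        )
    for m in re.finditer(r":\s*(-[\d.eE+-]+)", body):
        raise NewickParseError(
            f"negative branch length {m.group(1)!r} at position {m.start(1)}"
        )


class PhyloTree:
    """A rooted, branch-length-bearing phylogeny with uniquely labeled leaves.

    Thin wrapper over a :class:`dendropy.Tree` that enforces the invariants
    the comparative machinery relies on (single root, unique non-empty leaf
    labels, non-negative branch lengths) and exposes the operations the
    analysis needs: Newick round-trip, pruning, VCV construction,
    ultrametricity checks and deterministic polytomy resolution.

    An optional *root edge* (a stem above the root) is retained when present;
    its length is shared by every pair of taxa and enters the VCV as a
    constant added to all entries.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._t = dtree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        _prevalidate_newick(text)
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises various error types
            raise NewickParseError(f"Newick parse failed: {exc}") from exc
        return cls(dtree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def _validate(self) -> None:
        labels = []
        for leaf in self._t.leaf_node_iter():
            lab = leaf.taxon.label if leaf.taxon is not None else None
            if not lab:
                raise TreeError("unlabeled leaf")
            labels.append(lab)
        if not labels:
            raise TreeError("empty tree")
        dup = {l for l in labels if labels.count(l) > 1}
        if dup:
            raise TreeError(f"duplicate leaf labels: {sorted(dup)}")
        for edge in self._t.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError(f"negative branch length {edge.length}")

    # -- basic queries ------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        """Leaf labels in canonical (alphabetical) order."""
        return sorted(l.taxon.label for l in self._t.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._t.leaf_node_iter())

    @property
    def root_edge_length(self) -> float:
        e = self._t.seed_node.edge
        return float(e.length) if e.length else 0.0

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (including any root edge)."""
        depths: dict[str, float] = {}
        offset = self.root_edge_length
        for leaf in self._t.leaf_node_iter():
            d = offset
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        """True iff all root-to-leaf depths agree to ``rel_tol`` (relative)."""
        depths = np.array(list(self.leaf_depths().values()))
        dmax = depths.max()
        if dmax == 0:
            return True
        return bool((dmax - depths.min()) <= rel_tol * dmax)

    # -- Newick output ------------------------------------------------

    def to_newick(self) -> str:
        s = self._t.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        ).strip()
        return s

    def write_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- structural operations ----------------------------------------

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._t.clone(depth=1))

    def prune_to(self, keep, drop_root_edge: bool = False) -> "PhyloTree":
        """Restrict the tree to the leaves in ``keep``.

        Unary nodes created by pruning are suppressed with their branch
        lengths summed.  By default the residual path from the original root
        down to the retained leaves' MRCA is kept as a root edge, so every
        retained leaf keeps its original root-to-leaf depth and the VCV of
        the pruned tree equals the corresponding submatrix of the original
        VCV exactly.  With ``drop_root_edge=True`` that stem is discarded and
        depths are measured from the new root.
        """
        keep = set(keep)
        if not keep:
            raise TreeError("keep set is empty")
        missing = sorted(keep - set(self.leaf_labels))
        if missing:
            raise TreeError(f"labels not in tree: {missing}")
        t = self._t.clone(depth=1)
        t.retain_taxa_with_labels(sorted(keep))
        # Collapse any chain of unifurcations at the root into a root edge.
        stem = t.seed_node.edge.length or 0.0
        while len(t.seed_node.child_nodes()) == 1 and len(keep) > 1:
            child = t.seed_node.child_nodes()[0]
            stem += child.edge.length or 0.0
            child.parent_node = None
            t.seed_node = child
        t.seed_node.edge.length = None if drop_root_edge else (stem or None)
        return PhyloTree(t)

    def resolve_polytomies(self) -> "PhyloTree":
        """Binary tree with zero-length edges resolving multifurcations.

        Resolution is deterministic: at each multifurcation children are
        sorted by the smallest leaf label in their subtree and combined
        left-to-right under zero-length internal branches, which leaves the
        implied covariance matrix unchanged.
        """
        t = self._t.clone(depth=1)
        minlab: dict[int, str] = {}
        for node in t.postorder_node_iter():
            if node.is_leaf():
                minlab[id(node)] = node.taxon.label
            else:
                minlab[id(node)] = min(minlab[id(c)] for c in node.child_nodes())
        for node in list(t.preorder_node_iter()):
            kids = node.child_nodes()
            if len(kids) <= 2:
                continue
            kids = sorted(kids, key=lambda c: minlab[id(c)])
            for k in kids:
                node.remove_child(k)
            left = kids[0]
            for k in kids[1:-1]:
                newn = dendropy.Node()
                newn.edge.length = 0.0
                newn.add_child(left)
                newn.add_child(k)
                minlab[id(newn)] = min(minlab[id(left)], minlab[id(k)])
                left = newn
            node.add_child(left)
            node.add_child(kids[-1])
        return PhyloTree(t)

    def vcv(self) -> "PhyloCovariance":
        """Phylogenetic variance--covariance matrix (untransformed).

        Entry (i, j) is the root-to-MRCA path length of taxa i and j;
        the diagonal holds root-to-leaf depths.  Taxa are in canonical
        (alphabetical) order.
        """
        taxa = self.leaf_labels
        if not taxa:
            raise TreeError("empty tree")
        idx = {lab: i for i, lab in enumerate(taxa)}
        n = len(taxa)
        V = np.zeros((n, n))
        offset = self.root_edge_length
        # node depth measured from the root (excluding the root edge)
        depth: dict[int, float] = {id(self._t.seed_node): 0.0}
        for node in self._t.preorder_node_iter():
            if node.parent_node is not None:
                depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
        # leaves under each node; covariance of cross-child pairs = node depth
        leaves_below: dict[int, list[int]] = {}
        for node in self._t.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                leaves_below[id(node)] = [i]
                V[i, i] = depth[id(node)]
            else:
                kids = [leaves_below[id(c)] for c in node.child_nodes()]
                d = depth[id(node)]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                V[i, j] = V[j, i] = d
                leaves_below[id(node)] = [i for k in kids for i in k]
        V += offset
        return PhyloCovariance(taxa=taxa, matrix=V, lambda_applied=None)

    def __repr__(self) -> str:
        return f"PhyloTree(n_leaves={self.n_leaves})"


@dataclass
class PhyloCovariance:
    """Phylogenetic VCV matrix over an ordered taxon list.

    ``lambda_applied`` is ``None`` for the untransformed Brownian matrix, or
    the value of Pagel's lambda if :func:`lambda_transform` has been applied.
    """

    taxa: list[str]
    matrix: np.ndarray
    lambda_applied: float | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise TreeError("matrix shape does not match taxon list")
        if not np.allclose(self.matrix, self.matrix.T):
            raise TreeError("covariance matrix is not symmetric")

    def transform(self, lam: float) -> "PhyloCovariance":
        """Pagel's lambda transform: off-diagonals scaled by ``lam``."""
        if self.lambda_applied is not None:
            raise TreeError("lambda transform already applied")
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        V = self.matrix * lam
        np.fill_diagonal(V, np.diag(self.matrix))
        return PhyloCovariance(taxa=list(self.taxa), matrix=V, lambda_applied=lam)

    def reorder(self, taxa: list[str]) -> "PhyloCovariance":
        if sorted(taxa) != sorted(self.taxa):
            raise TreeError("taxon sets differ")
        perm = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(
            taxa=list(taxa),
            matrix=self.matrix[np.ix_(perm, perm)],
            lambda_applied=self.lambda_applied,
        )


# -- functional surface ------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick description with branch lengths."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def prune_to_taxa(tree: PhyloTree, keep, drop_root_edge: bool = False) -> PhyloTree:
    return tree.prune_to(keep, drop_root_edge=drop_root_edge)


def phylo_vcv(tree: PhyloTree) -> PhyloCovariance:
    return tree.vcv()


def lambda_transform(V: PhyloCovariance, lam: float) -> PhyloCovariance:
    return V.transform(lam)


def is_ultrametric(tree: PhyloTree, rel_tol: float = 1e-6) -> bool:
    return tree.is_ultrametric(rel_tol)
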