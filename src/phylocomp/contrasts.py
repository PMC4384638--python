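"""Felsenstein's phylogenetically independent contrasts.

Under Brownian motion, the standardized difference between the trait values
of two sister lineages is independent of every other such difference.  The
pruning recursion below computes one contrast per internal node of a fully
resolved tree: daughters are averaged with weights inverse to their branch
lengths, and the parent's branch is lengthened by v1*v2/(v1+v2) to account
for the uncertainty of the reconstructed ancestral value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import PhyloTree, TreeError

__all__ = ["ContrastSet", "felsenstein_contrasts"]

#: floor applied to expected contrast variances before standardization, so
#: zero-length resolving branches cannot produce a divide-by-zero
VARIANCE_EPS = 1e-12


@dataclass
class ContrastSet:
    """Standardized contrasts for one trait with their node provenance.

    ``node_ids`` identifies each internal node by the smallest leaf labels of
    its two daughter subtrees, so contrast sets computed from the same tree
    align pair-by-pair regardless of input leaf order.
    """

    contrasts: np.ndarray
    expected_variances: np.ndarray
    node_ids: list[str]
    n_taxa: int

    def __post_init__(self):
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        self.expected_variances = np.asarray(self.expected_variances, dtype=float)
        if len(self.contrasts) != len(self.node_ids):
            raise ValueError("contrasts and node_ids length mismatch")

    def __len__(self) -> int:
        return len(self.contrasts)


def felsenstein_contrasts(tree: PhyloTree, trait) -> ContrastSet:
    """Standardized independent contrasts of ``trait`` on ``tree``.

    Parameters
    ----------
    tree
        Rooted tree with branch lengths.  Polytomies are resolved
        deterministically with zero-length branches first.
    trait
        Mapping from leaf label to trait value; every leaf must be covered.

    Returns
    -------
    ContrastSet
        One contrast per internal node (n_taxa - 1 of them), emitted in
        postorder with children visited in sorted-label order, each equal to
        (x1 - x2) / sqrt(v1' + v2') where v' are the lengthened branches of
        the pruning recursion.
    """
    trait = dict(trait)
    missing = [l for l in tree.leaf_labels if l not in trait]
    if missing:
        raise TreeError(f"trait missing for leaves: {missing}")
    rt = tree.resolve_polytomies()
    root = rt._t.seed_node

    # minimum leaf label per subtree -> deterministic child ordering
    minlab: dict[int, str] = {}
    for node in rt._t.postorder_node_iter():
        if node.is_leaf():
            minlab[id(node)] = node.taxon.label
        else:
            minlab[id(node)] = min(minlab[id(c)] for c in node.child_nodes())

    contrasts: list[float] = []
    variances: list[float] = []
    node_ids: list[str] = []

    def visit(node):
        """Return (reconstructed value, lengthened branch length above node)."""
        blen = node.edge.length or 0.0
        if node.is_leaf():
            return float(trait[node.taxon.label]), blen
        kids = sorted(node.child_nodes(), key=lambda c: minlab[id(c)])
        if len(kids) != 2:  # pragma: no cover - guarded by resolve_polytomies
            raise TreeError("tree not fully resolved")
        x1, v1 = visit(kids[0])
        x2, v2 = visit(kids[1])
        vsum = max(v1 + v2, VARIANCE_EPS)
        contrasts.append((x1 - x2) / np.sqrt(vsum))
        variances.append(vsum)
        node_ids.append(f"{minlab[id(kids[0])]}|{minlab[id(kids[1])]}")
        if x1 == x2:  # keeps contrasts of a constant trait exactly zero
            xa = x1
        else:
            w1, w2 = 1.0 / max(v1, VARIANCE_EPS), 1.0 / max(v2, VARIANCE_EPS)
            xa = (w1 * x1 + w2 * x2) / (w1 + w2)
        return xa, blen + v1 * v2 / vsum

    # postorder emission ordered by the recursion itself
    visit(root)
    return ContrastSet(
        contrasts=np.array(contrasts),
        expected_variances=np.array(variances),
        node_ids=node_ids,
        n_taxa=tree.n_leaves,
    )
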