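"""Rooted phylogenetic trees and the covariance structures PGLS needs.

Trees are thin wrappers around :class:`dendropy.Tree` restricted to the
operations the body-mass pipeline requires: Newick round-tripping, polytomy
resolution, pruning to a taxon subset, and conversion to a phylogenetic
variance-covariance (VCV) matrix with Pagel's lambda scaling.

Branch lengths are treated as divergence time (My); no rescaling is applied.
Tip labels are normalized by trimming whitespace and mapping underscores to
spaces, so that tree files and trait tables written with either convention
match.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "CovarianceStructure",
    "NewickParseError",
    "normalize_label",
    "parse_newick",
    "write_newick",
    "resolve_polytomies",
    "prune_to_taxa",
    "vcv_from_tree",
    "lambda_transform",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be interpreted as a rooted tree."""


def normalize_label(label: str) -> str:
    """Trim whitespace and collapse underscores/runs of spaces to one space."""
    return re.sub(r"\s+", " ", label.replace("_", " ").strip())


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, wrapping a dendropy tree.

    The seed (root) node may carry its own subtending edge length; that edge
    is shared by every tip and is included in depths and covariances, which
    is what makes pruning depth-preserving.
    """

    _dtree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [normalize_label(lf.taxon.label) for lf in self._dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._dtree.leaf_node_iter())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._dtree.clone(depth=1))

    def is_binary(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self._dtree.preorder_internal_node_iter()
        )

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip, including the seed edge."""
        out: dict[str, float] = {}
        root_edge = self._dtree.seed_node.edge.length or 0.0
        for lf in self._dtree.leaf_node_iter():
            d = 0.0
            nd = lf
            while nd.parent_node is not None:
                d += _edge_length(nd)
                nd = nd.parent_node
            out[normalize_label(lf.taxon.label)] = d + root_edge
        return out

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        d = np.array(list(self.depths().values()))
        return bool(np.ptp(d) <= tol * max(1.0, d.max()))

    def rename_tips(self, mapping: Mapping[str, str]) -> "PhyloTree":
        """Return a copy with tip labels replaced via a synonym map."""
        norm = {normalize_label(k): v for k, v in mapping.items()}
        out = self.copy()
        for lf in out._dtree.leaf_node_iter():
            lab = normalize_label(lf.taxon.label)
            if lab in norm:
                lf.taxon.label = norm[lab]
        return out

    def write_newick(self) -> str:
        s = self._dtree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    # convenience aliases mirroring the module-level API
    def resolve_polytomies(self, seed: int) -> "PhyloTree":
        return resolve_polytomies(self, seed)

    def prune_to_taxa(self, keep: Iterable[str]) -> "PhyloTree":
        return prune_to_taxa(self, keep)

    def vcv(self, taxa: Sequence[str] | None = None) -> "CovarianceStructure":
        return vcv_from_tree(self, taxa)


def _edge_length(node: dendropy.Node) -> float:
    if node.edge.length is None:
        raise ValueError(
            f"branch length missing on edge above "
            f"{node.taxon.label if node.taxon else 'an internal node'}"
        )
    return float(node.edge.length)


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick description.

    Raises :class:`NewickParseError` for malformed input or duplicate tip
    labels; a missing branch length is tolerated here and only rejected when
    a covariance matrix is requested.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several unrelated types
        raise NewickParseError(f"invalid Newick string: {exc}") from exc
    tree = PhyloTree(dtree)
    labels = tree.tip_labels
    if any(not lab for lab in labels):
        raise NewickParseError("empty tip label in Newick string")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise NewickParseError(f"duplicate tip label: {lab!r}")
        seen.add(lab)
    return tree


def write_newick(tree: PhyloTree) -> str:
    return tree.write_newick()


def resolve_polytomies(tree: PhyloTree, seed: int) -> PhyloTree:
    """Arbitrarily resolve every polytomy with zero-length internal branches.

    The resolution order is randomized under ``seed``; because all inserted
    branches have length 0, every resolution yields the same tip covariance
    matrix, so the arbitrariness is statistically inconsequential.
    """
    out = tree.copy()
    out._dtree.resolve_polytomies(rng=random.Random(seed))
    for nd in out._dtree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            nd.edge.length = 0.0
    return out


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Restrict the tree to ``keep``, preserving depths and shared paths.

    Degree-2 internal nodes created by the pruning are suppressed with their
    branch lengths summed; the path above the surviving subtree is retained
    as the seed node's edge so root-to-tip depths are unchanged.
    """
    keep_norm = [normalize_label(k) for k in keep]
    present = set(tree.tip_labels)
    missing = sorted(set(keep_norm) - present)
    if missing:
        raise ValueError(f"taxa not in tree: {', '.join(missing)}")
    out = tree.copy()
    label_of = {lf.taxon.label: normalize_label(lf.taxon.label)
                for lf in out._dtree.leaf_node_iter()}
    out._dtree.retain_taxa_with_labels(
        [raw for raw, norm in label_of.items() if norm in set(keep_norm)]
    )
    return out


@dataclass
class CovarianceStructure:
    """Phylogenetic VCV: shared root-to-MRCA path lengths, with λ scaling.

    ``C[i, j]`` is the branch length shared between taxa *i* and *j* from the
    root down to their most recent common ancestor; the diagonal holds
    root-to-tip depths.  ``V`` is the Pagel's-λ transform: off-diagonals
    multiplied by λ, diagonal untouched.
    """

    taxa: tuple[str, ...]
    C: np.ndarray
    lam: float | None = None
    V: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.taxa)
        if self.C.shape != (n, n):
            raise ValueError("C must be square and aligned with taxa")

    def with_lambda(self, lam: float) -> "CovarianceStructure":
        return lambda_transform(self, lam)

    def matrix(self) -> np.ndarray:
        """The λ-scaled matrix if λ is set, else the raw C."""
        return self.C if self.V is None else self.V


def vcv_from_tree(tree: PhyloTree, taxa: Sequence[str] | None = None) -> CovarianceStructure:
    """Build the phylogenetic VCV for ``taxa`` (default: all tips, tree order).

    Accumulates each edge's length into the covariance of every pair of
    requested tips descended from it; works on polytomous trees and counts
    the seed node's own edge (shared by all tips).
    """
    tips_in_order = tree.tip_labels
    if taxa is None:
        order = tips_in_order
    else:
        order = [normalize_label(t) for t in taxa]
        missing = sorted(set(order) - set(tips_in_order))
        if missing:
            raise ValueError(f"taxa not in tree: {', '.join(missing)}")
        if len(set(order)) != len(order):
            raise ValueError("requested taxa contain duplicates")
    idx = {lab: i for i, lab in enumerate(order)}
    n = len(order)
    C = np.zeros((n, n))

    dtree = tree._dtree
    # postorder pass: per-node boolean membership over requested tips
    masks: dict[int, np.ndarray] = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            m = np.zeros(n, dtype=bool)
            i = idx.get(normalize_label(nd.taxon.label))
            if i is not None:
                m[i] = True
        else:
            m = np.zeros(n, dtype=bool)
            for ch in nd.child_nodes():
                m |= masks.pop(id(ch))
        masks[id(nd)] = m
        if not m.any():
            continue
        if nd.parent_node is None:
            ell = nd.edge.length or 0.0  # seed edge may be absent
        else:
            ell = _edge_length(nd)
        if ell:
            sub = np.flatnonzero(m)
            C[np.ix_(sub, sub)] += ell
    return CovarianceStructure(taxa=tuple(order), C=C)


def lambda_transform(cov: CovarianceStructure, lam: float) -> CovarianceStructure:
    """Scale off-diagonal covariances by Pagel's λ ∈ [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    V = lam * cov.C
    np.fill_diagonal(V, np.diag(cov.C))
    return CovarianceStructure(taxa=cov.taxa, C=cov.C, lam=float(lam), V=V)
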