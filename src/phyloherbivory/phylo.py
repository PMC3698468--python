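"""Rooted phylogenies and the Brownian-motion correlation matrix.

A community phylogeny enters the analysis only through the matrix of
expected trait correlations under Brownian motion: the covariance between
two tips is the depth (root-to-MRCA path length) of their most recent
common ancestor, and standardising by the tip depths yields a correlation
matrix with unit diagonal.  For an ultrametric tree this is MRCA depth
divided by tree depth.  The correlation form is what the diversity indices
(PSV/PSE) consume.

Trees are held as :class:`dendropy.Tree` objects wrapped in a thin
:class:`Phylogeny` value type that enforces the invariants the pipeline
relies on (unique tip labels, branch lengths present and non-negative).
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "PhylogenyError",
    "read_newick",
    "prune",
    "brownian_correlation",
    "write_correlation_tsv",
]

#: Relative tolerance on root-to-tip distance spread below which a tree is
#: considered ultrametric (all tips equidistant from the root).
ULTRAMETRIC_RTOL = 1e-6


class PhylogenyError(ValueError):
    """Invalid tree input (parse failure, duplicate labels, bad branch lengths)."""


class Phylogeny:
    """A rooted tree with branch lengths, validated for downstream use.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree` with branch lengths on every
        non-root edge.  The tree is not copied; treat it as owned.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- validation -----------------------------------------------------

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise PhylogenyError("tree contains an unlabeled tip")
            labels.append(leaf.taxon.label)
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise PhylogenyError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue  # root edge may legitimately lack a length
            if edge.length is None:
                head = edge.head_node
                name = head.taxon.label if head.taxon else "<internal node>"
                raise PhylogenyError(f"missing branch length on edge above {name}")
            if edge.length < 0:
                raise PhylogenyError(f"negative branch length {edge.length}")

    # -- basic queries --------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def root_to_tip_distances(self) -> dict[str, float]:
        """Path length from the root to every tip, keyed by tip label."""
        root_edge = self._tree.seed_node.edge.length or 0.0
        dists: dict[str, float] = {}
        for leaf in self._tree.leaf_node_iter():
            d = root_edge
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            dists[leaf.taxon.label] = d
        return dists

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        """True when all root-to-tip distances agree to relative tolerance."""
        d = np.array(list(self.root_to_tip_distances().values()))
        dmax = d.max()
        if dmax == 0.0:
            return True
        return (dmax - d.min()) / dmax <= rtol

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips})"


def read_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree from a string.

    Branch lengths are required on every non-root edge; duplicate tip
    labels are rejected.  Unlabeled internal nodes are fine.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        msg = str(exc)
        if "Duplicate taxon labels" in msg:
            label = msg.rsplit(":", 1)[-1].strip()
            raise PhylogenyError(f"duplicate tip label: {label!r}") from exc
        raise PhylogenyError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def read_newick_file(path) -> Phylogeny:
    """Read a single Newick tree from a file path."""
    with open(path, encoding="utf-8") as fh:
        return read_newick(fh.read())


def prune(phylogeny: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Induced subtree on ``keep``, preserving root-to-tip distances.

    Degree-2 internal nodes created by pruning are collapsed with their
    branch lengths summed.  Requires at least two kept tips.
    """
    keep = set(keep)
    tips = set(phylogeny.tip_labels)
    unknown = sorted(keep - tips)
    if unknown:
        raise PhylogenyError(f"{unknown[0]!r} not a tip (and {len(unknown) - 1} more)" if len(unknown) > 1 else f"{unknown[0]!r} not a tip")
    if len(keep) < 2:
        raise PhylogenyError("pruning requires at least 2 tips to keep")
    sub = phylogeny.tree.extract_tree_with_taxa_labels(keep)
    # extract_tree keeps a possibly length-bearing root edge; fold it away so
    # the root is the MRCA-side root with distances intact.
    return Phylogeny(sub)


def brownian_correlation(phylogeny: Phylogeny) -> pd.DataFrame:
    """Brownian-motion trait correlation matrix among tips.

    ``cov[i, j]`` is the shared root-to-MRCA path length of tips *i* and
    *j*; the returned matrix is the correlation form
    ``cov[i, j] / sqrt(cov[i, i] * cov[j, j])``, a symmetric PSD matrix
    with unit diagonal, invariant to uniform branch-length rescaling.
    For non-ultrametric trees the standardisation still applies but a
    warning is emitted, since the [0, 1] range guarantees of PSE are
    stated for the ultrametric/star standardisation.
    """
    tree = phylogeny.tree
    if phylogeny.n_tips < 2:
        raise PhylogenyError("correlation matrix requires >= 2 tips")

    # depth of every node measured from the start of the root edge (a
    # retained root edge, e.g. after pruning to a subclade, is shared
    # history for every tip)
    depth: dict[int, float] = {id(tree.seed_node): tree.seed_node.edge.length or 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    cov = np.zeros((n, n))

    # postorder accumulation: the MRCA of any pair of tips in different
    # child subtrees of a node is that node, so fill cov at the join.
    tipsets: dict[int, list[int]] = {}
    index = {id(lf): i for i, lf in enumerate(leaves)}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[id(node)] = [index[id(node)]]
            cov[index[id(node)], index[id(node)]] = depth[id(node)]
            continue
        children = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.asarray(children[a])
                ib = np.asarray(children[b])
                cov[np.ix_(ia, ib)] = d
                cov[np.ix_(ib, ia)] = d
        tipsets[id(node)] = [i for ch in children for i in ch]

    diag = np.diag(cov).copy()
    if np.any(diag <= 0):
        bad = labels[int(np.argmin(diag))]
        raise PhylogenyError(f"degenerate tree: tip {bad!r} has zero root-to-tip depth")
    if not phylogeny.is_ultrametric():
        warnings.warn(
            "tree is not ultrametric; standardising covariances to correlation "
            "form by the tip depths",
            stacklevel=2,
        )
    corr = cov / np.sqrt(np.outer(diag, diag))
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=labels, columns=labels)


def write_correlation_tsv(corr: pd.DataFrame, path) -> None:
    """Export a labeled correlation matrix as TSV."""
    corr.to_csv(path, sep="\t", index_label="tip")
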