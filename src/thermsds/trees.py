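"""Phylogeny container backed by dendropy with cached comparative-method matrices.

The comparative machinery needs three things from a tree: tip labels, the
shared-path-length (Brownian covariance) matrix, and patristic distances.
Both are computed once and cached; dendropy handles Newick parsing/writing.
"""
from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np


class TreeError(ValueError):
    """Base class for phylogeny validation problems."""


class NewickParseError(TreeError):
    """The Newick string could not be parsed."""


class MissingBranchLengthError(TreeError):
    """An edge has no branch length."""


class DuplicateLabelError(TreeError):
    """Two tips share the same label."""


class ZeroTerminalBranchError(TreeError):
    """A terminal branch has zero (or negative) length."""


class Phylogeny:
    """A rooted tree with strictly positive branch lengths and unique tip labels.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree`. Every non-root edge must carry a
        strictly positive length; terminal branches of zero length are
        rejected because they make the phylogenetic covariance singular.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._tip_labels: list[str] = [
            lf.taxon.label for lf in tree.leaf_node_iter()
        ]
        self._index = {lab: i for i, lab in enumerate(self._tip_labels)}
        self._cov: np.ndarray | None = None
        self._dist: np.ndarray | None = None

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parser errors
            if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
                raise DuplicateLabelError(str(exc)) from exc
            raise NewickParseError(f"could not parse Newick input: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def star(cls, labels: Sequence[str], depth: float = 1.0) -> "Phylogeny":
        """A star phylogeny: every tip attached to the root at distance *depth*."""
        newick = "(" + ",".join(f"{lab}:{depth}" for lab in labels) + ");"
        return cls.from_newick(newick)

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def _validate(self) -> None:
        seen: set[str] = set()
        n_tips = 0
        for node in self._tree.preorder_node_iter():
            is_root = node.parent_node is None
            length = node.edge.length
            if not is_root:
                if length is None:
                    raise MissingBranchLengthError(
                        "every non-root edge needs a branch length"
                    )
                if node.is_leaf() and length <= 0:
                    raise ZeroTerminalBranchError(
                        f"terminal branch of tip {node.taxon.label!r} has "
                        f"non-positive length {length}"
                    )
                if length <= 0:
                    raise TreeError(f"non-positive internal branch length {length}")
            if node.is_leaf():
                n_tips += 1
                if node.taxon is None or node.taxon.label is None:
                    raise TreeError("unlabeled tip")
                if node.taxon.label in seen:
                    raise DuplicateLabelError(
                        f"duplicate tip label {node.taxon.label!r}"
                    )
                seen.add(node.taxon.label)
        if n_tips < 2:
            raise TreeError("a phylogeny needs at least two tips")

    # ------------------------------------------------------------------
    # basic accessors
    # ------------------------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def index_of(self, labels: Sequence[str]) -> np.ndarray:
        """Positions of *labels* in tip order; raises on unknown labels."""
        try:
            return np.array([self._index[lab] for lab in labels], dtype=int)
        except KeyError as exc:
            raise TreeError(f"label {exc.args[0]!r} is not a tip of the tree")

    # ------------------------------------------------------------------
    # comparative-method matrices
    # ------------------------------------------------------------------
    def _compute_cov(self) -> np.ndarray:
        n = self.n_tips
        cov = np.zeros((n, n))
        depth: dict[int, float] = {}
        tipsets: dict[int, list[int]] = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            d = 0.0 if parent is None else depth[id(parent)] + node.edge.length
            depth[id(node)] = d
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = self._index[node.taxon.label]
                cov[i, i] = depth[id(node)]
                tipsets[id(node)] = [i]
            else:
                groups = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
                d = depth[id(node)]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        ia = np.array(groups[a])[:, None]
                        ib = np.array(groups[b])[None, :]
                        cov[ia, ib] = d
                        cov[ib.T, ia.T] = d
                merged: list[int] = []
                for g in groups:
                    merged.extend(g)
                tipsets[id(node)] = merged
        return cov

    @property
    def cov(self) -> np.ndarray:
        """Shared-path-length matrix (Brownian-motion covariance), tip order."""
        if self._cov is None:
            self._cov = self._compute_cov()
        return self._cov

    @property
    def distances(self) -> np.ndarray:
        """Patristic distance matrix: d_ij = t_i + t_j - 2 s_ij."""
        if self._dist is None:
            c = self.cov
            t = np.diag(c)
            self._dist = t[:, None] + t[None, :] - 2.0 * c
            np.fill_diagonal(self._dist, 0.0)
        return self._dist

    @property
    def tip_depths(self) -> np.ndarray:
        return np.diag(self.cov).copy()

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        return float(self.tip_depths.max())

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        t = self.tip_depths
        return bool(np.ptp(t) <= rel_tol * max(t.max(), 1e-300))

    def scaled_to_depth(self, target: float) -> "Phylogeny":
        """Return a copy with all branch lengths rescaled so max depth = target."""
        if target <= 0:
            raise TreeError("target depth must be positive")
        factor = target / self.depth
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return Phylogeny(clone)

    def subset(self, labels: Sequence[str]) -> "Phylogeny":
        """Prune to the given tip labels (unifurcations suppressed)."""
        keep = set(labels)
        missing = keep - set(self._tip_labels)
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)[:5]}")
        if len(keep) < 2:
            raise TreeError("a pruned phylogeny needs at least two tips")
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True
        )
        return Phylogeny(sub)

    # ------------------------------------------------------------------
    # IO / misc
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        """The underlying dendropy tree (shared, do not mutate)."""
        return self._tree

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, depth={self.depth:.4g})"
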