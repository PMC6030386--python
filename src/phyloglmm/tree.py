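"""Phylogenetic tip-to-tip (patristic) distances.

A rooted or unrooted Newick tree with branch lengths induces, for every
pair of tips, the patristic distance: the sum of branch lengths along the
shortest path connecting the two tips.  These distances drive the
phylogeny-induced correlation structure among OTU effects (see
:mod:`phyloglmm.kernel`).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import skbio


class AlignmentError(ValueError):
    """OTU labels in an abundance table do not match the tree tips."""


@dataclass
class PhyloDistances:
    """Tip labels plus the symmetric patristic distance matrix.

    Parameters
    ----------
    tip_labels
        Ordered, unique OTU identifiers (the tree tips).
    D
        ``(p, p)`` symmetric non-negative matrix of patristic distances in
        branch-length units, with a zero diagonal.  ``D[i, j]`` is the
        distance between ``tip_labels[i]`` and ``tip_labels[j]``.
    """

    tip_labels: list[str]
    D: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.tip_labels = [str(t) for t in self.tip_labels]
        D = np.asarray(self.D, dtype=float)
        p = len(self.tip_labels)
        if len(set(self.tip_labels)) != p:
            raise ValueError("tip labels must be unique")
        if D.shape != (p, p):
            raise ValueError(f"distance matrix shape {D.shape} does not match {p} tips")
        if not np.all(np.isfinite(D)):
            raise ValueError("distance matrix must be finite")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(D < 0):
            raise ValueError("distances must be non-negative")
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        self.D = D

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @classmethod
    def from_newick(cls, source: str | os.PathLike | io.TextIOBase) -> "PhyloDistances":
        """Read a Newick tree (file path, handle, or literal string)."""
        if isinstance(source, str) and not os.path.exists(source):
            source = io.StringIO(source)
        tree = skbio.TreeNode.read(source, format="newick")
        return cls.from_tree(tree)

    @classmethod
    def from_tree(cls, tree: skbio.TreeNode) -> "PhyloDistances":
        dm = tree.tip_tip_distances()
        return cls(tip_labels=list(dm.ids), D=np.asarray(dm.data, dtype=float))

    def reorder(self, labels: list[str]) -> "PhyloDistances":
        """Restrict/reorder to ``labels`` (all must be tips)."""
        index = {t: i for i, t in enumerate(self.tip_labels)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise AlignmentError(
                f"{len(missing)} OTU label(s) not found among tree tips, "
                f"e.g. {missing[:5]}"
            )
        idx = np.array([index[l] for l in labels])
        return PhyloDistances(list(labels), self.D[np.ix_(idx, idx)])

    def rescaled(self) -> "PhyloDistances":
        """Divide distances by the median off-diagonal value.

        Distances are not rescaled anywhere by default; this is an opt-in
        convenience so that one grid of the evolutionary-rate parameter
        transfers across trees built with different branch-length scales.
        """
        off = self.D[np.triu_indices(self.n_tips, k=1)]
        med = np.median(off)
        if med <= 0:
            return PhyloDistances(list(self.tip_labels), self.D.copy())
        return PhyloDistances(list(self.tip_labels), self.D / med)

    def align_columns(self, table_labels: list[str]) -> np.ndarray:
        """Indices into ``tip_labels`` matching ``table_labels`` order."""
        index = {t: i for i, t in enumerate(self.tip_labels)}
        try:
            return np.array([index[l] for l in table_labels])
        except KeyError as exc:
            raise AlignmentError(f"OTU label {exc} is not a tip of the tree") from None
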