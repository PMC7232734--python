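"""Module detection: average-linkage clustering of the TOM dissimilarity
followed by a static fixed-height cut or a branch-shape dynamic cut.

The dynamic cut walks the dendrogram top-down.  A subtree is accepted as a
branch when the height drop from its parent's merge to its own top merge
exceeds a threshold — a fraction of the tree's merge-height range
controlled by ``deep_split`` (0 conservative .. 4 aggressive).  Accepted
branches are split further whenever both children are themselves
sufficiently separated branches of at least ``min_module_size`` leaves;
leaves that never fall inside an accepted branch stay unassigned ("grey").
This finds the tight low-height clusters that a single fixed-height cut
misses when background genes merge just below the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .palette import UNASSIGNED, module_label

DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_DEEP_SPLIT = 2

# deep_split 0..4 -> required branch gap as a fraction of the height range
_GAP_FRACTIONS = (0.45, 0.35, 0.25, 0.15, 0.05)


@dataclass
class Dendrogram:
    """An average-linkage merge tree over named leaves."""

    labels: list[str]
    Z: np.ndarray = field(repr=False)  # scipy linkage matrix

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.Z[:, 2]


@dataclass
class ModulePartition:
    """Gene -> module-label assignment for one tissue; "grey" = unassigned."""

    tissue: str
    assignment: dict[str, str]
    min_module_size: int

    def modules(self) -> dict[str, set[str]]:
        """Non-grey module label -> member gene set."""
        out: dict[str, set[str]] = {}
        for g, lab in self.assignment.items():
            if lab != UNASSIGNED:
                out.setdefault(lab, set()).add(g)
        return out

    @property
    def n_modules(self) -> int:
        return len(self.modules())

    @property
    def n_unassigned(self) -> int:
        return sum(1 for lab in self.assignment.values() if lab == UNASSIGNED)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.assignment)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "tissue": self.tissue,
                "module_label": [self.assignment[g] for g in genes],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, min_module_size: int = 0) -> "ModulePartition":
        df = pd.read_csv(path, sep="\t", dtype=str)
        tissues = df["tissue"].unique()
        if len(tissues) != 1:
            raise ValueError(f"expected a single tissue per file, got {list(tissues)}")
        return cls(
            tissue=tissues[0],
            assignment=dict(zip(df["gene_id"], df["module_label"])),
            min_module_size=min_module_size,
        )


def hclust_average(D: np.ndarray, labels: list[str]) -> Dendrogram:
    """Average-linkage (UPGMA) tree of a symmetric dissimilarity matrix."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if len(labels) != D.shape[0]:
        raise ValueError("labels must match matrix dimension")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-10:
        raise ValueError("dissimilarity diagonal must be zero")
    if D.min() < -1e-12:
        raise ValueError("dissimilarity must be nonnegative")
    Ds = (D + D.T) / 2.0
    np.fill_diagonal(Ds, 0.0)
    Z = linkage(squareform(Ds, checks=False), method="average")
    return Dendrogram(list(labels), Z)


def _label_partition(
    tissue: str,
    clusters: list[set[str]],
    all_genes: list[str],
    min_module_size: int,
) -> ModulePartition:
    """Drop undersized clusters, order survivors by size, name from palette."""
    keep = [c for c in clusters if len(c) >= min_module_size]
    # deterministic: by decreasing size, then smallest member gene id
    keep.sort(key=lambda c: (-len(c), min(c)))
    assignment = {g: UNASSIGNED for g in all_genes}
    for rank, c in enumerate(keep):
        lab = module_label(rank)
        for g in c:
            assignment[g] = lab
    return ModulePartition(tissue, assignment, min_module_size)


def static_cut(
    dend: Dendrogram,
    height: float,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    tissue: str = "",
) -> ModulePartition:
    """Fixed-height cut: connected components below ``height``."""
    if height < 0:
        raise ValueError("cut height must be nonnegative")
    flat = fcluster(dend.Z, t=height, criterion="distance")
    clusters: dict[int, set[str]] = {}
    for g, c in zip(dend.labels, flat):
        clusters.setdefault(int(c), set()).add(g)
    return _label_partition(tissue, list(clusters.values()), dend.labels, min_module_size)


def _build_tree(Z: np.ndarray, n: int):
    """Children, heights and leaf counts for every internal node."""
    heights = np.zeros(2 * n - 1)
    counts = np.ones(2 * n - 1, dtype=int)
    children = {}
    for i in range(n - 1):
        a, b, h, c = int(Z[i, 0]), int(Z[i, 1]), Z[i, 2], int(Z[i, 3])
        node = n + i
        children[node] = (a, b)
        heights[node] = h
        counts[node] = c
    return children, heights, counts


def _leaves_of(node: int, children, n: int) -> list[int]:
    stack, out = [node], []
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            stack.extend(children[v])
    return out


def dynamic_cut(
    dend: Dendrogram,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    deep_split: int = DEFAULT_DEEP_SPLIT,
    tissue: str = "",
) -> ModulePartition:
    """Branch-shape dynamic cut of an average-linkage dendrogram.

    A subtree qualifies as a branch when its top merge sits at least
    ``gap`` below its parent's merge, where ``gap`` is a ``deep_split``-
    controlled fraction of the tree's merge-height range.  Qualifying
    branches are recursively split while both children also qualify;
    everything outside accepted branches is left grey.
    """
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    n = dend.n_leaves
    if n == 1:
        lab = module_label(0) if min_module_size <= 1 else UNASSIGNED
        return ModulePartition(tissue, {dend.labels[0]: lab}, min_module_size)
    children, heights, counts = _build_tree(dend.Z, n)
    h = dend.merge_heights
    h_range = float(h.max() - h.min())
    if h_range == 0:
        # degenerate flat tree: a single module when it meets min size
        clusters = [set(dend.labels)] if n >= min_module_size else []
        return _label_partition(tissue, clusters, dend.labels, min_module_size)
    gap = _GAP_FRACTIONS[deep_split] * h_range
    root = 2 * n - 2
    found: list[list[int]] = []

    def decompose(v: int) -> list[list[int]]:
        # v is an accepted branch; split while both children qualify
        if v >= n:
            a, b = children[v]
            qual = [
                c
                for c in (a, b)
                if counts[c] >= min_module_size and heights[v] - heights[c] >= gap
            ]
            if len(qual) == 2:
                return decompose(a) + decompose(b)
        return [_leaves_of(v, children, n)]

    def search(v: int, parent_h: float) -> None:
        if counts[v] < min_module_size:
            return
        if parent_h - heights[v] >= gap:
            found.extend(decompose(v))
            return
        if v >= n:
            a, b = children[v]
            search(a, heights[v])
            search(b, heights[v])

    # the root itself is not a branch (it has no parent to separate from);
    # descend into its children
    search_root_children = children[root]
    for c in search_root_children:
        search(c, heights[root])
    clusters = [{dend.labels[i] for i in leaves} for leaves in found]
    return _label_partition(tissue, clusters, dend.labels, min_module_size)


def detect_modules(
    D: np.ndarray,
    gene_ids: list[str],
    tissue: str = "",
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    deep_split: int = DEFAULT_DEEP_SPLIT,
) -> ModulePartition:
    """Convenience wrapper: cluster the dissimilarity and dynamic-cut it."""
    dend = hclust_average(D, gene_ids)
    return dynamic_cut(dend, min_module_size, deep_split, tissue=tissue)
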