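"""Beta-diversity distances and principal coordinates analysis.

Weighted UniFrac weights every branch of a rooted phylogeny by its
length times the absolute difference between the fractions of the two
communities descending from it.  Change-space distances are plain
Euclidean distances between per-subject log2-change vectors.  Both feed
PCoA (Gower double centering of -d^2/2, eigendecomposition).

Distances are computed here from first principles; scikit-bio supplies
only the tree and distance-matrix containers.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .tables import ChangeMatrix, FeatureTable


def _branch_table(tree: TreeNode, taxon_ids) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch leaf membership matrix and branch lengths.

    Returns (M, lengths) where M is branches x taxa 0/1 membership of
    each taxon below the branch.  The root carries no branch.
    """
    taxon_pos = {t: i for i, t in enumerate(taxon_ids)}
    tips = {t.name for t in tree.tips()}
    missing = [t for t in taxon_ids if t not in tips]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:10]}")

    rows, lengths = [], []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(taxon_ids))
            if node.name in taxon_pos:  # tree may have extra leaves
                vec[taxon_pos[node.name]] = 1.0
        else:
            vec = sum(below.pop(id(c)) for c in node.children)
        below[id(node)] = vec
        if node.is_root():
            continue
        if node.length is None:
            raise ValueError(f"branch without length at node {node.name!r}")
        if node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
        rows.append(vec)
        lengths.append(node.length)
    return np.asarray(rows), np.asarray(lengths)


def root_to_tip_depths(tree: TreeNode, taxon_ids) -> np.ndarray:
    """Root-to-leaf path length for each taxon, in taxon_ids order."""
    depths = {}
    for tip in tree.tips():
        d, node = 0.0, tip
        while not node.is_root():
            d += node.length or 0.0
            node = node.parent
        depths[tip.name] = d
    return np.array([depths[t] for t in taxon_ids])


def weighted_unifrac(
    table: FeatureTable, tree: TreeNode, normalized: bool = False
) -> DistanceMatrix:
    """Weighted UniFrac distances between all sample pairs.

    For samples A, B with branch-descendant abundance fractions A_b, B_b:

        d(A, B) = sum_b  l_b * |A_b - B_b|

    The normalized variant divides by sum_j depth_j * (A_j + B_j), the
    maximal attainable raw distance, bounding the result in [0, 1].
    The table must be in relative form (rows summing to 1).
    """
    if not table.is_relative():
        raise ValueError("weighted UniFrac needs relative abundances; call to_relative")
    M, lengths = _branch_table(tree, table.taxon_ids)
    X = table.data.to_numpy()  # samples x taxa
    F = X @ M.T  # samples x branches: fraction of community below each branch
    if lengths.sum() == 0:
        raise ValueError("tree has zero total branch length")
    # weighted L1 over branches
    condensed = pdist(F, metric="minkowski", p=1, w=lengths)
    if normalized:
        s = X @ root_to_tip_depths(tree, table.taxon_ids)  # per-sample mean depth
        denom = pdist(s[:, None], metric=lambda a, b: a[0] + b[0])
        with np.errstate(invalid="ignore"):
            condensed = np.where(denom > 0, condensed / denom, 0.0)
    return DistanceMatrix(squareform(condensed), ids=list(table.sample_ids))


def euclidean_distances(change: ChangeMatrix) -> DistanceMatrix:
    """L2 distances between per-subject change vectors."""
    vals = change.values.to_numpy()
    return DistanceMatrix(
        squareform(pdist(vals, metric="euclidean")), ids=list(change.subject_ids)
    )


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered matrix G = -J (d^2/2) J with J = I - 11'/n."""
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    return a - row - row.T + a.mean()


@dataclass
class Ordination:
    """PCoA embedding: coordinates scaled by sqrt(eigenvalue)."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # descending, retained (positive) axes
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float  # |sum of dropped negative eigenvalues|

    @property
    def pc1(self) -> pd.Series:
        return self.coordinates.iloc[:, 0]


def pcoa(d: DistanceMatrix, k: int | None = None) -> Ordination:
    """Principal coordinates of a distance matrix.

    Negative eigenvalues (non-Euclidean distances) are excluded from the
    coordinates; their absolute mass is reported.  Axis signs are
    canonicalized so the largest-magnitude loading on each axis is
    positive, making runs reproducible.
    """
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    g = gower_center(dm)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(1e-12, abs(eigval).max() * 1e-10) if eigval.size else 0.0
    pos = eigval > tol
    n_pos = int(pos.sum())
    neg_mass = float(-eigval[eigval < -tol].sum())

    if k is None:
        k = n_pos
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = max(n_pos, 1)

    vals = eigval[:k].clip(min=0.0)
    coords = eigvec[:, :k] * np.sqrt(vals)
    # canonical sign: the sample with the largest |coordinate| points positive
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] *= -1

    total = eigval[pos].sum()
    prop = vals / total if total > 0 else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"PCo{i + 1}" for i in range(k)]
    )
    return Ordination(frame, vals, prop, neg_mass)


def shear_tree(tree: TreeNode, taxon_ids) -> TreeNode:
    """Restrict a tree to the given leaves (for core/non-core strata)."""
    return tree.shear(list(taxon_ids))
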