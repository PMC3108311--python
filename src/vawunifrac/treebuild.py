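"""Distance-based tree construction and ordination.

Neighbor joining feeds the simulation pipeline (a tree over sampled
points); UPGMA and PCoA summarise pairwise community distance matrices.
All three operate on a plain symmetric distance matrix with ids.

Determinism: when several pairs tie for the best merge, the pair with the
lowest (row, column) index in the current matrix order is joined, so the
output depends only on the input order of ids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .tree import PhyloTree, ValidationError

__all__ = [
    "DistanceMatrixError",
    "Ordination",
    "as_distance_matrix",
    "neighbor_joining",
    "upgma",
    "pcoa",
    "read_distance_tsv",
    "write_distance_tsv",
]

logger = logging.getLogger(__name__)


class DistanceMatrixError(ValueError):
    """The input is not a valid distance matrix for this operation."""


def as_distance_matrix(d, ids=None) -> tuple:
    """Normalise input to (ndarray, list of ids).

    Accepts a square ndarray (with separate ids) or a scikit-bio
    DistanceMatrix-like object carrying ``.data`` and ``.ids``.
    """
    if hasattr(d, "data") and hasattr(d, "ids"):
        return np.asarray(d.data, dtype=float), list(d.ids)
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DistanceMatrixError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise DistanceMatrixError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise DistanceMatrixError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise DistanceMatrixError("distances must be nonnegative")
    if ids is None:
        ids = [str(i) for i in range(d.shape[0])]
    if len(ids) != d.shape[0]:
        raise DistanceMatrixError("number of ids must match matrix size")
    return d.copy(), list(ids)


def _build_tree(parent_of, length_of, names_of, root_key) -> PhyloTree:
    """Assemble a PhyloTree from dict-form parent pointers (keys arbitrary)."""
    children: dict = {}
    for k, p in parent_of.items():
        children.setdefault(p, []).append(k)
    order = []
    stack = [(root_key, False)]
    while stack:
        key, expanded = stack.pop()
        if expanded:
            order.append(key)
        else:
            stack.append((key, True))
            for c in reversed(children.get(key, [])):
                stack.append((c, False))
    index = {k: i for i, k in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=np.intp)
    length = np.zeros(n)
    names = []
    for k in order:
        i = index[k]
        names.append(names_of.get(k))
        if k != root_key:
            parent[i] = index[parent_of[k]]
            length[i] = length_of[k]
    return PhyloTree(parent, length, tuple(names))


def neighbor_joining(d, ids=None, clamp_negative: bool = False) -> PhyloTree:
    """Saitou–Nei neighbor joining, rooted at the final basal trifurcation.

    The pair minimising Q = (k-2)D - r_i - r_j is joined at every step
    (lowest-index pair on ties); limb lengths follow the standard NJ
    formulas and may be negative unless ``clamp_negative`` is set.  The
    last three clusters are attached to an unresolved root, mirroring the
    trifurcating "root" PHYLIP's neighbor program emits.
    """
    D, names = as_distance_matrix(d, ids)
    n = len(names)
    if n < 3:
        raise DistanceMatrixError("neighbor joining needs at least 3 items")
    parent_of: dict = {}
    length_of: dict = {}
    names_of = {("leaf", i): name for i, name in enumerate(names)}
    active = [("leaf", i) for i in range(n)]
    next_id = 0

    def limb(x):
        return max(0.0, x) if clamp_negative else x

    while len(active) > 3:
        k = len(active)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), k)
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        new = ("node", next_id)
        next_id += 1
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (k - 2))
        parent_of[active[i]] = new
        length_of[active[i]] = limb(li)
        parent_of[active[j]] = new
        length_of[active[j]] = limb(d_ij - li)
        d_new = 0.5 * (D[i] + D[j] - d_ij)
        keep = [x for x in range(k) if x not in (i, j)]
        D = np.vstack(
            [
                np.hstack([D[np.ix_(keep, keep)], d_new[keep, None]]),
                np.hstack([d_new[keep], [0.0]]),
            ]
        )
        active = [active[x] for x in keep] + [new]

    root = ("root", 0)
    if len(active) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        limbs = [(d01 + d02 - d12) / 2, (d01 + d12 - d02) / 2, (d02 + d12 - d01) / 2]
    else:  # n == 2 never reaches here (guarded above); defensive
        limbs = [D[0, 1] / 2, D[0, 1] / 2]
    for node, l in zip(active, limbs):
        parent_of[node] = root
        length_of[node] = limb(l)
    return _build_tree(parent_of, length_of, names_of, root)


def upgma(d, ids=None) -> PhyloTree:
    """UPGMA (average-linkage) clustering into an ultrametric rooted tree.

    The closest pair of clusters is merged at height half its distance;
    after a merge the distance to any other cluster is the size-weighted
    arithmetic mean of the members' distances.  Every leaf ends up at the
    same distance from the root.
    """
    D, names = as_distance_matrix(d, ids)
    n = len(names)
    if n < 2:
        raise DistanceMatrixError("UPGMA needs at least 2 items")
    parent_of: dict = {}
    length_of: dict = {}
    names_of = {("leaf", i): name for i, name in enumerate(names)}
    active = [("leaf", i) for i in range(n)]
    sizes = np.ones(n)
    heights = {key: 0.0 for key in active}
    next_id = 0
    while len(active) > 1:
        k = len(active)
        M = D.copy()
        np.fill_diagonal(M, np.inf)
        i, j = divmod(int(np.argmin(M)), k)
        if i > j:
            i, j = j, i
        h = D[i, j] / 2.0
        new = ("node", next_id)
        next_id += 1
        for x in (i, j):
            parent_of[active[x]] = new
            length_of[active[x]] = h - heights[active[x]]
        heights[new] = h
        d_new = (sizes[i] * D[i] + sizes[j] * D[j]) / (sizes[i] + sizes[j])
        keep = [x for x in range(k) if x not in (i, j)]
        D = np.vstack(
            [
                np.hstack([D[np.ix_(keep, keep)], d_new[keep, None]]),
                np.hstack([d_new[keep], [0.0]]),
            ]
        )
        sizes = np.append(sizes[keep], sizes[i] + sizes[j])
        active = [active[x] for x in keep] + [new]
    return _build_tree(parent_of, length_of, names_of, active[0])


@dataclass(frozen=True)
class Ordination:
    """Principal-coordinate projection of a distance matrix."""

    ids: tuple
    coordinates: np.ndarray  # (n items, k axes), scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # retained (positive) eigenvalues, descending
    proportion_explained: np.ndarray  # share of the positive eigenvalue mass

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# eigenvalues: "
                + " ".join(f"{x:.10g}" for x in self.eigenvalues)
                + "\n# proportion_explained: "
                + " ".join(f"{x:.10g}" for x in self.proportion_explained)
                + "\n"
            )
            k = self.coordinates.shape[1]
            fh.write("id\t" + "\t".join(f"axis{i+1}" for i in range(k)) + "\n")
            for name, row in zip(self.ids, self.coordinates):
                fh.write(name + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def pcoa(d, k: int = 2, ids=None) -> Ordination:
    """Classical (Torgerson) scaling of a distance matrix.

    The Gower-centred matrix -(1/2) J D^2 J is eigendecomposed; the top
    ``k`` axes with positive eigenvalues are kept, scaled by the square
    root of their eigenvalues.  Negative eigenvalues (non-Euclidean input)
    are excluded from the explained-variation proportions and trigger a
    warning.  Each axis is oriented so its largest-magnitude coordinate is
    positive.
    """
    D, names = as_distance_matrix(d, ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(names)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-10 * max(1.0, float(np.abs(eigval).max()))
    if eigval.max() <= tol:
        raise DistanceMatrixError("no positive eigenvalue; ordination is degenerate")
    if eigval.min() < -tol:
        warnings.warn(
            "distance matrix is not Euclidean; negative eigenvalues excluded",
            stacklevel=2,
        )
        logger.warning("non-Euclidean distance matrix: min eigenvalue %g", eigval.min())
    positive = eigval > tol
    kept = min(k, int(positive.sum()))
    vals = eigval[:kept]
    coords = eigvec[:, :kept] * np.sqrt(vals)
    # deterministic sign: the largest-magnitude loading on each axis is positive
    for a in range(kept):
        pivot = np.argmax(np.abs(coords[:, a]))
        if coords[pivot, a] < 0:
            coords[:, a] = -coords[:, a]
    proportions = vals / eigval[positive].sum()
    return Ordination(tuple(names), coords, vals, proportions)


def read_distance_tsv(path) -> tuple:
    """Read a square distance matrix TSV (first row/column are ids)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index.astype(str))


def write_distance_tsv(path, d, ids) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(ids) + "\n")
        for name, row in zip(ids, np.asarray(d)):
            fh.write(name + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
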