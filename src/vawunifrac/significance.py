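"""Permutation significance tests and pairwise community distance matrices.

The null hypothesis is that community labels are assigned at random to the
individuals sitting on the leaves of a fixed tree.  Significance is
assessed by relabelling: the A_T "A" labels are redistributed uniformly at
random among all m = A_T + B_T individuals (multiplicity-aware — a leaf
observed three times has its three individuals relabelled independently),
the statistic is recomputed on the fixed tree, and the p-value is the
fraction of relabellings whose statistic is greater than or equal to the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import metrics
from .tree import BranchTallySet, CommunityAssignment, PhyloTree, ValidationError, branch_tallies

__all__ = [
    "TestResult",
    "CommunityDistanceMatrix",
    "permute_assignment",
    "permutation_pvalue",
    "permutation_test",
    "pairwise_matrix",
]

_PERM_CHUNK = 256  # permutations evaluated per vectorised block


@dataclass(frozen=True)
class TestResult:
    statistic: str
    observed: float
    n_permutations: int
    null_values: np.ndarray
    pvalue: float


@dataclass(frozen=True)
class CommunityDistanceMatrix:
    ids: tuple
    values: np.ndarray
    statistic: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("distance matrix shape must match ids")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValidationError("matrix must be symmetric, nonnegative, zero-diagonal")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for name, row in zip(self.ids, self.values):
                fh.write(name + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    def to_phylip(self, path) -> None:
        """PHYLIP square matrix format (names truncated/padded to 10 chars)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids):5d}\n")
            for name, row in zip(self.ids, self.values):
                fh.write(f"{name[:10]:<10s}" + "  ".join(f"{x:.6f}" for x in row) + "\n")


def _expand_individuals(tree: PhyloTree, assignment: CommunityAssignment):
    """Return (leaf node index per individual, number of A labels)."""
    leaf_idx = []
    a_labels = 0
    for leaf, (a, b) in assignment.counts.items():
        v = tree.leaf_node(leaf)
        leaf_idx.extend([v] * (a + b))
        a_labels += a
    return np.array(leaf_idx, dtype=np.intp), a_labels


def permute_assignment(
    assignment: CommunityAssignment, rng: np.random.Generator
) -> CommunityAssignment:
    """Randomly relabel individuals, preserving A_T, B_T and per-leaf totals."""
    leaves = list(assignment.counts)
    totals = np.array([a + b for a, b in assignment.counts.values()])
    labels = np.zeros(int(totals.sum()), dtype=np.int64)
    labels[: assignment.a_total] = 1
    rng.shuffle(labels)
    owner = np.repeat(np.arange(len(leaves)), totals)
    new_a = np.bincount(owner, weights=labels, minlength=len(leaves)).astype(int)
    return CommunityAssignment(
        {leaf: (int(na), int(t - na)) for leaf, na, t in zip(leaves, new_a, totals)},
        names=assignment.names,
    )


def _null_values(
    tree: PhyloTree,
    assignment: CommunityAssignment,
    statistics: Sequence[str],
    n_permutations: int,
    rng: np.random.Generator,
) -> dict:
    """Null statistic values under label permutation, shared across statistics."""
    tallies = branch_tallies(tree, assignment)
    indiv_leaf, a_total = _expand_individuals(tree, assignment)
    m = indiv_leaf.size
    n_nodes = tree.n_nodes
    parent = tree.parent
    base = np.zeros(m, dtype=np.float64)
    base[:a_total] = 1.0
    out = {name: np.empty(n_permutations) for name in statistics}
    done = 0
    while done < n_permutations:
        p = min(_PERM_CHUNK, n_permutations - done)
        labels = np.tile(base, (p, 1))
        labels = rng.permuted(labels, axis=1)
        counts = np.zeros((n_nodes, p))
        # alpha_j per leaf, then one postorder accumulation for all columns
        np.add.at(counts, indiv_leaf, labels.T)
        for v in range(n_nodes - 1):
            counts[parent[v]] += counts[v]
        values = metrics.batch_statistics(
            tallies.lengths,
            counts[:-1],
            tallies.m_i,
            tallies.a_total,
            tallies.b_total,
            statistics=statistics,
        )
        for name in statistics:
            out[name][done : done + p] = values[name]
        done += p
    return out


def permutation_test(
    tree: PhyloTree,
    assignment: CommunityAssignment,
    statistics: Sequence[str] = metrics.STATISTICS,
    n_permutations: int = 1000,
    rng=None,
    plus_one: bool = False,
) -> dict:
    """Permutation test for several statistics sharing one set of relabellings.

    The tree (and hence its postorder and root-to-leaf distances) is fixed;
    only the per-branch counts are recomputed per permutation.  With
    ``plus_one`` the small-sample (k+1)/(N+1) p-value is reported instead
    of the plain k/N proportion.

    Returns {statistic name: TestResult}.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(rng)
    tallies = branch_tallies(tree, assignment)
    observed = {name: metrics.compute_statistic(tallies, name).value for name in statistics}
    null = _null_values(tree, assignment, statistics, n_permutations, rng)
    results = {}
    for name in statistics:
        k = int(np.sum(null[name] >= observed[name]))
        p = (k + 1) / (n_permutations + 1) if plus_one else k / n_permutations
        results[name] = TestResult(name, observed[name], n_permutations, null[name], p)
    return results


def permutation_pvalue(
    tree: PhyloTree,
    assignment: CommunityAssignment,
    statistic: str = "T",
    n_permutations: int = 1000,
    rng=None,
    plus_one: bool = False,
) -> TestResult:
    """Permutation test for a single statistic; see :func:`permutation_test`."""
    return permutation_test(
        tree, assignment, (statistic,), n_permutations, rng, plus_one
    )[statistic]


def pairwise_matrix(
    tree: PhyloTree,
    communities: Mapping[str, Mapping[str, int]],
    statistic: str = "T",
    prune: bool = True,
) -> CommunityDistanceMatrix:
    """Statistic values for every pair of k communities.

    ``communities`` maps community name -> {leaf: count}.  With ``prune``
    (the default) each pairwise comparison restricts the tree to the leaves
    present in at least one of the two communities, so comparisons with
    different leaf coverage remain commensurable.
    """
    names = list(communities)
    if len(names) < 2:
        raise ValidationError("need at least two communities")
    k = len(names)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            assignment = CommunityAssignment.from_counts(
                communities[names[i]], communities[names[j]], names=(names[i], names[j])
            )
            try:
                tallies = branch_tallies(tree, assignment, prune=prune)
                value = metrics.compute_statistic(tallies, statistic).value
            except (ValidationError, metrics.DegenerateStatisticError) as exc:
                raise type(exc)(
                    f"pair ({names[i]}, {names[j]}): {exc}"
                ) from exc
            out[i, j] = out[j, i] = value
    return CommunityDistanceMatrix(tuple(names), out, statistic)
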