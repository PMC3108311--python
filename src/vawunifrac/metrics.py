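"""The UniFrac family of two-community phylogenetic beta-diversity statistics.

Four statistics are computed from the same per-branch sufficient
statistics (branch length b_i, community descendant counts A_i, B_i):

* ``U``   — unweighted UniFrac: the fraction of occupied branch length
  leading to descendants of exactly one community.
* ``WU``  — weighted UniFrac: branch lengths weighted by the absolute
  difference of relative abundances |A_i/A_T - B_i/B_T|, normalised by the
  abundance-weighted sum of root-to-leaf distances, which bounds it in
  [0, 1].
* ``T``   — variance-adjusted weighted UniFrac: under the null that the
  A_T community-A labels are assigned at random among the m = A_T + B_T
  individuals, A_i is hypergeometric(m_i, m, A_T), so the branch weight
  |A_i/A_T - B_i/B_T| has null variance proportional to m_i(m - m_i).
  Each branch term is divided by sqrt(m_i(m - m_i)) (the branch-dependent
  part of the null standard deviation; the constant factor cancels in the
  ratio) and the statistic is standardised to [0, 1] by the analogous sum
  with |A_i/A_T - B_i/B_T| replaced by A_i/A_T + B_i/B_T.
* ``SqT`` — the squared-difference variant: branch weight
  (A_i/A_T - B_i/B_T)^2 / (m_i(m - m_i)), standardised by the analogous
  squared-sum terms.

Branches with m_i = 0 (no descendants among the compared individuals) or,
for T and SqT, m_i = m (zero null variance; the difference term is
identically 0) are dropped from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tree import BranchTallySet

__all__ = [
    "STATISTICS",
    "DegenerateStatisticError",
    "HypergeomMoments",
    "StatisticValue",
    "hypergeometric_moments",
    "unifrac",
    "weighted_unifrac",
    "vaw_unifrac",
    "sq_t",
    "compute_statistic",
]

STATISTICS = ("U", "WU", "T", "SqT")


class DegenerateStatisticError(ValueError):
    """The statistic is undefined on this input (zero denominator)."""


@dataclass(frozen=True)
class HypergeomMoments:
    """Null mean and variance of a branch count A_i.

    Under random assignment of A_T of the m individuals to community A,
    the count of A-individuals among the m_i descending through a branch
    is hypergeometric with parameters (m_i, m, A_T).
    """

    mean: float
    variance: float
    m_i: int
    m: int
    a_total: int


@dataclass(frozen=True)
class StatisticValue:
    name: str
    value: float
    numerator: float
    denominator: float


def hypergeometric_moments(m_i: int, m: int, a_total: int) -> HypergeomMoments:
    """Exact null moments of A_i ~ Hypergeometric(m_i, m, A_T)."""
    if not (0 <= m_i <= m and 0 <= a_total <= m and m >= 1):
        raise ValueError(
            f"hypergeometric parameters out of range: m_i={m_i}, m={m}, A_T={a_total}"
        )
    dist = stats.hypergeom(M=m, n=a_total, N=m_i)
    if m == 1 or m_i in (0, m) or a_total in (0, m):
        variance = 0.0  # a single draw pool or a forced count: no dispersion
    else:
        variance = float(dist.var())
    return HypergeomMoments(
        mean=float(dist.mean()),
        variance=variance,
        m_i=m_i,
        m=m,
        a_total=a_total,
    )


def _ksum(x: np.ndarray) -> float:
    # order-robust accumulation for the branch sums
    return float(np.sum(x, dtype=np.longdouble))


def unifrac(tallies: BranchTallySet) -> StatisticValue:
    """Unweighted UniFrac: unique branch length over occupied branch length."""
    occupied = tallies.m_i > 0
    if not occupied.any():
        raise DegenerateStatisticError("no branch carries any individual")
    unique = (tallies.a > 0) ^ (tallies.b > 0)
    num = _ksum(tallies.lengths[unique & occupied])
    den = _ksum(tallies.lengths[occupied])
    if den <= 0:
        raise DegenerateStatisticError("total occupied branch length is zero")
    return StatisticValue("U", num / den, num, den)


def weighted_unifrac(tallies: BranchTallySet) -> StatisticValue:
    """Weighted UniFrac, normalised to [0, 1].

    Numerator: sum_i b_i |A_i/A_T - B_i/B_T| over all branches.
    Denominator: sum_j d_j (alpha_j/A_T + beta_j/B_T) over occupied leaves,
    which equals sum_i b_i (A_i/A_T + B_i/B_T) and hence dominates the
    numerator, with equality exactly when every occupied branch leads to a
    single community.
    """
    pa = tallies.a / tallies.a_total
    pb = tallies.b / tallies.b_total
    num = _ksum(tallies.lengths * np.abs(pa - pb))
    den = _ksum(
        tallies.leaf_depths
        * (tallies.leaf_a / tallies.a_total + tallies.leaf_b / tallies.b_total)
    )
    if den <= 0:
        raise DegenerateStatisticError("weighted UniFrac denominator is zero")
    return StatisticValue("WU", num / den, num, den)


def _variance_scale(tallies: BranchTallySet) -> tuple:
    """Per-branch sqrt(m_i (m - m_i)) and the mask of informative branches."""
    m_i = tallies.m_i
    m = tallies.m
    mask = (m_i > 0) & (m_i < m)
    scale = np.sqrt(m_i[mask] * (m - m_i[mask]).astype(float))
    return scale, mask


def vaw_unifrac(tallies: BranchTallySet) -> StatisticValue:
    """Variance-adjusted weighted UniFrac (T), standardised to [0, 1]."""
    if tallies.m < 2:
        raise DegenerateStatisticError("need at least two individuals")
    scale, mask = _variance_scale(tallies)
    if not mask.any():
        raise DegenerateStatisticError("every branch is uninformative (m_i in {0, m})")
    pa = tallies.a[mask] / tallies.a_total
    pb = tallies.b[mask] / tallies.b_total
    w = tallies.lengths[mask] / scale
    num = _ksum(w * np.abs(pa - pb))
    den = _ksum(w * (pa + pb))
    if den <= 0:
        raise DegenerateStatisticError("variance-adjusted denominator is zero")
    return StatisticValue("T", num / den, num, den)


def sq_t(tallies: BranchTallySet) -> StatisticValue:
    """Squared-difference variant of T.

    Branch weight (A_i/A_T - B_i/B_T)^2 / (m_i(m - m_i)), standardised by
    the matching squared-sum terms so the value stays in [0, 1] with 1 at
    total separation.
    """
    if tallies.m < 2:
        raise DegenerateStatisticError("need at least two individuals")
    scale, mask = _variance_scale(tallies)
    if not mask.any():
        raise DegenerateStatisticError("every branch is uninformative (m_i in {0, m})")
    pa = tallies.a[mask] / tallies.a_total
    pb = tallies.b[mask] / tallies.b_total
    w = tallies.lengths[mask] / scale**2
    num = _ksum(w * (pa - pb) ** 2)
    den = _ksum(w * (pa + pb) ** 2)
    if den <= 0:
        raise DegenerateStatisticError("variance-adjusted denominator is zero")
    return StatisticValue("SqT", num / den, num, den)


_FUNCS = {
    "U": unifrac,
    "WU": weighted_unifrac,
    "T": vaw_unifrac,
    "SqT": sq_t,
}


def compute_statistic(tallies: BranchTallySet, statistic: str) -> StatisticValue:
    """Dispatch by statistic name ('U', 'WU', 'T', 'SqT')."""
    try:
        func = _FUNCS[statistic]
    except KeyError:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}") from None
    return func(tallies)


# -- vectorised kernel over permuted tallies --------------------------------


def batch_statistics(
    lengths: np.ndarray,
    a_counts: np.ndarray,
    m_i: np.ndarray,
    a_total: int,
    b_total: int,
    statistics=STATISTICS,
) -> dict:
    """Evaluate statistics for many assignments sharing one tree.

    ``a_counts`` has shape (n_branches, P): column p holds the A_i of the
    p-th assignment.  The per-leaf totals (hence m_i) are fixed across
    label permutations, so B_i = m_i - A_i, and the weighted UniFrac
    denominator can use the branch-sum identity
    sum_j d_j(alpha_j/A_T + beta_j/B_T) = sum_i b_i(A_i/A_T + B_i/B_T).

    Returns {name: values array of shape (P,)}.
    """
    m = a_total + b_total
    a = a_counts
    b = m_i[:, None] - a
    pa = a / a_total
    pb = b / b_total
    out = {}
    occupied = m_i > 0
    informative = occupied & (m_i < m)
    if "U" in statistics:
        unique = ((a > 0) ^ (b > 0)) & occupied[:, None]
        den = float(lengths[occupied].sum())
        if den <= 0:
            raise DegenerateStatisticError("total occupied branch length is zero")
        out["U"] = lengths @ unique / den
    if "WU" in statistics:
        num = lengths @ np.abs(pa - pb)
        den = lengths @ (pa + pb)
        if np.any(den <= 0):
            raise DegenerateStatisticError("weighted UniFrac denominator is zero")
        out["WU"] = num / den
    if "T" in statistics or "SqT" in statistics:
        if not informative.any():
            raise DegenerateStatisticError("every branch is uninformative (m_i in {0, m})")
        scale = np.sqrt(m_i[informative] * (m - m_i[informative]).astype(float))
        diff = pa[informative] - pb[informative]
        tot = pa[informative] + pb[informative]
        if "T" in statistics:
            w = lengths[informative] / scale
            out["T"] = (w @ np.abs(diff)) / (w @ tot)
        if "SqT" in statistics:
            w2 = lengths[informative] / scale**2
            out["SqT"] = (w2 @ diff**2) / (w2 @ tot**2)
    return out
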