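import numpy as np
import pytest

import vawunifrac as vf


@pytest.fixture
def four_leaf_tree():
    """Two-cherry tree: ((L1:1,L2:1):1,(L3:1,L4:1):1);"""
    return vf.parse_newick("((L1:1,L2:1):1,(L3:1,L4:1):1);")


@pytest.fixture
def separated_assignment():
    return vf.CommunityAssignment(
        {"L1": (1, 0), "L2": (1, 0), "L3": (0, 1), "L4": (0, 1)}
    )


def random_tree(rng: np.random.Generator, n_leaves: int) -> vf.PhyloTree:
    """Random rooted tree with uniform [0,2] branch lengths.

    Built by repeatedly joining two random subtrees, then rooting at a
    final multifurcation of the last 2-3 subtrees.
    """
    parts = [f"L{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_leaves)]
    while len(parts) > 3:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    return vf.parse_newick("(" + ",".join(parts) + ");")


def random_assignment(
    rng: np.random.Generator, leaf_names, max_count: int = 3
) -> vf.CommunityAssignment:
    """Random assignment guaranteed to put >=1 individual in each community."""
    while True:
        counts = {
            name: (int(rng.integers(0, max_count + 1)), int(rng.integers(0, max_count + 1)))
            for name in leaf_names
        }
        a_t = sum(a for a, _ in counts.values())
        b_t = sum(b for _, b in counts.values())
        if a_t >= 1 and b_t >= 1:
            return vf.CommunityAssignment(counts)


def brute_force_tallies(tree: vf.PhyloTree, assignment: vf.CommunityAssignment):
    """Independent tally oracle: enumerate each branch's full descendant leaf set."""
    children = [[] for _ in range(tree.n_nodes)]
    for v in range(tree.n_nodes - 1):
        children[tree.parent[v]].append(v)

    def descend_leaves(v):
        if not children[v]:
            return [v]
        out = []
        for c in children[v]:
            out.extend(descend_leaves(c))
        return out

    a = np.zeros(tree.n_branches, dtype=int)
    b = np.zeros(tree.n_branches, dtype=int)
    for v in range(tree.n_branches):
        for leaf in descend_leaves(v):
            ca, cb = assignment.counts.get(tree.names[leaf], (0, 0))
            a[v] += ca
            b[v] += cb
    return a, b


def brute_force_statistics(tree: vf.PhyloTree, assignment: vf.CommunityAssignment):
    """Independent statistic oracle: naive per-branch enumeration of all formulas."""
    a, b = brute_force_tallies(tree, assignment)
    lengths = tree.length[: tree.n_branches]
    a_t, b_t = assignment.a_total, assignment.b_total
    m = a_t + b_t
    depths = vf.leaf_root_distances(tree)

    u_num = u_den = 0.0
    wu_num = 0.0
    t_num = t_den = 0.0
    sq_num = sq_den = 0.0
    for i in range(tree.n_branches):
        m_i = a[i] + b[i]
        diff = abs(a[i] / a_t - b[i] / b_t)
        tot = a[i] / a_t + b[i] / b_t
        if m_i > 0:
            u_den += lengths[i]
            if (a[i] > 0) != (b[i] > 0):
                u_num += lengths[i]
        wu_num += lengths[i] * diff
        if 0 < m_i < m:
            scale = np.sqrt(m_i * (m - m_i))
            t_num += lengths[i] * diff / scale
            t_den += lengths[i] * tot / scale
            sq_num += lengths[i] * diff**2 / scale**2
            sq_den += lengths[i] * tot**2 / scale**2
    wu_den = sum(
        depths[leaf] * (ca / a_t + cb / b_t) for leaf, (ca, cb) in assignment.counts.items()
    )
    return {
        "U": u_num / u_den,
        "WU": wu_num / wu_den,
        "T": t_num / t_den,
        "SqT": sq_num / sq_den,
    }
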