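"""Geometric two-community simulator for power and type-I-error studies.

A community is a cloud of points in the plane; the spread of the cloud
stands in for the phylogenetic diversity of the community, with the
maximum within-community distance kept at 0.3 units (the scale of
between-phylum 16S distances).  Three scenario families are provided:

* ``circles`` — both communities uniform on disks of radius 0.15 (the
  second radius may shrink to 0.134 or 0.116) whose centres are offset by
  0 to 0.047 units; shrinking or offsetting controls the overlap.
* ``ellipses`` — both communities uniform on a 0.3 x 0.15 ellipse, one of
  them rotated ("pivoted") about the common centre.
* ``radial`` — both communities live on the same radius-0.15 disk; one is
  uniform, the other draws its radial distance as the c-th root of a
  uniform draw on [0, 0.15^c], clumping points towards the periphery for
  c > 2 and towards the centre for c < 2 (c = 2 recovers the uniform
  disk).

Each replicate samples n points per community (default 200), builds a
neighbor-joining tree on the Euclidean distances among all 2n points (each
point a leaf carrying one individual of its community), and runs the
shared-label permutation test for all four statistics.  Rejection rates
over replicates estimate the type-I error (identical communities) or the
power (different communities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import metrics
from .significance import permutation_test
from .tree import CommunityAssignment
from .treebuild import neighbor_joining

__all__ = [
    "SimulationScenario",
    "PowerEstimate",
    "circles_scenario",
    "ellipses_scenario",
    "radial_scenario",
    "sample_disk",
    "sample_radial",
    "sample_ellipse",
    "sample_scenario",
    "run_replicate",
    "estimate_power",
]

#: default points per community
N_POINTS = 200
#: radius of the reference community-A disk
RADIUS_A = 0.15
#: semi-axes of the simulation ellipses (length 0.3, width 0.15)
ELLIPSE_SEMI_AXES = (0.15, 0.075)


@dataclass(frozen=True)
class SimulationScenario:
    """Geometry of one two-community comparison."""

    kind: str  # 'circles' | 'ellipses' | 'radial'
    n_points: int = N_POINTS
    radius_a: float = RADIUS_A
    radius_b: float = RADIUS_A
    offset: float = 0.0
    pivot_deg: float = 0.0
    c: float = 2.0
    semi_axes: tuple = ELLIPSE_SEMI_AXES

    def __post_init__(self):
        if self.kind not in ("circles", "ellipses", "radial"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.n_points < 3:
            raise ValueError("need at least 3 points per community")
        if min(self.radius_a, self.radius_b) <= 0 or self.offset < 0 or self.c <= 0:
            raise ValueError("radii and c must be positive, offset nonnegative")


def circles_scenario(
    radius_b: float = RADIUS_A, offset: float = 0.0, n_points: int = N_POINTS
) -> SimulationScenario:
    return SimulationScenario("circles", n_points=n_points, radius_b=radius_b, offset=offset)


def ellipses_scenario(pivot_deg: float = 0.0, n_points: int = N_POINTS) -> SimulationScenario:
    return SimulationScenario("ellipses", n_points=n_points, pivot_deg=pivot_deg)


def radial_scenario(c: float, n_points: int = N_POINTS) -> SimulationScenario:
    return SimulationScenario("radial", n_points=n_points, c=c)


def sample_disk(center, radius: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform on a disk: angle uniform, radius R*sqrt(U)."""
    return sample_radial(center, radius, 2.0, n, rng)


def sample_radial(center, radius: float, c: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points with radial distance the c-th root of U[0, R^c]; c=2 is uniform."""
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    r = radius * rng.uniform(0.0, 1.0, n) ** (1.0 / c)
    return np.asarray(center, float) + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def sample_ellipse(
    semi_axes, pivot_deg: float, n: int, rng: np.random.Generator, center=(0.0, 0.0)
) -> np.ndarray:
    """n points uniform on an ellipse interior, rotated about its centre.

    Rejection sampling from the bounding box (acceptance pi/4), then
    rotation by the pivot angle.
    """
    a, b = semi_axes
    pts = np.empty((0, 2))
    while pts.shape[0] < n:
        cand = rng.uniform(-1.0, 1.0, (2 * (n - pts.shape[0]) + 8, 2))
        cand = cand[(cand**2).sum(axis=1) <= 1.0]
        pts = np.vstack([pts, cand])
    pts = pts[:n] * np.array([a, b])
    phi = np.deg2rad(pivot_deg)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    return np.asarray(center, float) + pts @ rot.T


def sample_scenario(scenario: SimulationScenario, rng: np.random.Generator) -> tuple:
    """Sample (points_a, points_b) for one replicate of a scenario."""
    n = scenario.n_points
    if scenario.kind == "circles":
        pts_a = sample_disk((0.0, 0.0), scenario.radius_a, n, rng)
        pts_b = sample_disk((scenario.offset, 0.0), scenario.radius_b, n, rng)
    elif scenario.kind == "ellipses":
        pts_a = sample_ellipse(scenario.semi_axes, 0.0, n, rng)
        pts_b = sample_ellipse(scenario.semi_axes, scenario.pivot_deg, n, rng)
    else:  # radial: A uniform, B clumped, same disk
        pts_a = sample_disk((0.0, 0.0), scenario.radius_a, n, rng)
        pts_b = sample_radial((0.0, 0.0), scenario.radius_a, scenario.c, n, rng)
    return pts_a, pts_b


def run_replicate(
    scenario: SimulationScenario,
    n_permutations: int = 1000,
    rng=None,
    statistics: Sequence[str] = metrics.STATISTICS,
) -> dict:
    """One full comparison: sample, build NJ tree, permutation-test.

    Every sampled point becomes one leaf carrying a single individual of
    its community; all statistics share the same permutations.  Returns
    {statistic: p-value}.
    """
    rng = np.random.default_rng(rng)
    pts_a, pts_b = sample_scenario(scenario, rng)
    pts = np.vstack([pts_a, pts_b])
    names = [f"A{i:03d}" for i in range(len(pts_a))] + [f"B{i:03d}" for i in range(len(pts_b))]
    tree = neighbor_joining(squareform(pdist(pts)), ids=names)
    assignment = CommunityAssignment(
        {name: (1, 0) if name.startswith("A") else (0, 1) for name in names}
    )
    results = permutation_test(tree, assignment, statistics, n_permutations, rng)
    return {name: res.pvalue for name, res in results.items()}


@dataclass(frozen=True)
class PowerEstimate:
    """Rejection rates of the statistics over independent replicates."""

    scenario: SimulationScenario
    statistics: tuple
    counts: dict  # statistic -> number of replicates with p < alpha
    n_replicates: int
    n_permutations: int
    alpha: float
    seed: object = None

    @property
    def rates(self) -> dict:
        return {s: self.counts[s] / self.n_replicates for s in self.statistics}

    @property
    def standard_errors(self) -> dict:
        """Binomial standard error sqrt(p(1-p)/R) of each rate."""
        return {
            s: float(np.sqrt(r * (1.0 - r) / self.n_replicates))
            for s, r in self.rates.items()
        }


def estimate_power(
    scenario: SimulationScenario,
    n_replicates: int = 200,
    n_permutations: int = 400,
    alpha: float = 0.05,
    seed=None,
    statistics: Sequence[str] = metrics.STATISTICS,
) -> PowerEstimate:
    """Monte-Carlo rejection rate (type-I error or power) of each statistic.

    Rejection uses the strict rule p < alpha.  Each replicate gets an
    independent child RNG spawned from ``seed`` via ``SeedSequence.spawn``,
    so results are reproducible and replicates could run in any order.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    counts = {s: 0 for s in statistics}
    for child in children:
        pvals = run_replicate(scenario, n_permutations, np.random.default_rng(child), statistics)
        for s in statistics:
            if pvals[s] < alpha:
                counts[s] += 1
    return PowerEstimate(
        scenario, tuple(statistics), counts, n_replicates, n_permutations, alpha, seed
    )
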