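# Methods

## Model and test

The package compares two communities of individuals placed on a common
rooted phylogeny. The null hypothesis is that community labels are
unrelated to phylogeny: conditional on the tree and on which leaves the
`m = A_T + B_T` individuals occupy, the `A_T` "A" labels are a uniformly
random subset of the `m` individuals. Under this null the count `A_i` of
A-individuals descending through a branch with `m_i` individuals is
hypergeometric `(m_i, m, A_T)` with

    E[A_i]   = m_i·A_T/m
    Var[A_i] = A_T·(m_i/m)(1 − m_i/m)(m − A_T)/(m − 1),

so the weighted-UniFrac branch weight `|A_i/A_T − B_i/B_T|` has null
variance proportional to `m_i(m − m_i)` — the proportionality constant
(involving `A_T`, `B_T`, `m`, `m − 1`) is the same for every branch. The
variance-adjusted statistic T divides each branch term by
`√(m_i(m − m_i))` and standardises by the matching sum of
`A_i/A_T + B_i/B_T` terms, so `T ∈ [0, 1]`: each numerator term is
bounded by its denominator term, with equality exactly when a branch
leads to a single community. The constant factor cancels in the ratio,
which is why only `√(m_i(m − m_i))` appears; tests verify this against
the full hypergeometric variance. SqT applies the same construction to
the squared difference with weight `1/(m_i(m − m_i))`, standardised by
squared sums — the unique analogue that preserves both the [0, 1] range
and the value 1 at total separation.

Branches with `m_i = 0` carry no information and branches with
`m_i = m` have a difference term that is identically zero along with a
zero variance scale; both are excluded from numerator and denominator
(the 0/0 limit is taken as 0). This keeps T finite and equals the limit
of the statistic as such branches become informative.

Significance: individuals are relabelled uniformly at random
(multiplicity-aware — a leaf observed three times has three
independently relabelled individuals; per-leaf totals and `A_T`, `B_T`
are preserved), the statistic is recomputed on the fixed tree, and
`p = #{null ≥ observed}/N`, ties counting as ≥ and the observed value
not included in the null sample. The `(k+1)/(N+1)` small-sample variant
is available behind a flag but off by default. For a tie-free statistic
the p-value is uniform on the grid `{0, 1/N, …, 1}` under the null;
the test suite checks this with a chi-square over the exact discrete
grid rather than a Kolmogorov–Smirnov test, which assumes a continuous
null and mis-calibrates on a distribution with N+1 atoms.

## Data model and conventions

* Trees are used exactly as rooted in the input Newick; the root
  placement matters through the leaf depths `d_j` and branch
  orientation. Neighbor-joining output is rooted at its basal
  trifurcation, matching the convention of classic distance-matrix
  phylogeny programs.
* Negative branch lengths (which NJ can produce) are kept by default;
  `clamp_negative`/`clamp_negative_lengths` zeroes them on request.
  Plain Newick input rejects negative lengths unless explicitly allowed.
* Leaves missing from an assignment count (0, 0). For pairwise
  community matrices the tree is by default sheared to the leaves
  present in each pair (collapsing unary nodes, summing lengths) so
  comparisons with different coverage stay commensurable; single
  comparisons use the full tree. Both behaviours are overridable.
* Multifurcations are supported throughout; nothing is binarised.
* The branch count excludes the synthetic edge above the root.
* Sums over branches accumulate in extended precision; suite equality
  checks use relative tolerance 1e-9.

## Tree building and ordination

Neighbor joining follows Saitou–Nei: join the pair minimising
`Q = (k−2)D − r_i − r_j`, standard limb-length formulas, final basal
trifurcation. UPGMA merges the closest pair at half its distance with
size-weighted average linkage, giving an ultrametric tree by
construction. Both break ties by the lowest (row, column) index in the
current matrix order, so output is a deterministic function of input
order. PCoA is classical scaling: eigendecomposition of the
Gower-centred `−½D²`, axes scaled by `√eigenvalue`, each axis oriented
so its largest-magnitude coordinate is positive; negative eigenvalues
(non-Euclidean input) are excluded from the explained-variation
proportions with a warning, and no Cailliez/Lingoes correction is
applied. Independent cross-checks in the tests compare NJ against
scikit-bio's implementation and additive-matrix recovery, UPGMA against
scipy average-linkage cophenetic distances, and PCoA against scikit-bio
and exact Euclidean round trips.

## Simulator

A community is a planar point cloud whose spread stands in for
phylogenetic diversity; the maximum within-community distance is kept at
0.3 units (the scale of between-phylum 16S distances). Three families:

* circles — A uniform on a radius-0.15 disk; B uniform on a disk of
  radius 0.15/0.134/0.116 whose centre is offset 0–0.047 along the
  x-axis. Disk sampling uses angle uniform, radius `R√u`.
* ellipses — both uniform on a 0.3 × 0.15 ellipse (semi-axes
  0.15, 0.075, rejection-sampled from the unit disk scaled), B rotated
  by the pivot angle about the common centre. The pivot point is not
  uniquely determined by the scenario description; rotation about the
  shared centre is the reading consistent with the stated overlaps.
* radial — both on the same radius-0.15 disk; A uniform, B with radial
  distance `R·u^(1/c)` (the c-th root of a uniform draw on `[0, R^c]`):
  c = 2 is exactly uniform, c > 2 clumps to the periphery, c < 2 to the
  centre.

Each replicate: sample n = 200 points per community, compute Euclidean
distances among the 400 points, build one NJ tree (each point a leaf
carrying one individual), evaluate all four statistics, and test them
against the same N label permutations — sharing permutations cuts cost
4× and leaves each marginal p-value valid. Per-replicate cost is
dominated by NJ (O(n³) vectorised); the permutation pass recomputes only
branch counts (one postorder accumulation over a 2D count matrix), so it
is linear in tree size per permutation.

Replicates draw child seeds from `numpy.random.SeedSequence.spawn`, so
results are reproducible from a single seed and independent of
evaluation order.

Default study profile: R = 200 replicates × N = 400 permutations (the
scaled-down profile; rejection at p < 0.05, strict). The full-fidelity
profile (R = 1000, N = 1000) is available by argument or CLI flag.
Monte-Carlo uncertainty on a rate is reported as the binomial standard
error `√(p(1−p)/R)` (≈ 0.035 at worst for R = 200).

What the simulator does and does not emulate: point clouds plus NJ
produce trees whose leaf depths and branch structure resemble
distance-based phylogenies of real amplicon data, and abundance enters
only through leaf multiplicity (each simulated individual is distinct).
Real 16S collections have collapsed duplicate sequences, alignment and
sequencing noise, and reference-based trees; passing the simulation
checks shows the statistics and test behave correctly on
distance-faithful trees, not that any particular biological conclusion
transfers.

## Known limitations

* Two-community statistics only; k-community comparisons go through
  pairwise matrices (no single multi-community statistic, no
  α-parameterised generalised UniFrac).
* The permutation test conditions on the tree; uncertainty in tree
  inference is not propagated.
* PHYLIP's internal tie-breaking in `neighbor` is order-dependent and
  not reproduced exactly; this package's deterministic lowest-index rule
  can differ on tied joins (the statistics are robust to such ties at
  simulation scale).
* No rarefaction/jackknifing and no multiple-testing correction across
  pairs; matrix entries are raw statistic values.
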