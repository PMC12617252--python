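# Methods

This note documents the models, numerical choices, and validation logic
behind `morphnet`, and what the synthetic-data experiments do and do not
demonstrate.

## Density estimation

Each region's vertex values are summarized as a discrete probability
vector: a Gaussian-kernel density evaluated at `grid_size` equally
spaced points (default 28) and renormalized to sum to one. The
bandwidth is Silverman's normal-reference rule, `h = (4/3n)^(1/5) · sd`
(identical to the "silverman" factor of `scipy.stats.gaussian_kde`); a
fixed numeric bandwidth is available for reproducibility experiments.
Degenerate regions (all vertex values identical) become a point mass on
the grid cell nearest the common value, so two identical regions still
compare as maximally similar rather than erroring.

Because the Jensen–Shannon divergence requires a common support, two
regions are always compared on a shared grid. The default policy
re-evaluates both densities on a grid spanning the union of the two
regions' value ranges (the tightest common support); a cheaper
per-subject global grid is available as a configuration switch for
sensitivity analysis. Grids use the exact data range without padding:
the kernel mass outside the range is small and cancels in the
renormalization, and the choice keeps the density shift-equivariant.

Probability cells are floored at 1e-12 before any logarithm and
renormalized, which removes undefined 0·log 0 terms while perturbing
the divergence by far less than any tolerance used downstream.

## Similarity and thresholding

Edges are `w = 1 − JSD(p, q)` with base-2 logarithms, so weights lie in
[0, 1] and 1 means identical distributions. The network literature
also uses the metric form `1 − sqrt(JSD)`; it is provided behind a
configuration flag (`one_minus_sqrt_jsd`) but `1 − JSD` is the default.

Binarization keeps, at sparsity `s`, the `max(n−1, round(s·n(n−1)/2))`
strongest edges with the maximum-weight spanning tree of the similarity
matrix forced in ("minimum spanning tree" of the divergence `1 − w`;
the orientation is stated explicitly because the two conventions are
easy to confuse). Consequences, all tested: every level is connected;
edge sets are nested along the grid; the edge-count formula holds
exactly (at 210 nodes and s = 0.03: 658 edges). Rounding is
half-away-from-zero so counts are platform-stable, and ties in edge
weights are broken lexicographically by (i, j), making the construction
fully deterministic. The default grid is 0.03–0.30 in steps of 0.01
(28 levels).

## Graph topology

Metrics operate on binary adjacency matrices with
`scipy.sparse.csgraph` BFS distances: Watts–Strogatz clustering
(degree < 2 contributes 0), characteristic path length over unordered
pairs (hard error on disconnected input — upstream thresholding
guarantees connectivity, so a disconnected graph indicates a caller
bug), and nodal efficiency `E_i = mean_{j≠i} 1/d_ij`. All three are
validated exhaustively against brute-force oracles (triangle
enumeration, python BFS) on every graph with up to six nodes and on
random 12-node graphs.

Null normalization: `zCp = Cp / mean(Cp over rewired nulls)` and
likewise for `Lp` (the gamma/lambda ratio convention — the words
"normalized by the corresponding average value" describe a ratio, not a
z-score; a z-score mode is available by flag). Default 100 nulls per
graph. Nulls are Maslov–Sneppen double-edge swaps with 10·|E| attempts
(a standard mixing heuristic, configurable). Swaps that would
disconnect the graph are rejected per-swap: after swapping
(a−b, c−d) → (a−d, c−b) in a connected graph, every node remains
attached to one of the four endpoints, so global connectivity is
equivalent to b being reachable from a — checked with an early-exit
search, which keeps the per-swap cost low. Graphs admitting no valid
swap (complete graphs) are returned unchanged with a logged notice,
which also yields the identity normalization (1, 1).

Per-subject scalars for group comparison are range-normalized
trapezoidal AUCs across the sparsity grid (per-level values are
retained in the tidy output for sensitivity analysis; whether to test
per level or integrated is genuinely open, and AUC is the default
because it yields one well-defined scalar per subject).

## Statistics

Permutation ANOVA: the classical one-way F (computed on row-centered
data to avoid catastrophic cancellation in the sum-of-squares shortcut)
with unrestricted group-label permutations and the add-one estimator
`p = (1 + #{F_perm ≥ F_obs})/(B + 1)`, so p is never zero and the
smallest attainable value is 1/(B+1). One permutation set is shared by
all regions of a family (subjects are permuted, not region values),
B = 1000 by default. Measures with zero total variance are flagged NaN
and excluded from FDR families.

Post-hoc pairwise two-sample t-tests (pooled variance by default, Welch
by flag) are gated inside the function on main-effect p < 0.05 —
calling without a significant main effect raises, so the gate cannot be
bypassed by a careless caller. BH-FDR (statsmodels) is applied within
three family types: per feature across regions, per network across
nodes, per group × clinical variable across candidate measures. Raw
p < 0.1 results that fail FDR are labelled "marginal" and never
promoted.

Clinical correlations use Spearman's rank correlation throughout;
Shapiro–Wilk results for every clinical variable are recorded as
metadata rather than used to branch to Pearson, keeping the reported
statistic unambiguous. Candidate measures are restricted, in code, to
those with significant between-group differences (the data-driven
selection rule). Pairs with n < 4 or zero variance are flagged, not
computed.

## Synthetic cohorts

The generator emulates the study's data structure, not cortical
geometry. Per feature it draws fixed per-region baseline locations
(shared template), subject-level regional means
(`between_sd`), and vertex noise (`within_sd`), optionally as a
mean-preserving two-component mixture so the density/JSD machinery is
exercised on non-Gaussian shapes. Defaults are chosen once at
plausible surface-morphometry scales (CT ≈ 2.5 ± 0.3 mm vertex scatter,
SD ≈ 1.3 ± 0.45 mm, FD and GI dimensionless near 2.5–2.7); the true
within-region distribution shapes of real data are unknown, so these
are modelling choices, not inferences.

A location effect of magnitude d shifts the target group's regional
mean by `d · sqrt(between_sd² + within_sd²/m_r)` — i.e. d is Cohen's d
on subject-level regional means, the quantity the downstream tests
compare, which makes Monte-Carlo recovery of d exact by construction.
Vertex counts per region are drawn once per design (50–500 by default)
and shared across subjects, mirroring a fixed template parcellation.

Clinical covariates have lognormal marginals on the scale of
early-abstinence cohorts (e.g. median abstinence ≈ 60 days, use
frequency ≈ 2.5/day), deliberately non-normal so the Shapiro–Wilk
reporting path is exercised. Planted associations couple a clinical
variable to a morphometric summary through a latent-Gaussian copula on
normal scores, with latent correlation `2·sin(π·ρ/6)` solving the
Gaussian-copula Spearman identity; the declared marginal is preserved
exactly and the sample Spearman converges to the target ρ.

What passing tests show: the pipeline is internally correct (oracle
agreement, exact contracts), statistically calibrated under the null,
and able to recover planted effects of the stated sizes at the study's
group sizes. What they do not show: anything about real cortical data
— the generator has no spatial autocorrelation on the mesh, no scanner
noise, no realistic inter-regional covariance, and no claim about
patient neurobiology.

## Validation problem sizes and statistical subtleties

- Null calibration runs 500 no-effect cohorts at 10/10/10 subjects,
  20 regions, B = 200. Permutation p-values are uniform on the
  attainable grid {k/201}; the uniformity check therefore applies the
  standard randomized-p transform (subtract a uniform jitter within
  each atom), which is exactly U(0, 1) under the null, before the KS
  comparison. A chi-square over the atoms gives the same verdict.
- With discrete permutation p-values BH is strictly conservative: at
  B = 200 and a 20-region family the rank-1 BH threshold (0.0025) is
  below the smallest attainable p (1/201), so a family can only reject
  via two or more near-minimal p-values. The false-positive check is
  accordingly one-sided (observed count of families with any rejection
  must not exceed the upper 95% binomial bound at p = q), which is the
  guarantee BH actually provides.
- Effect recovery uses the study's group sizes (26/24/32) at 20
  regions. At 210 regions a single true effect cannot survive BH with
  B = 1000 (1/1001 > 0.05/210): detecting isolated effects there
  requires more permutations, a cost the validation avoids by shrinking
  the family rather than weakening the test.
- Full-parcellation structural checks run one subject at 210 regions
  with reduced vertex counts (30–60 per region); node/edge-count
  contracts are size-exact and unaffected by vertex counts.

## Known limitations

- The pairwise shared-grid density evaluation is O(n²) KDE evaluations
  per subject and feature; at 210 regions with realistic vertex counts
  a cohort-scale run is minutes, not seconds. The per-subject global
  grid switch trades a small support approximation for one evaluation
  per region.
- Rewiring-based normalization is the dominant cost at dense sparsity
  levels; `n_null` and the swap factor are configurable.
- Surface-format adapters (reading standard morphometry file formats
  directly) are an extension point; the core consumes delimited vertex
  tables.
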