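# morphnet

Individual (single-subject) morphological brain-network analysis for
surface-based morphometry, with a synthetic-cohort generator for
validating every stage against known ground truth.

## The problem

Cross-sectional structural-MRI studies (for example comparing
heroin-abstinent patients, methamphetamine-abstinent patients, and
healthy controls) increasingly analyse *morphological similarity
networks*: per-subject graphs whose nodes are cortical atlas regions
(210 in a Brainnetome-style parcellation) and whose edges quantify how
similar two regions' distributions of a vertex-wise morphometric
feature are — cortical thickness (CT), fractal dimension (FD),
gyrification index (GI), or sulcal depth (SD). `morphnet` implements
this construction and the accompanying group-statistics scheme as a
tested, reusable Python library.

## The method

For each subject, feature, and region *i*, the vertex values inside the
region are turned into a discrete probability distribution
*p<sub>i</sub>* — a Gaussian kernel density estimate (Silverman's
normal-reference bandwidth) evaluated at 28 equally spaced grid points
and renormalized. Edges are

&nbsp;&nbsp;&nbsp;&nbsp;*w<sub>ij</sub>* = 1 − JSD(*p<sub>i</sub>*, *p<sub>j</sub>*),

where JSD is the base-2 Jensen–Shannon divergence
½KL(*p*‖*m*) + ½KL(*q*‖*m*) with *m* = (*p*+*q*)/2, bounded in [0, 1].
The weighted matrix is binarized over a sparsity grid (0.03–0.30 in
steps of 0.01); the maximum-weight spanning tree is forced into every
level, so each graph keeps max(*n*−1, round(*s·n(n−1)/2*)) edges and is
always connected. Topology per level: clustering coefficient *Cp*,
characteristic path length *Lp* — each also normalized by its mean over
100 degree-preserving Maslov–Sneppen rewired nulls (*zCp*, *zLp*) — and
nodal efficiency *E<sub>i</sub>* = mean<sub>j≠i</sub> 1/*d<sub>ij</sub>*
per region; per-subject scalars are range-normalized AUCs across the
sparsity grid.

Group statistics mirror the study scheme: one-way ANOVA *F* with
permutation p-values (B = 1000, add-one convention), post-hoc pooled
two-sample t-tests gated on main-effect p < 0.05, Benjamini–Hochberg
FDR at q < 0.05 within declared families (per-feature across regions;
per-network across nodes; per group × clinical variable for
correlations), and Shapiro–Wilk-documented Spearman correlations between
clinical covariates and the measures that survived the group
comparison.

The synthetic-cohort module generates vertex-wise data for the
three-group design (default n = 26/24/32), with planted regional
effects (location shifts in Cohen's d units on regional means, scale or
shape changes) and planted Spearman associations between clinical
variables and morphometric summaries via a latent-Gaussian copula that
preserves the declared (lognormal) clinical marginals.

## Worked example

```python
import morphnet as mn

design = mn.CohortDesign(
    n_roi=20, vertices_per_roi=(50, 500), features=("CT", "SD"),
    effects=(mn.PlantedEffect(roi_id=7, feature="CT", groups=("HA",),
                              magnitude=-1.2),),
    seed=42)
records = mn.generate_cohort(design)          # 82 subjects: 26 HA, 24 MA, 32 HC
regional = mn.regional_stats(records, ("CT",),
                             mn.PipelineConfig(n_perm=1000, seed=1))
print(regional[regional.significant][["roi_id", "F", "p", "q", "t_HA_HC"]])
```

prints

```
   roi_id          F         p        q  t_HA_HC
6       7  10.083114  0.000999  0.01998 -3.05502
```

— the planted cortical-thickness deficit in ROI 7 is recovered: the
main effect survives FDR across the 20-region family (q = 0.02) and the
post-hoc t is negative (HA below controls), matching the planted
direction. The permutation p of 0.000999 is the smallest attainable
value, 1/(B+1) = 1/1001. More narrative walkthroughs are in
`examples/` (network construction, graph topology and small-world
normalization, cohort simulation, full statistics).

A thin CLI wraps the same functions:
`morphnet simulate|features|network|metrics|stats|all` (see
`morphnet --help`).

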