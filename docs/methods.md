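# Methods

## Model and procedure

The package treats a CSF proteomic dataset as a proteins × samples matrix
of log abundances with missing entries, accompanied by per-sample
annotations (subject, group, visit, months from baseline). The analysis
has five stages.

**Preprocessing.** Abundances are natural-log transformed. A protein is
removed when its missing fraction is *strictly* greater than 0.5 in at
least one group (so exactly 50% is retained). Each sample is centered to
the median of its observed *background* values and scaled by their median
absolute deviation, where the background is the floor(0.9·P) proteins
with the lowest variance of observed values (ties at the cutoff break
lexicographically by protein id, making the panel deterministic). The MAD
here is the raw median absolute deviation from the median — no 1.4826
consistency factor — because the aim is exact unit-MAD per sample, not an
estimate of a Gaussian σ. After the transform every sample's observed
background values have median 0 and MAD 1 up to float rounding (an
even-length median averages two floats, so "exact" means ~1e-15).

Outlying samples are detected on the normalized matrix from the pairwise
sample distances (root-mean-square difference over shared observed
proteins, which is missingness-robust and agrees with Euclidean distance
on complete data). A sample is excluded when the robust z-score of its
mean distance to all other samples exceeds 3.0. The z-score uses the
median center and scale `max(1.4826·MAD, SD)`: a raw MAD estimated from a
few dozen mean distances is noisy enough to flag several percent of clean
samples per run, while the SD floor restores calibration (clean-data
flag rate ≈ 2–4% of runs) and genuine outliers — which sit at robust
z ≈ 10 and inflate the SD only ~2-fold — remain clearly above the cut.
Many simultaneous extreme outliers could in principle mask each other
through the SD term; the MAD term bounds that effect.

The default stage order is filter → normalize → outlier-detect. The axis
of MAD scaling (per sample over background, the default) and a per-protein
alternative are both implemented because either reading is defensible;
a `scale_axis` flag switches them.

**Network construction.** Pairwise Pearson correlations use
pairwise-complete observations; entries with fewer than `min_pairwise_n`
(default 10) shared samples, or zero variance on the shared samples, are
undefined and enter the adjacency as r = 0 (a neutral weight) with a
logged count. The signed adjacency is a = ((1+r)/2)^β with β = 7; the
clustering dissimilarity is 1 − a by default, with the topological
overlap alternative `t = (Σᵤ a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`
available by flag (the two give identical partitions on block-diagonal
structure; TOM additionally rewards shared neighbors).

Initial modules come from average-linkage clustering cut *adaptively* at
`cut_fraction` (default 0.95) of the maximum merge height. Because random
pairwise correlations concentrate near zero while genuinely co-regulated
blocks merge far below the root, a cut that scales with the data's own
dissimilarity range isolates real blocks and leaves near-random proteins
in sub-threshold clumps. Clusters smaller than `min_module_size`
(default 5) are unassigned (label 0). This is a deliberately simple
adaptive rule rather than the multi-parameter dynamic hybrid tree cut of
the reference WGCNA stack; at the sizes involved here it recovers planted
partitions essentially perfectly (ARI ≈ 0.99) and leaves ≥ 90% of
pure-noise proteins unassigned, which is the behavior that matters
downstream. A `static` mode cuts at an absolute height instead. Its main
known limitation: modules with within-correlation ≲ 0.35 at β = 7 merge
above the default cut and are missed; lowering `cut_fraction`'s complement
(raising the cut) trades noise-module false positives for such weak-module
sensitivity.

Modules whose eigenproteins have dissimilarity (1 − Pearson r) below the
merge cut height 0.05 are fused iteratively (closest pair first,
eigenproteins recomputed after each merge), then labels are renumbered
1..M by decreasing size. The "cut height 0.05" is interpreted as this
eigenprotein-merge threshold: 0.05 is implausibly low as a static tree
cut on a correlation dissimilarity but is a standard merge height.

An eigenprotein is the first principal component score vector of the
module's member profiles (each median-imputed and standardized to
mean 0 / SD 1, ddof = 1), scaled to unit variance and signed to correlate
non-negatively with the module's mean standardized profile. The
variance-explained is the first eigenvalue fraction. Intramodular
connectivity kin sums a protein's adjacency to same-module partners;
the ceil(0.10·size) proteins with the largest kin per module are hubs
(ties break by protein id).

Stability: each iteration drops one uniformly chosen sample, rebuilds the
network with the same configuration, matches iteration modules to the
reference modules by greedy maximum-Jaccard label matching, and scores
each protein 1 when its (mapped) label equals its reference label,
unassigned matching unassigned. The reference network uses all samples.
Note that dropping a single sample perturbs pairwise correlations only
slightly, so even spurious noise clumps retain stability ≈ 0.6–0.8; the
informative contrast is against the exact 1.0 of clean modules, and the
statistic is most useful comparatively across modules.

**Group comparisons.** Eigenprotein differences are tested per module and
per disease group against the reference group only, with a two-sided
Mann-Whitney U: exact null when both groups have ≤ 12 samples and the
pooled values are untied, normal approximation with tie and continuity
correction otherwise; an all-tied comparison carries no evidence and
returns p = 1. With fewer than 20 such tests, raw p-values at 0.05 are
reported (no correction).

Differential correlation compares each protein pair's within-group
correlations through Fisher's transform, Z = (z₁ − z₂)/√(1/(n₁−3) +
1/(n₂−3)) with pairwise-complete n per group, two-sided normal p, and BH
step-up control at FDR 0.1 over all tested pairs (all pairs with defined
correlations and n > 3 in both groups; a within-module restriction is a
flag). The per-pair n uses pairwise-complete counts, not group size,
because missingness varies per protein. At the default scale (~370k
pairs from ~860 proteins) the test family is large; because sample
correlations within a module co-fluctuate through the group's realized
factor values, false discoveries cluster by module, which is an inherent
property of correlation screening rather than a miscalibration (the
type-I error on independent null pairs is 0.05 within Monte-Carlo error).

**Enrichment.** Foregrounds (e.g. proteins of significant pairs, or
longitudinally decreasing proteins) are tested against module memberships
or user GMT sets with the upper-tail hypergeometric probability
P(X ≥ a), background = all proteins/genes entering the network stage.
Odds ratios are sample odds ratios with the Haldane–Anscombe +0.5
correction when any 2×2 cell is zero; the one-sided upper tail matches
the enrichment (OR > 1) question. Protein-to-gene abstraction collapses
many-to-one; a gene whose proteins span modules follows its highest-kin
protein. Cross-tabulation module preservation runs the same test on every
(module A, module B) cell over the identifier intersection of two
networks, BH-adjusted across the grid.

**Longitudinal screen.** Per protein, the random-intercept fixed-slope
model y_it = β₀ + b_i + β₁·t_it + ε_it with b_i ⟂ ε (uncorrelated
covariance structure) is fitted by REML to subjects with ≥ 2 visits,
time anchored at each subject's first visit. The implementation profiles
the likelihood over the single variance ratio θ = σ_b²/σ² — β and σ²
have closed forms at fixed θ via per-subject block inverses — and
optimizes θ by bounded scalar search on log(1+θ). This is authored
in-package so the σ² → 0 boundary (noise-free trajectories) resolves
exactly; it agrees with an independent general-purpose mixed-model
implementation to ≥ 5 significant figures on regular data (asserted in
the tests). The slope's t-test uses df = n_obs − n_subjects − 1, the
inner-outer degrees-of-freedom rule for a within-subject covariate in a
random-intercept model. Natural log is the abundance scale throughout.
A protein needs ≥ 5 subjects with ≥ 2 observed visits (configurable) to
be fitted; BH at 0.1 classifies directions.

## Synthetic data: what it emulates and what it does not

The generator draws a per-subject factor f_m per module and sets protein
i of module m to μᵢ + τᵢ(λ_m f + √(1−λ_m²) ε) with λ_m = √w_m, so
same-module pairs have correlation w_m and loadings are equal within a
module (the simplest structure achieving the target). Group-level module
shifts add δ to f for that group's subjects; they move eigenproteins
without touching within-group correlations. Decorrelation resamples the
named protein's factor independently within the named group, which
removes its correlation with the whole module there while preserving its
marginal variance — deliberately isolating correlation change from
abundance change. A consequence: *every* pair involving a perturbed
protein is truly decorrelated, so planted pairs are concentrated on few
perturbed proteins in the small tight modules, keeping the set of
genuinely altered pairs sparse relative to the full within-module family.
Follow-up visits reuse the subject's factor draw (a subject-level random
effect) with fresh measurement noise and add slope·months for drifting
proteins. Missingness is MCAR per group by default (an
intensity-dependent MNAR mode exists but is off, since the emulated
processing chain reports no mechanism); outlier samples receive a +4 SD
global shift plus 3× residual-noise inflation (a location *and* scale
corruption — a pure location shift would be removed exactly by per-sample
median centering).

The default study-shaped fixture has 10 modules of sizes
183/115/110/90/75/67/64/58/7/7 (776 assigned proteins) plus 107 noise
proteins; groups of 41/20/19 subjects plus 3 extra planted outlier
subjects; within-module correlation 0.8, with 0.9 for the first and the
two smallest modules (pairwise correlations of 0.9+ are what tight CSF
modules show); shifts of ±1.5 latent units in three modules for the first
disease group and one for the second; 10 decorrelated pairs through 4
perturbed proteins in the two smallest modules; 18 high-missingness
proteins (rate 0.7 in one group); 3% MCAR missingness; and 15 decreasing
plus 10 increasing longitudinal proteins at ∓0.04 log-units/month among
20 disease subjects with a 20/12/10/2 ladder of visits 2–5 at 6-month
spacing.

What passing tests on this fixture do *not* show about real data: the
generator has no batch structure, no peptide-level quantification noise,
no intensity-dependent missingness by default, equal loadings within
modules, and Gaussian factors/noise. Real CSF data additionally couple
abundance with variance (low-abundance proteins correlate more weakly),
which the generator's independent τᵢ does not reproduce. One interaction
the fixture *does* expose: per-sample background-median normalization
partially absorbs the largest module's factor (a fifth of the proteome
moving together drags the sample median), attenuating that module's
correlations; module-recovery validation therefore runs on log
abundances, while the full pipeline keeps the normalization, whose
purpose is cross-run comparability on real instrument data.

## Numerical and design choices

- Correlations are clipped to [−1, 1]; atanh inputs to 1 − 1e-15.
- Eigenprotein PCA uses SVD of the standardized member matrix; the
  two-protein uncorrelated case gives variance-explained exactly 1/2.
- BH adjustment is the vectorized step-up (reverse cumulative minimum),
  asserted equal to the literal definition and to an independent
  implementation.
- The exact Mann-Whitney branch enumerates the null only for ≤ 12 + ≤ 12
  untied samples, where enumeration is cheap.
- REML's θ search runs on log(1+θ) over [0, 25] (θ up to ~7·10¹⁰) with
  the θ = 0 boundary checked explicitly; RSS is floored at 1e-300 inside
  the log for the noise-free case, where σ̂² = 0 and the slope p-value
  degenerates to 0.
- The coverage of the slope's 95% CI is estimated from 400 simulation
  replicates (Monte-Carlo SD ≈ 0.011 at the true ≈ 0.94–0.95).
- Single global seed: stage seeds are spawned from a `SeedSequence`, so
  stage-level runs are reproducible independently and all derived seeds
  stay below 2³¹.
- All study parameters (β = 7, min module size 5, merge cut 0.05, >50%
  missingness, 10% hubs, FDR 0.1, outlier z 3.0) are configuration
  defaults, not hard-coded constants.

## Known limitations

- The adaptive fractional cut has one parameter where dynamic tree cut
  has several; very heterogeneous module tightness within one dataset may
  need a per-dataset `cut_fraction`.
- Leave-one-out stability is a weak perturbation at small sample counts
  (see above); bootstrap or leave-k-out would separate noise modules more
  sharply.
- The Fisher r-to-z comparison assumes bivariate normality within groups;
  heavy-tailed abundance distributions inflate its tails.
- Hypergeometric enrichment treats proteins as exchangeable; correlated
  module membership and foreground construction from the same network
  make the module-enrichment p-values descriptive rather than strictly
  inferential.
- The longitudinal model has a fixed slope and random intercept only;
  per-subject slope heterogeneity is absorbed into residual variance,
  which is conservative for the slope test but understates
  subject-level variation.
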