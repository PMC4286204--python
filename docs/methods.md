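# Methods

## The model

`commtrees` analyses community survey data — a quadrat × taxon matrix of
proportion cover (or presence/absence) with quadrats nested in sites — with
sum-of-squares multivariate regression trees (MRT). An MRT recursively
partitions the quadrats into two groups using rules on explanatory
variables, choosing at each node the split that maximally reduces the
within-group sum of squared Euclidean distances of the multi-column
response to the group centroid:

    ΔSS = SS(parent) − SS(left) − SS(right),
    SS(node) = Σ_i ||y_i − ȳ(node)||²

which, for any binary split, equals the between-group term
`(n_l n_r / n) · ||ȳ_l − ȳ_r||²`. Numeric and ordered-categorical variables
admit threshold rules (`x ≤ t` goes left; ordered factors split only
contiguously in their declared order); unordered categoricals with L
observed levels admit all `2^(L−1) − 1` binary level-set partitions,
searched exhaustively.

Explanatory power is summarised by the relative error
`RE = Σ(leaf SS) / SS(root) = 1 − R²`; an unsplit tree has RE = 1.
Predictive power is the cross-validated relative error (CVRE): held-out
quadrats are predicted by the centroid of the leaf they land in, and the
summed squared prediction error is divided by the total SS of the full data
about its grand mean, so a root-only model has CVRE ≈ 1. CVRE = 0 is
perfect prediction, CVRE ≥ 1 is no predictive power, and values below 0.60
are labelled "strong" in the reporting vocabulary.

## Blocked cross-validation

Quadrats within a site (remnant patch) are not independent, so folds
partition *sites*: sites are shuffled by seed and dealt into k folds of
near-equal size, every quadrat inherits its site's fold, and fold integrity
(no site on both sides of a train/test division) is asserted on every run.
k defaults to 10, or to the number of sites when fewer than 10
(leave-one-site-out). Repeated fold assignments with distinct derived seeds
can be averaged (`CVConfig.reps`, default 50); the heavy simulation studies
in this repository use k = 5 with a single repetition per dataset, a
problem-size choice that leaves the qualitative conclusions unchanged while
keeping full enumeration runs desk-scale.

Fold trees are pruned to each candidate size from the full-data tree's
pruning sequence by choosing the largest subtree with at most that many
leaves from the fold tree's own weakest-link sequence. Tree size is chosen
by minimum mean CVRE (ties to the smaller tree); a one-standard-error rule
is available.

## Pruning

Trees are pruned by CART weakest-link cost-complexity pruning: repeatedly
collapse the internal node with the smallest per-leaf SS gain
`g(t) = (SS(t) − Σ leaf SS of branch) / (|leaves| − 1)`, yielding a nested
sequence of subtrees with non-decreasing complexity values ending at the
root-only tree. Growth controls (`GrowControl`): minimum child size 5,
minimum splittable node 10, minimum split improvement 0.001 of the root SS,
unlimited depth. These mirror common recursive-partitioning practice and
are exposed in configuration rather than claimed to be canonical.

## Best-subsets selection

Greedy tree growth over a rich candidate set can be "locked" into an early
split sequence with poor out-of-sample error. The best-subsets search
enumerates every nonempty predictor subset (all `2^p − 1`, guarded above
p = 15 unless a maximum subset size is given), fits and cross-validates
each on the *same* fold assignments — a paired comparison — and selects the
subset with minimum CVRE (ties: smaller subset, then lexicographic order).
Because the full set is itself a candidate, the winner can never have worse
CVRE than the full-predictor model on those folds.

## Preprocessing

Four steps in a fixed order: (1) remove quadrats with no cover recorded;
(2) remove rare taxa present in fewer than 5% of the remaining quadrats
(the denominator is the quadrats that contain any cover, not all surveyed
quadrats and not sites); (3) log-transform cover, f(x) = ln(x+1) — the base
is not specified by the transform's common statement; natural log is used,
and since a base change rescales all SS uniformly it cannot alter tree
topology, RE or CVRE; (4) standardize each quadrat by its total so rows sum
to 1. Standardization defaults to dividing the *transformed* values by
their own row totals (it is the final step); dividing raw covers by raw
totals before the log is available as `standardize_basis="raw"`, which is
the scale-invariant variant. Occurrence (0/1) responses skip steps 3–4:
both transforms are cover-specific.

## Indicator values

For taxon i and group j, fidelity `A_ij = mean_ij / Σ_k mean_ik` and
frequency `B_ij` (proportion of group-j quadrats where i is present) give
`IndVal_ij = A_ij · B_ij ∈ [0, 1]`. Groups come from a fitted tree: the two
breakpoint-labelled sides of each split (evaluated over the quadrats
reaching that split) and the full leaf partition. Significance of each
taxon's maximum IndVal uses free permutation of quadrat group labels with
the add-one estimator `p = (r + 1)/(n_perm + 1)`; permutations are not
blocked by site (standard IndVal practice), and no multiple-testing
correction is applied across taxa or groupings — reported probabilities are
raw, a documented caveat. IndVal is computed on the same preprocessed
abundances fed to the tree; raw-cover input is equally valid and available
to callers.

## Null models for grouped analyses

Aggregating species into morphogroups models fewer entities; good
morphogroup performance could in principle be an artefact of that
reduction. The null model reassigns species to groups uniformly at random
while exactly preserving the multiset of group sizes — holding entity count
and size structure fixed while destroying biological coherence — and reruns
the entire aggregate → preprocess → best-subsets pipeline per replicate
(default 99, minimum 19). The report gives the observed best CVRE's
mid-rank quantile within the null distribution. This size-preserving
reassignment is the minimal null consistent with the question; alternative
nulls (abundance-weighted, taxonomically constrained) are out of scope.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not any
particular field dataset:

- **Design**: sites with a fixed number of quadrats; patch-scale predictors
  drawn once per site and broadcast, quadrat-scale predictors drawn per
  quadrat; numeric variables uniform within ranges typical of semi-arid
  woodland surveys (e.g. pH 6.1–8.5, organic C 1.3–3.4%, time since
  fencing 1–50 years), grazing intensity an ordered low < medium < high
  factor.
- **Truth**: a list of threshold/level-set rules whose crossed outcomes
  partition predictor space into regions. Each morphogroup has a regional
  profile of expected aggregate cover, `base_cover × Gamma(0.8, 1/0.8)`
  draws (mean 0.1, coefficient of variation ≈ 1.1), making regional
  compositions distinct.
- **Coherence c ∈ [0, 1]**: a species' regional mean is
  `w_s · (c · μ_group,region + (1−c) · ν_species,region)` with ν an
  independent profile from the same distribution and w_s a Dirichlet(2)
  within-group abundance share. c = 1 makes member species exact scaled
  copies of their group response; c = 0 removes all group signal.
- **Noise**: covers are lognormal around the mean (σ = 0.6 by default,
  mean-preserving) and zeroed with probability 0.3 — reproducing
  overdispersed (variance > mean), zero-rich cover data with a few dominant
  taxa, the very features motivating the log transform. Rare species occupy
  1–3 quadrats at trace cover.
- **Presets**: "fencing-like" (21 sites × 3 quadrats = 63 quadrats, 54
  species in 10 morphogroups, rules on grazing ≤ medium and time since
  fencing ≤ 29 y) and "fragmentation-like" (25 sites, 71 quadrats, 60
  species in 6 morphogroups, rules on patch size and location in remnant).

What the generator does *not* emulate: spatial autocorrelation, temporal
succession, microenvironment stratification within sites, observer error,
or cover constrained to sum ≤ 1 per quadrat (layered biocrust cover can
overlap; only non-negativity is enforced). Passing simulation tests
therefore demonstrate correct behaviour under piecewise-constant responses
with realistic noise, not performance on any particular real survey.

## Numerical choices

- Split tie-breaks: earlier variable in declared column order, then smaller
  threshold, then lexicographically smallest level-set; improvements are
  compared with a 1e-12 guard, making fits deterministic and invariant to
  row order.
- Numeric thresholds are midpoints between adjacent distinct observed
  values.
- Missing predictor values never block a split: candidates are scored on
  the observed rows and missing rows go to the child with more training
  observations (recorded on the rule). Responses must be complete.
- A node whose SS is ≤ 1e-12 of the root SS is treated as pure. If the
  root SS is zero (constant responses) RE is defined as 0 with a warning.
- Permutation p-values use (r+1)/(n+1) and so never reach 0.

## Known limitations

- No distance-based MRT (only squared-Euclidean responses), no surrogate
  splits, no forests or stochastic subset search, no nested CV to correct
  the selection bias of choosing the best subset by CVRE (the reported best
  CVRE is an optimistic estimate for the selected model; the paired-fold
  design still ranks subsets fairly).
- Only one grouping level (site) is respected by cross-validation.
- Best-subsets enumeration is exponential in p; above 15 predictors a
  maximum subset size must be supplied.
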