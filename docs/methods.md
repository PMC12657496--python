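# Methods

`fhstrat` implements an end-to-end analysis for studying heterogeneity
among preadolescents (ages 9–10) with a positive family history of
substance use (FHSU-P): environmental-profile subgrouping, family-history
density scoring, a trial-level reinforcement-learning model of the
Monetary Incentive Delay (MID) task, and mixed-model subgroup contrasts.
Because the cohort data this design targets are access-restricted, the
package ships a synthetic cohort generator that reproduces the
statistical structure the analysis assumes; every downstream stage is
developed and tested against it.

## Family-history classification and density

FHSU status is a screen on the parent-reported family-history item
about *drug*-related problems in any blood relative: a record is
positive iff at least one drug-problem indicator is endorsed for a
biological parent, biological grandparent, or any other blood relative.
Alcohol-only records are negative — the item wording is drug-specific,
so the classifier does not count alcohol endorsements (this is a
deliberate reading of an ambiguity; the density score below does count
them).

Family-history density (FHD) is the weighted sum of endorsed
first/second-degree relatives: +0.5 per biological-parent report and
+0.25 per biological-grandparent report, counted separately for alcohol
and drug problems and summed. With 2 parents and 4 grandparents per
substance the score is a multiple of 0.25 in [0, 4]; a parent endorsed
for both substances contributes 1.0. Other blood relatives affect
status but never the score. Missing indicators are treated as negative
with a logged warning (conservative; every participant receives a
score).

## Synthetic cohort generator

The generator emulates a multi-site developmental study:

* **Nesting.** Families have one or two children; the number of
  participants in two-child families is the closest even integer to
  n·`sibling_fraction` (default 0.2511). Families are assigned
  uniformly to `n_sites` sites (default 21) and never span sites.
* **Latent structure.** FHSU status (default positive fraction 0.309)
  and the latent environmental subgroup are drawn at the *family*
  level: siblings share both their blood relatives and their household
  environment. Participant-level marginals still follow the mixing
  weights. Five default profiles carry weights proportional to
  744/300/267/201/443.
* **Profile features.** 33 categorical/ordinal sociodemographic
  features partitioned into 8 parental, 11 family/sustenance, and 14
  child/school variables. Nine are discriminative: each profile fixes a
  modal category per feature, and category weights are tilted as
  base_rate·exp(separation·1[modal]), normalized, so separation 0
  reproduces the population base rates exactly and large separation
  concentrates responses on the modal level. The modal mass is capped
  at 0.98: survey responses retain irreducible noise, and a
  near-point-mass column would standardize into a handful of extreme
  leverage points. A feature whose modal level is shared by every
  profile (rule-breaking peer involvement) is left at base rates — the
  shared mode is already the population mode, and concentrating it
  would only manufacture a degenerate column with no between-subgroup
  signal. The remaining 24 features are subgroup-independent.
  Heavily skewed hardship indicators are represented as three-level
  ordinal difficulty scales with moderate rates rather than 99/1
  binaries, and employment/marital status carry three well-separated
  categories: after z-standardization, near-degenerate categorical
  columns produce |z| ≈ 10 outliers that k-means isolates into junk
  clusters which outgain genuine structure.
* **Outcomes.** CBCL t-scores (internalizing, externalizing, total) and
  the five UPPS-P subscales are population mean + per-subgroup additive
  shift + site intercept + family intercept + Gaussian residual.
  Default means/SDs are the family-history-negative group values; the
  default shifts are the subgroup means minus that baseline. CBCL
  scores are truncated to [25, 100]; UPPS-P subscales are rounded and
  clipped to the instrument range [4, 16] (four items, Likert 1–4).
  Default site SD 1.0 and family SD 2.0 are modest relative to the
  residual scale, which is realistic for well-harmonized multi-site
  protocols. No subgroup shift is planted on MID behaviour, matching
  the empirical finding that prediction-error summaries do not separate
  the groups.
* **MID runs.** Each run is 50 contiguous trials, exactly 10 per trial
  type (large/small win, neutral, small/large loss) in pseudorandom
  order; hits are i.i.d. Bernoulli with probability 0.6 by default (the
  task's adaptive staircase targets ~60% success). Two runs per
  participant by default.
* **Family history.** Indicator endorsement rates are set from the
  target group FHD means (rate = target/4 for positive records with all
  twelve parent/grandparent indicators free; target/2 for negative
  records, whose drug indicators are forced off). A positive record
  with no endorsed parent/grandparent drug indicator gets the
  other-blood-relative item set, which preserves the score.

What the generator does *not* emulate: item-level instruments,
missingness beyond an optional MCAR mask, families larger than two
children, subgroup-correlated filler features (the real cohort's
hardship items do differ across subgroups), longitudinal structure, or
any neuroimaging measure. Passing tests therefore demonstrate that the
pipeline recovers structure of this idealized form, not that the real
cohort satisfies these assumptions.

## Profile clustering

FHSU-P participants are clustered with k-means on the 33 features after
mode imputation and z-standardization.

**Encoding.** The default encodes every feature as per-category
indicator columns (one-hot) before standardization. With one integer
column per feature, the squared standardized distance two subgroups can
express on a differing feature is bounded by 1/(p·q) — about 8 for
realistic splits — regardless of how far apart their modal categories
are coded; profile pairs that differ on one or two features (as two of
the default profile pairs do) are then inherently weaker than the ~n
sum-of-squares any single independent filler column can shed, and
k-means provably prefers carving filler columns over separating them.
Indicator encoding spans each category difference across two columns
and removes the arbitrary spacing of integer codes. Integer coding is
retained (`encoding="integer"`) as a sensitivity analysis preserving
the literal 33-column geometry.

**Model selection.** The distortion (within-cluster sum of squares)
curve is computed for k = 1..10, taking for each k the best of 20
seeded multi-start fits (10 k-means++ restarts each) plus warm-started
candidate splits of the previous solution (extra centroid at the point
farthest from its centroid, tried per cluster). The number of clusters
is selected by a sequential permutation calibration of the curve: for
k = 1, 2, …, the observed drop D(k) − D(k+1) is compared with the
drops obtained on 20 reference datasets in which every column is
permuted independently *within* the clusters of the k-solution. Such
references preserve the structure found so far — including every
within-cluster category marginal, so rare-category columns and their
single-column distortion yields are fully represented — while
containing no structure beyond it. The scan stops at the first k whose
drop does not exceed every reference drop (an empirical-quantile test
at level ≈ 1/(B+1) with B = 20); a marginal rejection — an observed
drop above the reference maximum but within four reference SDs of the
reference mean, where an upper-tail reference draw is plausible —
escalates to two further reference batches before deciding, sharpening
the level to ≈ 1/(3B+1) exactly where it matters. Stopping at k = 1
flags the data as having no significant cluster structure. The classical maximum-second-difference
elbow is available as `method="second_difference"` and works well for
compact, comparably separated clusters; it is not the default because
profile cohorts whose subgroups share a dominant good/poor-environment
polarity produce hierarchical distortion curves whose curvature
concentrates at the coarsest split for any monotone transform of the
curve, so a curvature rule cannot return the finer true k. Silhouette,
Davies–Bouldin, and Calinski–Harabasz indices are reported per k as
corroboration and are never auto-combined with the selection rule.

**Stability audits.** Seed stability refits the chosen k under 20
seeds and reports the mean ± SD Hungarian-matched centroid shift over
all seed pairs. Bootstrap stability (100 replicates) refits on
with-replacement resamples, transfers labels to all original rows by
nearest bootstrap centroid, and reports the normalized mutual
information against the reference assignment (mean, SD, range). The
pipeline audits with n_init = 30 (and the curve effectively with 200
restarts per k): at 10 restarts roughly a quarter of seeds land in a
visibly suboptimal local minimum on cohorts of this geometry, which
would report optimizer noise as instability.

**Attribution.** k-means exposes no model to explain, so a surrogate
multiclass classifier is trained to predict cluster labels and its SHAP
values are aggregated (mean |value| over rows and classes; summed over
each feature's indicator columns). The default surrogate is a
gradient-boosted tree ensemble whose exact TreeSHAP contributions are
computed natively by xgboost; a multinomial-logistic surrogate with the
exact linear-model SHAP values coef·(x − mean) is available.

**Visualisation.** Centered PCA scores (2 components by default) with
explained-variance ratios.

## Reward prediction error

For each MID trial with cue value Cu ∈ {+5, +0.2, 0, −0.2, −5} points,
the learner computes EV_t = pGain_t·Cu_t and RPE_t = R_t − EV_t, with
pGain (the subjective probability that the cued amount is realized)
initialized at 0.5 and learning rate η = 0.7 for all participants. The
outcome convention is: win trials pay +|Cu| on a hit, else 0; loss
trials pay 0 on a hit (loss avoided), else Cu; neutral trials pay 0.

Two update rules are implemented. The default, `normalized`,

    pGain ← pGain + η·RPE/Cu          (no update when Cu = 0)

rewrites as pGain + η·(R/Cu − pGain), a Rescorla–Wagner delta rule on a
probability; since R/Cu ∈ {0, 1} under the outcome convention, pGain
remains in [0, 1] for every admissible sequence, provably. The
`literal` rule multiplies the error by the cue instead, pGain ←
pGain + η·RPE·Cu; it leaves [0, 1] after a single large-magnitude trial
(0.5 → 9.25 for a hit large win), so it is clipped to [0, 1] and clip
events are counted. A probability cannot follow the multiplicative
form unclipped, which is why the normalized form is the default; both
are exposed because the multiplicative form is what some
implementations state. One pGain sequence is shared across runs and
trial types (the recurrence indexes only trial order); an independent
state per cue type is available for sensitivity analysis.

Positive/negative prediction errors are summarized per cue condition as
the mean RPE over trials with RPE > 0 (PPE) and RPE < 0 (NPE);
zero-RPE trials count in neither, and empty cells are reported as
missing rather than zero.

## Group inference

Each outcome is modelled as

    outcome ~ subgroup + sex + age + race_ethnicity
              + (1 | site) + (1 | family)

fit by maximum likelihood. Subgroup is categorical with a designated
reference level (the family-history-negative group by default); the
coefficient estimate (CE) for each non-reference level is the adjusted
contrast. The family intercept is fit as a variance component nested
within site, valid because families never span sites here. The
optimizer runs Powell first, then L-BFGS: the variance-component
likelihood of this design is nearly flat (family variance is identified
only through the ~25% sibling pairs) and gradient-only optimization
stalls; the Powell path reproduces reference ML fits (R/lme4, checked
in the test suite) to six decimals. Near-boundary variance estimates
are reported with a warning, not an error. Fixed-effect p-values are
Wald with a normal reference — mixed-model degree-of-freedom
conventions differ across ecosystems, and at the sample sizes this
design targets the choice is immaterial. Outcomes are modelled on
their raw scale by default, with z-scaling behind a flag.

Benjamini–Hochberg step-up adjustment is applied separately within each
outcome domain (CBCL, UPPS-P, RPE): adjusted p_(i) = min over j ≥ i of
m·p_(j)/j, capped at 1, with m the domain's test count.

Demographic tables use Pearson χ² (uncorrected) on full contingency
tables for categorical variables, two-proportion z-tests for binary
splits, and Welch t-tests for continuous variables; percentages are
count/group-n·100 rounded to two decimals. Expected cell counts below
1 attach a warning flag to the row. No claim is made to reproduce any
specific published omnibus Z statistic, whose underlying test family is
not always stated.

## Pipeline

`fhstrat` (CLI) orchestrates simulate → fhd → cluster → rpe → compare →
report. Artifacts are CSV/JSON in an output directory; a manifest
records the effective configuration and SHA-256 checksums of every
output, and two runs with identical config and seed are byte-identical.
Stage dependencies are checked and a missing upstream artifact names
the stage to run first.

## Problem sizes and numerical choices

Tests and the acceptance script exercise cohorts of 2,000 FHSU-P
participants for clustering (the scale at which the subgroup structure
is comfortably identified), 4,000 for mixed-model effect recovery, and
200 small replicates (n = 250, 6 sites) for the null false-positive-rate
check. Distortions are recomputable from labels and centroids to 1e-8
relative tolerance; EV/RPE identities hold to machine precision; the
elbow's low-confidence flag uses a 5%-of-total-SS threshold for the
second-difference method (structureless Gaussian curves stay below
~3%, planted blobs above 30%). Mode imputation breaks ties toward the
earlier category. Constant columns standardize to zeros with a
warning.

## Known limitations

* The generator's subgroup signal lives entirely in nine features with
  modal-level differences; two default profile pairs differ on only
  one to three features, which is the binding constraint on how
  separable the planted structure can be. Real cohorts carry
  correlated signal across many more variables.
* Under indicator encoding the feature matrix has ~130 columns, not
  33; the integer-coded geometry is available but demonstrably cannot
  express the default twin-profile separations.
* Family variance components are weakly identified at realistic
  sibling fractions; CE estimates are robust to this, the variance
  components themselves are noisy.
* The sequential permutation elbow is an approximate test (level ≈
  1/(B+1) per stage, references conditioned on a fitted rather than
  true partition); over long scans its per-stage errors accumulate.
* FHD's informant structure (who reported which relative) is not
  modelled; indicators are independent Bernoulli draws tuned only to
  the group mean.
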