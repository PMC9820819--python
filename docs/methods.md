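# Methods

This package implements a three-stage association analysis between CSF
Alzheimer's-disease (AD) biomarkers and macro-/microelement
concentrations measured in CSF and plasma, together with a synthetic
cohort generator that supplies ground truth for every stage.  This note
documents the models, the numerical choices, and what the synthetic
studies do and do not establish.

## Synthetic cohort model (`csfmetals.cohort`)

The generator emulates a memory-clinic cohort of 124 AD, 50 MCI and 19
healthy-control (HC) patients (193 total), with plasma collected from a
randomly chosen 143-patient subset.  These sizes are the defaults of
`CohortConfig`; all parameters below are configurable.

**Elements.** ICP-MS concentration data are right-skewed, so every
element is log-normal.  Per-element medians and geometric SDs
(`views.CSF_ELEMENT_SCALE`, `views.PLASMA_ELEMENT_SCALE`) are synthetic
defaults placed at physiologically plausible magnitudes; tightly
regulated plasma electrolytes (Ca, Na) get small spreads.  Correlation
structure comes from a Gaussian copula on the log scale: each configured
`FactorBlock` has one latent factor; an element in a block with
correlation rho is `sqrt(rho)*g_block + sqrt(1-rho)*noise`.  The default
blocks mirror the groups a varimax factor analysis of such data
typically produces: a dominant 16-element CSF block, smaller CSF blocks
(Al/Cd/Pb, B/Li, Hg/Mo), and plasma analogues.

**Disease signal.** A latent severity score is normal with
diagnosis-shifted mean (AD 0.9 > MCI 0.0 > HC -1.3).  Each biomarker's
log concentration loads on severity with the canonical sign structure —
amyloid beta negative; tau isoforms, VILIP-1, NFL, S100B, YKL-40
positive — plus loadings on the dominant CSF element block (0.30) and
the dominant plasma block (0.30), so the correlation screen and the
factor regressions have recoverable signal.  The dominant block of each
view also tracks severity (0.25), which deliberately makes some
biomarker-element associations diagnosis-confounded (exercising the
adjustment stage), and the dominant CSF and plasma blocks are coupled
(0.45) to mimic shared exposure across compartments.  Even so, natural
three-way alignment in the default cohort tops out below the Jaccard
threshold of the miner, so three-view redescriptions on unplanted
synthetic cohorts are rare or absent; the three-view machinery is
validated with planted three-view subgroups instead.

**Planted redescriptions.** A `PlantedRedescription` places a random
`member_fraction` of the cohort inside every configured interval (all
views); each non-member falls inside the conditions of a view with
probability `leak_fraction` (one randomly chosen condition is pushed
outside otherwise), so the cross-view Jaccard of the planted queries has
a known lower bound of about `m / (m + 2*eps*n)`.  Planting happens
before missingness: a planted member with a masked cell simply drops out
of the support, mirroring the rule semantics for missing measurements.
An interval covering an attribute's whole support is rejected as a
configuration error.

**Missingness** is completely at random per attribute; defaults make
NFL, albumin, S100B and CSF P the sparsest measurements so that
pairwise-complete sample sizes vary across the correlation table.
Patients outside the plasma subset have the entire plasma view missing.
Informative missingness and assay-noise mechanisms (plate effects,
instrument drift) are out of scope.

What passing tests show: the pipeline recovers structure *of the kind it
assumes* (log-normal margins, latent-factor blocks, interval-defined
subgroups).  Real cohort data have heavier tails, batch effects, and
missingness correlated with severity; nothing here certifies behaviour
under those violations.

## Correlation screen (`csfmetals.screen`)

One record per (biomarker, element, view) pair on pairwise-complete
observations (n >= 3 required; zero-variance vectors are rejected).
Spearman is the primary coefficient (Pearson on average ranks); Pearson
is reported alongside, and no per-pair auto-switch is attempted.  p
comes from the two-sided t approximation with n-2 degrees of freedom.
Multiple-comparison control is operationalized as a hard p <= 0.001
gate (configurable).

Adjustment computes residual-on-residual partial correlations: x and y
(ranks first for Spearman, as are numeric covariates) are regressed on
the covariate design (categoricals one-hot encoded, intercept included)
and the residuals correlated, with n-2-k degrees of freedom.  A pair is
"retained" when the partial p still meets the gate.  Complete cases per
model: a patient missing disease duration is dropped only from fits
that use it.  Rank-deficient designs raise an error naming the
collinear columns.

## Factor model (`csfmetals.factors`)

Each element view is reduced by PCA on the correlation matrix of its
complete-case standardized submatrix; the CSF view drops P by default
because its 60% missingness would collapse the complete-case sample.
Six components are extracted by default (an eigenvalue>1 rule is
available via `n_factors="kaiser"`), then varimax-rotated with Kaiser
row normalization (SVD algorithm, tolerance 1e-8, up to 1000 sweeps).
Factor columns are ordered by explained variance and signed so the
largest-magnitude loading is positive.  Rotation is orthogonal, so
communalities, total explained variance, and the reduced-rank
reconstruction error are invariant (checked to 1e-8 or better).

Adequacy: Bartlett's sphericity chi2 = -(n-1-(2p+5)/6) ln det R with
p(p-1)/2 degrees of freedom, and the KMO index from squared
correlations versus squared anti-image partial correlations (computed
from the inverse correlation matrix).  Near-singular R raises an error
advising column removal.

Group assignment: an element joins the factor of its largest absolute
loading when that magnitude reaches the threshold (default 0.4);
negative loadings assign by magnitude and keep their sign in reports;
sub-threshold elements are listed as unassigned with their best
loading, rather than being forced into a group.

Factor scores use the regression (Thompson) method, `Z R^-1 L`, on the
complete-case standardized data.  Each biomarker is regressed on all
factor scores simultaneously (OLS, >= 10 complete cases); reports give
the standardized coefficient, the SE of the unstandardized coefficient,
p, and a 95% CI per factor.

## Redescription miner (`csfmetals.mining`)

A redescription is a pair or triple of AND-only conjunctive queries on
distinct views describing nearly the same patients.  Conditions are
closed intervals `[low, high]` at observed data values or categorical
equalities; a patient missing any used attribute is not described.
Accuracy is the Jaccard index |intersection| / |union| of the query
supports (0/0 := 0).

**Significance.** The p-value is the probability that independent
uniformly random patient subsets of the observed sizes intersect at
least as much as observed: exactly the hypergeometric upper tail for
two sets; for three sets an exact convolution of conditional
hypergeometrics (used whenever the universe has <= 500 patients),
otherwise seeded Monte Carlo.  Tests verify exact equality with full
enumeration on universes up to 12 patients.

**Mining universe.** A mining task's universe is the set of patients
with at least one measurement in every participating view.  A patient
whose plasma view is entirely missing can never be described by a
plasma rule; keeping such patients would only inflate unions and
misstate the significance model's universe size.  With the default
cohort this makes plasma-inclusive tasks run on 143 patients.

**Search.** Per seeded run: (1) k-means (k = 8) on the first view's
standardized complete-case data provides the initial target partition;
(2) each view's rule archive is seeded with systematic marginal rules —
every contiguous decile interval (width >= 2 deciles) of every
attribute, plus categorical levels, support-bound filtered — which are
ordinary one-condition queries and give the scoring stage a complete
single-condition baseline; (3) for 30 alternations, a multi-target
variance-reduction regression tree (plus a 20-tree bootstrap forest
with random feature subsets, each forest tree specializing on 1-2
randomly chosen targets) is grown on each view to predict the other
view's most recent rule supports (round-robin for three views), and
every root-to-node path becomes a query, with per-attribute constraints
merged and snapped to attained values; (4) all cross-view combinations
of archived rules are scored by Jaccard; candidates are prioritized by
Jaccard *excess* over the expected Jaccard of independent same-size
subsets and deduplicated by intersection support (raw Jaccard ordering
lets broad pairs, which overlap heavily by chance, crowd out genuine
subgroups); (5) surviving candidates are greedily refined by ANDing
single conditions from the discovered pool while Jaccard strictly
increases and support stays above the minimum, then interval bounds are
tightened to the value range attained on the intersection when that
improves Jaccard; (6) filters (support bounds, Jaccard >= 0.5,
p <= 0.01 by default) are applied, results pooled over 10 runs,
deduplicated by (support set, attribute multiset) keeping the higher
Jaccard then the shorter rule, and sorted by p-value.

Clinical covariates (MMSE, age, APOE) ride along with the biomarker
view, where they may appear in reported rules.  Categorical one-hot
splits map to equality conditions on the positive branch; the negative
branch is a negation, which the AND-only rule language excludes, so it
is dropped from the harvested query (this only widens a candidate).

**Overfitting control.** Two defaults keep the search from
manufacturing redescriptions out of noise, chosen as the least
restrictive settings for which twenty independent-view cohorts yield
zero emitted redescriptions at full default search effort:
`min_samples_leaf` equals the minimal support (a leaf below minimal
support cannot yield a valid rule, and finer leaves let the alternation
carve 4-5 sigma spurious alignments), and individual queries are capped
at 45% of the universe (`max_query_support_frac`) — with millions of
rule pairs scored per run, pairs of half-cohort rules reach Jaccard 0.5
by selection chance alone, and the random-subset significance model has
no power against breadth.  The cap means the miner will not report
rules broader than ~0.45n even where such rules would be legitimate;
relax it explicitly if breadth matters more than the false-discovery
guarantee.

**Specificity labels.** Per-diagnosis percentages use each diagnosis
group's full size as denominator.  A single-group label requires that
group's percentage to be >= 1.5x each other group's; the adjacent pairs
AD&MCI and HC&MCI require both top groups >= 1.5x the third; everything
else is labelled none.  The dominance factor 1.5 is a package invention
(no external rule exists) and is configurable.

## Reporting (`csfmetals.pipeline`)

`run_pipeline` orchestrates all stages from one config and seed, writes
plain CSV/TSV/JSON outputs (correlations, factor solutions and
regressions, redescription lists and summary tables, co-occurrence
counts) and a manifest with the master seed, derived per-stage seeds,
parameters, package version and row counts — and no timestamps, so
identical configs produce byte-identical bundles.  Rendered tables
round correlations to 3 decimals, Jaccard to 5, percentages to 1;
rendering never computes, only formats.

## Problem sizes used in the validation studies

The shipped studies run at the cohort's natural scale (n = 193):
planted-recovery uses ten cohorts with three planted subgroups each
(supports 40-60, leak 0.05) mined at full default effort; the
false-discovery audit uses twenty independent-view cohorts; screen
calibration uses 50,000 null pairs of length 100; the confounder study
uses 100 replicates.  The `scripts/acceptance.py` reproduction script
runs the same computations with three seeds per simulation study.

One consistency check deserves a note: the test that reconstructs a
subgroup's support from its per-diagnosis percentages uses a
125-patient AD denominator, because that is the only denominator under
which the percentages land on integer counts (45/125 = 36.0%), even
though the cohort itself has 124 AD patients.  The generator keeps 124;
the check documents the one-patient discrepancy rather than resolving
it.

## Known limitations

- The significance model ignores the search's selection effect; the
  overfitting controls above are what keep the false-discovery rate at
  zero on independent views, not the p-value itself.
- MCAR missingness and log-normal margins are idealizations; see the
  generator section.
- The varimax solution is unique only up to column permutation and
  sign; deterministic ordering/sign conventions are applied, but
  loadings for nearly-tied factors can swap between datasets.
- Specificity labelling with dominance 1.5 is heuristic; borderline
  subgroups get `none` rather than a forced label.
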