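# Methods

This note documents the models, numerical choices, and design decisions in
`capdyn`, and what the synthetic-data experiments do and do not demonstrate.

## Frame-level preprocessing

Input cohorts are parcellated BOLD matrices (frames × parcels) per subject,
day, and run, with a framewise-displacement (FD) series per frame.  Per run,
the first `n_dummy` frames (default 100) are dropped from signal and FD, the
per-parcel run mean is subtracted, and runs are concatenated in acquisition
order (default permutation 2-1-4-3 of the stored runs, truncated to the
actual run count).  Motion scrubbing removes frames with FD strictly greater
than 0.5 mm; a frame with FD exactly at the threshold is kept.  Scrubbing is
represented as a boolean mask rather than by deleting frames, so original
frame indices remain addressable for diagnostics; the mask is applied at
clustering and metric time.  Run length is data-driven and never hard-coded.

## Split-half permutation CAP estimation

Each permutation splits the subject list into two disjoint halves of size
⌊N/2⌋, excluding one uniformly chosen subject when N is odd.  Per split, the
kept frames of all member subjects (both days) are concatenated and clustered
with Lloyd's k-means for each k in the scan range (default 2–8 in the bundled
configurations; the upper bound is configurable and conventionally 15).
Numerical choices:

* k-means++ initialization with 3 restarts per k (best inertia kept).  A
  single initialization occasionally lands in a poor local optimum at the
  true k, denting the silhouette curve and destabilizing the elbow; three
  restarts remove nearly all such events at modest cost.
* max 1,000 Lloyd iterations, tolerance 1e-4 on inertia.
* Mean silhouette computed on a seeded uniform subsample of 2,000 frames
  (all frames when the pool is smaller); subsample size is configurable and
  recorded.
* An empty cluster triggers a re-run from a freshly derived seed (≤ 5
  retries).

**Elbow rule.**  With k and silhouette range-normalized to [0, 1], the knee
is the first interior local maximum of the excess of the curve above the
chord joining its endpoints (`y + x − 1` for a decreasing curve).  Taking the
*first* local maximum rather than the global one makes the rule robust to
noisy bumps in the high-k tail, which are artifacts of silhouette subsampling
and local optima, not knees.  A curve with no point above the chord (e.g. a
straight-line decline) has no knee; the rule falls back to the silhouette
argmax with a warning.  Ties break toward smaller k.

All per-permutation seeds derive from one base seed via
`numpy.random.SeedSequence` spawning, so permutations are independent and
results do not depend on execution order.  Failed permutations are recorded
in the ledger with their error, never silently dropped.

## Basis CAPs, matching, Δ occurrence

Centroids from every split with the same k̂ are stacked and clustered by
ward/Euclidean agglomeration into k̂ clusters; each cluster's parcel-wise
mean is z-scored across parcels (mean 0, SD 1) to give a basis CAP.  Ward
linkage is used because it is the one linkage the pipeline specifies
elsewhere (neural features); basis construction is deterministic given the
ledger and invariant to permutation order.

Estimated CAPs are labeled against a basis set by **greedy rank-ordered
one-to-one Pearson matching**: the full estimated × basis correlation matrix
is computed over parcels and the globally largest unused pair is taken
repeatedly.  "Rank correlation" in the matching context is interpreted as
this rank-ordered greedy assignment of Pearson correlations (a Spearman
option exists behind a flag), because the surrounding spatial-similarity
analyses are all Pearson.  Ties at machine precision break toward the lower
basis index, logged.  On noisy-copy instances the greedy assignment agrees
with the exhaustive optimum essentially always; on uncorrelated random
inputs no matcher is meaningful.

Conventional names are assigned post hoc: anti-correlated pattern pairs
(most-negative spatial correlation, greedily) become I±, II±; an unpaired
pattern becomes III.  Within a pair, "+" goes to the member whose
largest-|z| parcel is positive — the naming is arbitrary by construction.

**Δ occurrence.**  Per subject per split, the number of permutations (among
those whose split contained the subject) yielding k̂ = 5 minus those
yielding k̂ = 4; solutions with other k̂ count toward neither.  The
per-split differences are averaged within subject and z-scored across
subjects (population SD).  Zero across-subject variance yields all-zero
z-scores with a warning rather than NaNs.

## Temporal metrics

Kept frames are assigned to states by nearest centroid (Euclidean — the
k-means criterion) or, against a basis set, by maximum Pearson correlation
with the per-frame maximum r returned (zero-variance frames fall back to the
Euclidean rule and are flagged).  The post-scrub label sequence is run-length
encoded; consequently same-state frames on both sides of a scrubbed gap merge
into one segment, and a scrubbed middle state shortens the apparent dwell
([I,II,I] with II scrubbed → DT 2).  Segments never span the day boundary;
by default they also break at run boundaries, since runs are not contiguous
in time (a no-break option exists).

Per subject × CAP × day: FO = kept frames in state / all kept frames (the
denominator is kept frames, not pre-scrub frames); mean DT = mean segment
length in TR; var DT = SD of segment lengths.  Var DT uses the population SD
(ddof 0) so a single segment gives 0 rather than NaN, consistent with the
zero-for-degenerate convention used throughout; a sample-SD switch exists.
CAPs never visited in a subject-day get all-zero metrics.

Permutation averaging emits two variants per cell: the include-as-zeros mean
over all permutations containing the subject (used for the feature matrix)
and a present-only mean over permutations whose solution contained that CAP
(used for reliability of the rare CAP III, where structurally zero days
carry no signal).  Both are clearly named in the output table.

## Reliability statistics

ICC(2,1) is the two-way random-effects, absolute-agreement, single-measure
intraclass correlation computed from explicit ANOVA mean squares.  Undefined
cases (zero total variance, < 2 subjects) raise a typed signal in the scalar
function and become NaN rows with a warning in the report tables, so
permutation-level ICC distributions can skip undefined draws with a count.
Day-to-day Pearson correlations per CAP × metric use the permutation-averaged
values across subjects; for CAP III, subjects zero on both days are excluded.
The three-axes table reports the across-subject coefficient of variation
(SD/mean, population SD by default) of each metric per CAP per day; the
between-day displacement of a CAP in this space reads out its state variance.

## Feature space and association

The feature matrix is subjects × (3 metrics × k CAPs × 2 days), metric-major
column order, zeros for absent CAPs, z-scored per column by default (FO is a
fraction, DT measures are in TR — incommensurate units; the flag is
recorded and the raw variant available).  Subgroups come from ward/Euclidean
agglomeration with flat clusters cut at 70 % of the final merge height (the
cut fraction is configurable, including the 7 % variant that appears in some
descriptions of this procedure).  Note that any fractional cut strictly below
the final merge necessarily yields at least two flat clusters; a single
cluster can only arise from degenerate (identical-row) input, which is
special-cased with a warning.

PCA is computed by SVD of the column-centered matrix with a deterministic
sign convention (largest-|loading| element positive).  For each component
the 30 loadings are split into day-1/day-2 halves matched feature-by-feature
and their Pearson r reported; a strongly negative value flags a "day-flip"
component that encodes systematic day-to-day change.

Behavioral preparation converts reaction-time variables to 1/RT (a guard
refuses double preparation), then centers and unit-scales every column.
Behavioral-PC significance uses a null built by independently permuting
subject order within each variable — this breaks inter-variable correlation
while preserving marginals; permuting whole rows would leave the correlation
structure intact and test nothing.  P-values use the add-one estimator
(1 + #{null ≥ observed}) / (1 + n_perm).  Split-half reproducibility reports
|r| between same-rank loading vectors of PCAs fit in random half-cohorts
(absolute value absorbs PCA sign indeterminacy).

The association model is OLS `behavioral PC ~ 3 neural PCs + age + sex`;
partial R² per predictor is the proportional reduction in error sum of
squares when the predictor enters the otherwise-full model.  Subgroup
comparisons use Welch two-sided t-tests with an explicit Bonferroni family of
(components tested) × (subgroup pairs), recorded in the output.  Cross-
validated prediction refits both PCAs and the regression on split 1 and
projects split-2 subjects onto the split-1 component spaces (split-1
centering); held-out R² = 1 − SSE/SST on split 2, with a null from shuffling
the split-2 scores.

## Synthetic cohorts: what they emulate

The generator plants K spatial patterns built as sign-flipped anti-correlated
pairs (plus one optional extra state), z-scored across parcels.  State
sequences are Markov chains started from their stationary distribution, one
chain per run.  Trait and state variance are Gaussian perturbations on the
self-transition logit: subject effect ~ N(0, trait_sd), day effect
~ N(0, day_sd), giving direct control of the ICC the reliability module
should recover.  Frames are `snr × pattern + N(0, 1)` i.i.d. per parcel.
FD series are a low baseline (|N(0.08, 0.03)|) plus per-frame spikes
(probability 0.02, magnitude 1 mm — above the scrub threshold).  Behavioral
variables are linear in two latent neural factors (the z-scored stationary
occupancy of state I+ and the mean persistence logit) plus N(0, 1) noise; a
subset is stored as strictly positive reaction-time variables of the form
1/(shift + y) so the reciprocal transform recovers the underlying linear
variable exactly, and a sex effect is planted in a random 10 % of variables.

Reference conditions: 20 subjects, 64 parcels, 2 runs × 200 frames per day,
2 days, TR 0.72 s, 4 base states with p_stay = 0.8 (mean dwell 5 TR),
trait_sd 0.5, day_sd 0.2, snr 1.  30 % of subjects ("subgroup C") carry the
extra state III at a stationary occupancy of 0.03, implemented by giving
every other state a small absolute entry probability into III (entry =
π(1 − p_stay)/(1 − π)).  The low occupancy is what makes detection of the
fifth state depend on how many carriers a split contains — the mechanism
behind the bimodal k̂ ∈ {4, 5} across split-half permutations and the
Δ-occurrence separation of carriers; at high occupancy every split detects
five states and the phenomenon disappears.  The remaining subjects split
into subgroups A and B, with B shifted (+0.75) on the CAP II self-transition
logits to give the feature space real subgroup structure.

**What these simulations do not emulate:** hemodynamic convolution and
temporal autocorrelation of noise, spatial autocorrelation across parcels,
non-Gaussian artifacts, realistic HCP run lengths, or behavioral measurement
structure beyond a linear factor model.  Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the stated
generative assumptions, not performance on real rs-fMRI.

## Problem sizes in the test and acceptance runs

The bundled experiments use the reference conditions above with 50
permutations (4-state recovery), 100 permutations (extra-CAP phenomenon),
and 5–15 permutations per point for the reliability sweep.  The
zero-day-variance ICC calibration uses 1,600-frame runs (3,200 frames/day):
the realized occupancy of a finite Markov chain differs from its stationary
probability by sampling noise of order √(p(1−p)(1+p_stay)/(1−p_stay)/n), so
day-to-day ICC approaches 1 only as sequences lengthen — at 400 frames/day
the ceiling is ≈ 0.77 even with identical transition matrices on both days,
and the frame-assignment step itself is exact (estimated FO correlates 1.000
with realized occupancy).  The acceptance script runs 100 permutations on
the mixed cohort.

## Known limitations

* Silhouette subsampling makes k̂ stochastic near curve plateaus; the
  first-local-maximum elbow rule reduces but does not eliminate rare 6/7-CAP
  solutions, which remain in the ledger (they count toward neither side of
  the Δ-occurrence statistic).
* Greedy matching is not globally optimal in adversarial cases; an
  exhaustive matcher is provided for small k and used as a cross-check.
* ICC(2,1) assumes the two-way random-effects model; with only 2 sessions
  the session mean square is noisy, and permutation-level ICC distributions
  should be interpreted accordingly.
* The pipeline treats each subject-day as a separate sequence and by default
  breaks dwell segments at run boundaries; whether to bridge runs is a
  substantive choice exposed as configuration.
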