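# Methods

## The model

`t2ebm` implements an event-based model (EBM) of disease progression for
cross-sectional two-group data, together with the PCA front end used to
compress item-level neuropsychological batteries into a small biomarker
panel, maximum-likelihood subject staging, and the downstream inferential
layer (covariate-adjusted group comparisons, partial correlations,
Benjamini–Hochberg FDR).

An *event* is one biomarker's transition from its normal distribution to
its abnormal distribution. The model assumes

- a single ordering σ of the K events shared by all subjects;
- each subject sits at a latent stage k ∈ {0..K}: the first k events of σ
  have occurred, the rest have not;
- given the event indicator, a biomarker value is drawn from a Gaussian
  normal or abnormal component specific to that biomarker;
- biomarkers are conditionally independent given the stage.

Because earlier events are abnormal in more subjects, a cross-sectional
cohort spanning a range of stages identifies the ordering without any
longitudinal data.

### Per-biomarker mixtures

For each (direction-harmonized) biomarker a two-component Gaussian mixture
is fitted by EM on the pooled cohort (`fit_abnormality_model`). The normal
component is initialized from the healthy-control moments and, by default,
bounded by them (mean within ±1 control SD, SD within [0.5, 1.5]× the
control SD); the abnormal mean is constrained above the normal mean. Five
EM restarts are run; among restarts whose final log-likelihood ties within
2 nats, the fit with the smallest abnormal weight is kept, so that under
null signal the model claims the weakest abnormality consistent with the
data rather than an arbitrary bulk split.

The control anchor presumes largely event-free controls. When controls are
themselves staged (as in this synthetic design, which mirrors a study where
controls received nonzero stages), marginal mixtures are weakly identified
for events that almost everyone or almost no one has passed. `fit_ebm`
therefore treats the marginal fits only as initialization and refines all
components jointly (below).

### Posteriors, ordering, event-centers

Subject values map to event posteriors P(event occurred | value) by Bayes'
rule. The central ordering minimizes the summed *probabilistic Kendall
distance* to the patients' posterior vectors: for an ordering placing i
before j, a subject contributes |p_i − p_j| whenever p_j > p_i. The pair
weight makes confident discordances cost more and reduces to the classic
Kendall distance for binary posteriors. Because the total distance
decomposes over ordered pairs, the search is a linear ordering problem:
for K ≤ 7 all K! permutations are scored exactly (lexicographic
tie-break); above that, a descending-mean-posterior start is refined by
adjacent swaps and single-event insertions until no move improves.

Event-centers place each event on a [0,1] timeline: the
certainty-weighted mean of its normalized rank (rank − ½)/K in each
subject's descending-posterior order, with subject weights
c_s = mean|2p − 1|, made monotone along the ordering by
pool-adjacent-violators. The estimator is a stated stand-in: the source
methodology only fixes the [0,1] normalization, not the estimator.

### Joint refinement

With staged controls the marginal mixtures mislabel saturated events, so
`fit_ebm` runs a likelihood-guarded coordinate ascent on the joint model
(components + per-event prevalence + stage prior π + ordering):

1. *EM at fixed ordering*: E-step computes each subject's stage posterior;
   M-step re-estimates π (mean posterior mass), each component's moments
   from soft event-occurred labels, and each event's prevalence. A
   component side carrying under one effective subject is left untouched
   (unidentified), and component SDs are floored at 0.1× the column SD so
   degenerate spikes cannot dominate the likelihood. EM runs to
   convergence (|Δll| < 1e−4) so configurations are compared at equal
   convergence.
2. *Ordering proposals*: (a) a global event-to-position assignment — each
   event's profile likelihood at every position is scored against the
   leave-one-event-out stage field with a single moment fit, an AIC-style
   penalty per estimated component side, and a small skewness term that
   breaks the exact tie between the two sequence ends for saturated
   events; the Hungarian algorithm returns the jointly best assignment —
   and (b) an insertion descent on the joint likelihood. Each proposal is
   re-fitted by EM and accepted only if the joint log-likelihood improves.
3. Starting orderings: a severity-transition ordering (each marker's
   running-mean crossing along a leave-one-out severity ranking; saturated
   markers placed toward the end suggested by their skewness), the
   descending mean marginal posterior, the marginal Kendall solution, and
   (for K ≤ 12) end-flipped variants of the first; the refit with the best
   joint log-likelihood wins.

The reported `EventSequence` is the Kendall central ordering of the
refined posteriors, whose prevalences are the stage-field event
frequencies, so the two views coincide in practice.

### Staging

Stage likelihood multiplies abnormal-component densities for passed events
and normal-component densities for pending ones; everything is computed in
log space (stable for values tens of SDs out). An EM loop refines the
cohort stage prior starting from uniform (E: stage posteriors; M: prior =
mean posterior mass; monotone total log-likelihood). The headline
per-subject summary is the posterior-mean stage divided by K — a [0,1]
severity index — matching a study design that reports continuous group
means with SDs; MAP stages (ties toward the smaller stage) are also
emitted. Both groups are staged under the patient-fitted sequence.

### Bootstrap

Ordering confidence is a subject-level bootstrap: B resamples with
replacement, full refit (mixtures + ordering) per resample, warm-started
from the full-data ordering; a resample missing one group entirely is
redrawn (at most 10 times). The positional-variance matrix F[i, m] is the
frequency of biomarker i at position m; rows and columns each sum to 1.

## PCA front end

Battery items are z-scored against the controls and decomposed on the
correlation matrix (trace = p), so eigenvalue thresholds are meaningful.
Sampling adequacy uses the KMO statistic (anti-image partial correlations
from the inverse correlation matrix) and Bartlett's sphericity test
χ² = −(n − 1 − (2p+5)/6)·ln det R with p(p−1)/2 degrees of freedom.
Component selection follows the Kaiser rule (eigenvalue > 1, the operative
rule downstream); the Jolliffe variant (cumulative variance > 70% with all
eigenvalues > 0.7) is computed alongside and a warning is raised when the
two disagree. Scores are z-items × unit-norm eigenvectors with the sign
fixed so each component's largest-magnitude loading is positive
(deterministic across eigendecomposition backends); no rotation is
applied. The per-battery composite is the eigenvalue-weighted mean of the
selected component scores; an equal-weight alternative is available, since
the source only states that a composite was formed, not its weights.

## Preprocessing

Fixed order: direction harmonization (higher = more abnormal; higher-is-
better columns are negated) → z-scoring against the healthy controls
(n−1 SD) → OLS residualization of age, sex and education fitted on the
controls only and applied to everyone. Controls are the reference because
the EBM's "normal" anchor must be disease-free. GMV features are the mean
GMV of their member AAL regions per hemisphere (17 × 2 features plus the
cerebellar vermis = 35 columns) and are divided by total intracranial
volume before z-scoring (flag-controlled, default on).

## Statistics

Group comparisons are per-outcome ANCOVAs (`outcome ~ group + age + sex +
education`, partial F for the group term, adjusted means at the grand
covariate means) — per-outcome rather than a single multivariate model,
matching per-variable F reporting. The EBM stage contrast is a
pooled-variance t-test, as stage covariates were already removed upstream.
The sex table uses the Pearson χ² without continuity correction. Partial
correlations are Pearson correlations of OLS residuals on (intercept +
covariates) with p-values from the t transform at df = n − k − 2;
multiplicity is controlled per analysis family (group comparisons; the
clinical-correlation grid) by Benjamini–Hochberg.

## The synthetic cohort

The generator emulates the study conditions: 119 patients vs 87 controls;
a 16-marker cognitive panel (MMSE, MoCA, TMT-A/B, SAS, SDS and the
CVLT/STROOP/WCST principal-component scores) with a 2-SD normal/abnormal
separation on the harmonized scale; subject stages binomial(K, 0.55) for
patients and binomial(K, 0.45) for controls — overlapping but shifted, the
simplest two-parameter family echoing the reported normalized stage means
(≈0.54 vs ≈0.49), with controls drawn from the same event process because
the study assigns controls nonzero stages. Battery items load 0.8 on their
assigned factor plus Gaussian noise (SD 0.6); the latent factors are the
negated harmonized PC biomarkers, so the PCA stage recovers structure that
is genuinely disease-related. Item lists follow the named item groups:
CVLT 17 items/4 factors, STROOP 11/2, WCST 15/4. Linear age/sex/education
confounds are added to every marker; clinical chemistry is drawn from
group-specific normals matched to the published group means/SDs and is
deliberately *not* coupled to the cognitive scores beyond group
membership, so the correlation stage is exercised without a built-in
effect. A regional GMV table (AAL region volumes plus TIV) atrophies in a
separate ground-truth order with stages proportional to the cognitive
stages (3% volume loss per abnormality unit, 1% measurement noise).

What the generator does **not** emulate: missing data, scanner or site
effects, non-Gaussian score distributions, floor/ceiling effects of real
neuropsychological instruments, and any direct glucose–cognition coupling.
Passing recovery tests therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not performance on real data.

## Known limitations and honest failure modes

With binomial stage distributions at these sample sizes the earliest and
latest events are frequently *saturated*: no subject is observed on the
minority side of the mixture. In roughly half of simulated cohorts there
is no subject at stage 0 and none at stage K, in which case the two end
events are exactly exchangeable between the two sequence ends — the
likelihood is identical under the flip, and no estimator can resolve it
(the skewness tie-break is then an unbiased coin). Mixture-weight
estimation error at 2-SD component overlap (weight SE ≈ 0.1–0.2 at
n ≈ 200) further limits the resolution of adjacent mid-sequence
positions. Concretely, at K = 10 and n = 206 the median Kendall tau-b
between recovered and true orderings is ≈ 0.5 for this implementation,
while an oracle given the true mixture parameters reaches 1.0; for
staging, the Bayes posterior mean computed from the true parameters caps
the true-vs-estimated stage correlation at a median of ≈ 0.88 under these
same conditions — a ceiling inherent to the stage posterior's width, not
to the estimator. The positional-variance bootstrap is the honest report
of this uncertainty and shows exactly which positions are firm.

Problem sizes used in the shipped tests and acceptance script (20 or 10
cohorts of 206 subjects, K = 10; bootstrap B = 100 or 25; FDR calibration
with 1000 replicates of 10 tests) were chosen to exercise the study-scale
regime while keeping a full run in the minutes range.

## Numerical choices

- All randomness flows from one root `SeedSequence` with named substreams
  per stage, so changing the bootstrap count does not perturb simulation
  draws.
- Mixture EM: tolerance 1e−6, max 500 iterations, 5 restarts; component SD
  floor 1e−8 (marginal) / 0.1 column SD (joint refinement).
- Severity quantization {0, ⅓, ⅔, 1} rounds ties up and is reporting-only.
- Stage posteriors are computed in log space with `logsumexp`; stage-prior
  EM tolerance 1e−8, max 200 iterations.
- Kendall ordering ties break lexicographically; event-center monotonicity
  via isotonic regression clipped to [0, 1].
- The SAS/SDS mood scales are included as events by default and excludable
  by config, since their role in the source battery is ambiguous.
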