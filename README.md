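# t2ebm — event-based modelling of cognitive decline in type 2 diabetes

Type 2 diabetes mellitus (T2DM) is a major risk factor for cognitive
impairment, but cross-sectional studies cannot directly observe *in what
order* cognitive domains and brain structures deteriorate. `t2ebm`
implements the analysis chain that answers this from a single
cross-sectional two-group sample:

1. **PCA reduction** of item-level neuropsychological batteries
   (CVLT, STROOP, WCST) to a few principal-component scores, with
   Kaiser–Meyer–Olkin and Bartlett sphericity adequacy checks and the
   Kaiser eigenvalue-greater-than-1 selection rule;
2. an **event-based model (EBM)**: per-biomarker normal/abnormal Gaussian
   mixtures, per-subject event posteriors, and the central event sequence
   σ minimizing the summed probabilistic Kendall-τ distance
   Σ_s Σ_{i≺j} |p_si − p_sj|·1[p_sj > p_si], with event-centers on a
   [0,1] progression timeline and bootstrap positional-variance
   diagnostics;
3. **maximum-likelihood staging**: each subject's stage k maximizes
   L(k) = Π_{m≤k} f_a(x_{σ(m)}) · Π_{m>k} f_n(x_{σ(m)}) with an
   EM-refined stage prior; the group summary is the posterior-mean stage
   normalized to [0,1];
4. a **statistical layer**: age/sex/education-adjusted ANCOVAs, the stage
   t-test, the sex χ², partial correlations with clinical chemistry, and
   Benjamini–Hochberg FDR per analysis family.

Because the study's subject-level data are not deposited, the package
ships a **synthetic-cohort generator** with a known ground-truth event
sequence, per-subject stages, factor-structured battery items, regional
gray-matter volumes and covariate confounds, so every stage of the
pipeline is testable against an answer key. It is aimed at methodologists
and students who want a transparent, fully testable EBM reference
implementation, not a clinical tool.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate_cohort.py     # cohort + ground truth -> results/cohort/
python analysis/02_reduce_batteries.py    # battery PCA -> results/pca/
python analysis/03_fit_cognitive_ebm.py   # EBM + bootstrap -> results/ebm_cognitive/
python analysis/04_stage_subjects.py      # staging -> results/staging/
python analysis/05_group_statistics.py    # ANCOVA/correlations -> results/stats/
python analysis/06_fit_gmv_ebm.py         # 35-ROI GMV EBM -> results/ebm_gmv/
```

Output of steps 01–02 (a 119-patient / 87-control cohort):

```
cohort written to results/cohort
  119 patients / 87 controls, K=16 cognitive events
  true first event: STROOP_PC2
  mean true stage patients=8.88, controls=6.93
CVLT: KMO=0.853, Bartlett chi2=2465.2 (p=0.00e+00), 4 components kept
  (77.88% of variance), eigenvalues [5.01, 3.33, 3.24, 1.65]
STROOP: KMO=0.939, Bartlett chi2=1790.3 (p=0.00e+00), 2 components kept
WCST: KMO=0.855, Bartlett chi2=1751.8 (p=1.34e-296), 4 components kept
```

The Kaiser rule recovers exactly the planted factor counts (4/2/4). Step
04 then reports

```
normalized EBM stage: patients 0.59 (0.16) vs controls 0.49 (0.16)
pooled t(204) = 4.43, p = 1.56e-05
correlation with true stages: r = 0.78
```

— patients sit significantly later on the inferred timeline than
controls, and the per-subject stages track the generator's hidden stages.
Step 03 prints the recovered cascade with its event-centers and its
Kendall τ against the hidden ordering, plus how many markers keep their
modal position across 50 bootstrap refits: with overlapping mixtures and
binomial stages many extreme sequence positions are genuinely
under-determined, and the positional-variance matrix makes that
uncertainty explicit (see `docs/methods.md` for the identifiability
analysis). Step 05's partial-correlation family finds no survivor after
FDR — correct, since the generator couples clinical chemistry to group
membership only.

A single command runs everything end to end and writes a machine-readable
run manifest:

```bash
t2ebm run --seed 1 --out results/full_run       # or: python -m t2ebm.cli ...
t2ebm simulate --seed 3 --out mycohort/         # individual stages: pca/ebm/stage/stats
```

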