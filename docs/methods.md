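# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions, for maintainers and users who
want to know exactly what is computed.

## Stratification and aggregation

Tumour samples are labelled marker-negative iff their marker expression is
*strictly* lower than the mean over normal samples; a value exactly equal
to the reference mean is positive. Probe-level β values are averaged per
(gene, region, sample) over non-missing probes; a probe annotated to
several (gene, region) pairs contributes to all of them, annotations are
taken at face value (no TSS200/TSS1500 precedence re-assignment), and a
pair whose probes are all missing in a sample stays missing. Expression is
assumed to be on the log2 scale already; the CLI's `--log2-offset` applies
log2(x+1) for raw counts.

## Differential calling

Per-feature two-group comparison uses the Welch unequal-variance t-test on
β or log2 values directly, with Benjamini–Hochberg adjustment (statsmodels)
over all tested features. A moderated/shrinkage t statistic is deliberately
not used: the pipeline's substance is the thresholding and integration
scheme, and the plain Welch test keeps the statistic transparent; the test
function is an argument where it matters. Features with zero variance in
both groups get p = 1. Methylation testing runs on β values, not M values,
because the effect-size thresholds are defined on Δβ. Multiple-testing
families are per region for methylation (each region is BH-adjusted
separately), one family for expression.

Thresholds (all strict inequalities):

| call | effect | FDR |
|---|---|---|
| DMS | \|Δβ\| > 0.3 | < 0.05 |
| DMG (hyper / hypo) | Δβ > 0.3 / < −0.3 | < 0.01 |
| DEG (up / down) | log2FC > 1 / < −1 | < 0.01 |

The expression threshold is exposed as a flag (`lfc_min`) because an
alternative convention of |FC| > 1.5 exists in practice; the default is 1
on the log2 scale.

Quadrant integration assigns each per-region gene in DMG ∩ DEG exactly one
of HyperUp/HyperDown/HypoUp/HypoDown. A gene assigned different quadrants
in different regions keeps the quadrant from the region with the smallest
methylation FDR (ties broken by lexicographic region order); the conflict
is reported. Gene-set over-representation is a one-sided hypergeometric
upper tail against a user-supplied GMT collection intersected with the
analysis universe.

## Network proximity

The disease–drug distance is the closest-distance form: for each target,
the minimum hop count to the disease set, plus a weight −ln(deg(t)+1) for
targets that are themselves disease genes (weighted mode); the drug score
is the average over targets. Conventions:

- Distances are unweighted, undirected hop counts (multi-source BFS).
- The degree in the weight is the network degree of the target node t,
  applied when t is in the disease set. Weighted distances can be negative.
- Targets absent from the network or unreachable from the disease set are
  excluded from the average (and logged) rather than scored as infinite.
- The random reference draws target-size-matched node sets uniformly from
  the whole network, 10,000 repetitions by default; a degree-binned
  matching mode exists behind a flag but uniform sampling is the default,
  matching the size-matched-only reference definition.
- z = (d_obs − μ)/σ with the reference sample mean and SD (ddof = 1);
  z is undefined (NaN) when σ = 0.
- The empirical p is one-sided toward proximity with the add-one
  correction, p = (1 + #{draws < d_obs} + U·#{draws = d_obs})/(n_reps+1).
  Hop distances are discrete, so null draws tie with the observed distance
  in bulk; U is a Uniform(0,1) variable, deterministically keyed by the
  seed and the target set, that spreads each tie block so the null p is
  approximately uniform (a standard randomised/fuzzy p for discrete
  statistics). `randomize_ties=False` sets U = 1, recovering the purely
  conservative estimator.
- Seeding: the master seed spawns one substream per distinct target-set
  size, so reference distributions are cached per size and results never
  depend on the order drugs are scored in.
- Screening applies BH across the drug catalogue's empirical p values and
  flags candidates at FDR < 0.01, ranked by ascending z.

## Classification

LDA uses the pooled within-class covariance; when features outnumber
samples the pooled covariance is singular, so it is reduced to its
diagonal (configurable). Class priors are equal: the threshold is the
midpoint of the projected class means. LOOCV refits on every n−1 subset; a
training fold that collapses to one class falls back to the majority
class, logged. ROC sweeps all score thresholds with ties grouped; the
trapezoidal AUC equals the Mann–Whitney statistic with half credit for
ties.

## Prognosis

The risk score is linear in log2 expression with no intercept. Raw log2
values are used by default; optional per-gene centring/scaling parameters
can be stored in the model file. Missing model genes are a hard error
naming the genes (platforms genuinely lack some transcripts, e.g.
RP11-44K6.2 on older arrays).

- **Kaplan–Meier**: product-limit estimator; all events at a tied time are
  processed together; samples censored exactly at an event time count as
  at risk there.
- **Log-rank**: O/E/V tabulation over distinct event times with the
  hypergeometric variance; the reported hazard ratio is the O/E
  approximation exp((O1−E1)/V). Table-style HRs with Wald CIs come from
  `cox_univariate` instead, which maximises the Breslow partial likelihood
  by Newton–Raphson (step clipped to ±5; monotone likelihoods are flagged
  as separation with effectively unbounded CIs).
- **Maxstat**: exhaustive scan over midpoints between consecutive distinct
  score values, keeping splits that leave both groups at least
  `min_group_frac` (default 0.1) of the cohort; returns the cutoff with the
  largest log-rank statistic. Samples strictly above the cutoff are
  high-risk (ties at the cutoff are low-risk).
- **Time-dependent AUC**: cumulative-case / dynamic-control with inverse
  probability-of-censoring weights from the KM estimate of the censoring
  distribution, G evaluated at T− for cases and at the horizon for
  controls; horizons with no cases or no controls yield NaN, flagged.
- **Stability selection**: B repetitions (default 1,000); each subsamples
  80% of the cohort without replacement (the resampling scheme is a
  package choice; standard stability selection, exposed as a flag), fits
  an L1-penalised Cox path (scikit-survival's coxnet — the solver is a
  pluggable dependency; the wrapper is the contribution), picks the
  penalty by k-fold (default 10) cross-validated held-out Breslow partial
  likelihood, and records the nonzero-coefficient gene set. Output is the
  per-gene selection count and the count of each exact combination;
  repetitions whose subsample or folds lack events are redrawn and logged.

## The synthetic-data generator

The generator's role is to emulate the statistical structure of the real
inputs closely enough that every downstream stage can be exercised with
known truth:

- **Methylation**: background probes are iid Beta(2, 2) — bounded,
  unimodal, mid-range. Planted gene-regions use a skewed baseline
  (Beta(2, 6) before a +δ hypermethylation shift, Beta(6, 2) before a −δ
  hypomethylation shift) so the shift survives clipping to [0, 1]; this
  mirrors the biology (hypermethylation acts on initially unmethylated
  regions) and makes the planted mean Δβ equal the nominal δ. Default
  δ = 0.4 with 30 samples per group, the regime the thresholds are
  designed for.
- **Expression**: per-gene baseline N(6, 1.5) shared between groups,
  N(0, sd) noise, planted genes shifted ±lfc in group B (default 1.5). A
  designated marker gene has group-B values straddling the group-A mean so
  stratification is exercised.
- **Network and drugs**: preferential-attachment growth (degree
  heterogeneity matters for the degree weight), reduced to the giant
  component. Proximal drugs draw three quarters of their targets from the
  disease set and the rest from its direct neighbours — 8 targets by
  default, within the 1–10 range of real catalogues — so that "proximal"
  drugs genuinely sit on the disease module while decoys draw targets
  uniformly. Sampling proximal targets more diffusely (uniformly over the
  disease set plus neighbourhood) does not produce a separably proximal
  drug on networks of a few hundred nodes, defeating the generator's
  purpose.
- **Survival**: exponential event times with hazard
  `baseline_rate · exp(Σ coef_g (x_g − mean_g))` (the linear predictor is
  centred per gene so `baseline_rate` keeps its meaning), independent
  exponential censoring, `censor_rate = 0` disabling censoring.

Not emulated: probe chemistry and CpG-island structure, batch effects,
sample-level covariance between methylation and expression matrices
(planted DMEGs are coupled in direction only, per gene), network
modularity beyond preferential attachment, and non-proportional hazards.
Passing tests therefore demonstrate the machinery's correctness and
calibration under clean planted signal, not performance on real cohorts.

## Problem sizes

The test and reproduction scripts run at desk scale, chosen as the
smallest sizes at which each property is cleanly measurable: 400 genes ×
3 regions × 3 probes at n = 30/30 for the differential pipeline; 300–500
network nodes with 50 decoy drugs and 1,000–10,000 reference repetitions
for the proximity screen; n = 120–300 cohorts with 50 candidate genes,
B = 100 and 3-fold CV for stability selection.

## Known limitations

- The Welch test on β values ignores the mean–variance relation of β;
  an M-value or moderated variant would be more powerful at small n.
- The O/E hazard-ratio approximation is biased away from 1 for strong
  effects; use `cox_univariate` when the HR itself matters.
- The maxstat cutoff's log-rank p is not corrected for the maximal
  selection; treat the reported chi-square as descriptive.
- IPCW weights assume censoring independent of the score.
- Stability-selection frequencies depend on the penalty grid
  (`n_alphas`, `alpha_min_ratio`); combinations, more than per-gene
  counts, are sensitive to it.
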