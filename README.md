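# dmegnet

Combined methylation–expression analysis, network-proximity drug screening,
and prognostic risk modelling for marker-stratified cancer cohorts — built
around the workflow used to characterise PD-1-negative gastric cancer.

## What it does

Given a tumour cohort with 450k-style methylation β values, log2 expression,
a protein-interaction network, a drug→target catalogue and survival
follow-up, the pipeline:

1. **Stratifies** tumour samples into marker-negative/positive classes: a
   tumour is *negative* iff its marker (PD-1) expression is strictly below
   the mean of the normal samples.
2. **Aggregates** probe-level β to gene-region level (gene body, TSS200,
   TSS1500) by averaging non-missing probes, then calls **DMGs**
   (FDR < 0.01, Δβ beyond ±0.3) and **DEGs** (FDR < 0.01, |log2FC| > 1)
   with Welch tests and Benjamini–Hochberg adjustment. Genes passing both
   filters (**DMEGs**) are placed into the four quadrants HyperUp /
   HyperDown / HypoUp / HypoDown.
3. **Screens drugs** by weighted closest-distance network proximity.
   For disease genes *S* and drug targets *T* on the interaction network,

       d(S,T) = (1/|T|) Σ_{t∈T} [ min_{s∈S} d(s,t) + ω_t ],
       ω_t = −ln(deg(t)+1)  if t ∈ S, else 0,

   standardised against size-matched uniformly random target sets
   (10,000 repetitions by default):

       z(S,T) = (d(S,T) − μ_d(S,R)) / σ_d(S,R),

   with an add-one empirical p (randomised over tie blocks, since hop
   distances are discrete) and BH screening across the catalogue.
4. **Evaluates marker panels** by PCA, two-class LDA with leave-one-out
   cross-validation, and ROC/AUC.
5. **Scores prognosis** with a linear risk model,
   `RiskScore = Σ_g coef_g · expr_g`; the published 10-gene gastric-cancer
   signature (SELL, EOMES, IYD, RP11-44K6.2, JPH1, TRIM29, PCED1B, TSPAN8,
   CEACAM5, PPP1R16B) ships as package data. Around it: Kaplan–Meier
   curves, log-rank tests, maximally-selected cutoffs, univariate Cox,
   IPCW time-dependent AUC, and lasso-Cox stability selection (B resampled
   repetitions of cross-validated penalised fits, counting how often each
   gene and each exact gene combination is selected).

A seed-deterministic synthetic-data generator (`dmegnet.synthetic`)
produces every input with planted ground truth — group-wise β shifts in
chosen regions, planted fold-changes, a scale-free network with one or more
drugs whose targets sit on the disease module, and exponential survival
with a known linear log-hazard — so the entire pipeline is testable
without external data.

## Worked example

```python
from dmegnet import make_network_and_drugs, screen_drugs

net, disease, drugs, truth = make_network_and_drugs(n_nodes=500, seed=0)
table = screen_drugs(net, disease, drugs, n_reps=10000, weighted=True, seed=1)
print(table.head(3).round(3))
```

```
               n_targets      d     mu  sigma      z      p    fdr  candidate
drug
drug_prox000           8 -0.904  1.652  0.335 -7.631  0.000  0.005       True
drug_decoy008          8  0.469  1.652  0.335 -3.531  0.003  0.074      False
drug_decoy016          8  0.728  1.652  0.335 -2.758  0.011  0.189      False
```

The planted proximal drug (`drug_prox000`) has observed distance −0.904
(negative because its targets inside the disease set earn the degree
weight), 7.6 null SDs below the random-reference mean, and is the only
catalogue entry passing FDR < 0.01.

Prognosis on a synthetic cohort with one planted gene (log-hazard
coefficient 1.0, n = 200):

```python
import numpy as np
from dmegnet import (make_expression, make_survival, maxstat_cutoff,
                     logrank_test, td_auc)
from dmegnet.prognosis import assign_risk_groups

expr, _ = make_expression(n_genes=50, n_per_group=100, lfc=0.0,
                          n_up=0, n_down=0, seed=2)
expr = expr.drop(index="PD1")
surv, _ = make_survival(expr, {"G00000": 1.0}, baseline_rate=0.2,
                        censor_rate=0.05, seed=3)
scores = expr.loc["G00000"] - expr.loc["G00000"].mean()
cut, chi2 = maxstat_cutoff(scores.to_numpy(), surv["time"], surv["event"])
groups = assign_risk_groups(scores, cut)
lr = logrank_test(surv["time"], surv["event"], groups.to_numpy())
```

prints (via the surrounding script)
`cutoff=0.353 chi2=101.3 logrank p=7.97e-24 HR=10.77 AUC(2.86)=0.825`:
the maximally-selected cutoff splits the cohort into risk groups whose
survival differs with hazard ratio ≈ 10.8, and the risk score discriminates
events by the median follow-up time with time-dependent AUC ≈ 0.83.

A `dmegnet` console script exposes the same steps as subcommands
(`simulate`, `stratify`, `aggregate`, `dm`, `de`, `dmeg`, `enrich`,
`proximity`, `score`, `cutoff`, `km`, `tdauc`, `select`, `evaluate`);
run `dmegnet --help`.

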