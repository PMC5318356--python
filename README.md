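# migranet

Pairwise and Bayesian **network meta-analysis (NMA)** of randomized trials of
prophylactic (preventative) migraine medications: placebo, topiramate,
propranolol, gabapentin, amitriptyline, divalproex and valproate, compared on
nine endpoints — monthly migraine headache days and headache frequency
(raw mean differences, MD), and seven binary outcomes analysed as odds
ratios (OR): ≥50% reduction in attacks, all adverse events, nausea,
somnolence, dizziness, all-cause withdrawal, and withdrawal due to adverse
events.

The package is aimed at meta-analysts who want the *complete* two-step
evidence-synthesis chain as tested, scriptable code:

1. **Pairwise meta-analysis** of every direct comparison under the
   random-effects model with the DerSimonian–Laird estimator:
   weights `w_i = 1/se_i²`, Cochran's `Q = Σ w_i (y_i − ȳ_w)²`,
   `τ²_DL = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`, random-effects weights
   `w*_i = 1/(se_i² + τ²)` and Wald 95% CIs.
2. **Bayesian NMA** under the hierarchical consistency model: arm-level
   likelihoods `r_ik ~ Binomial(n_ik, p_ik)` with
   `logit(p_ik) = μ_i + δ_ik` (or normal arm means for MD endpoints),
   trial effects `δ_ik ~ N(d_{t_ik} − d_{t_i1}, τ²)` with the exchangeable
   multi-arm construction (between-arm covariance τ²/2), vague priors, and
   a seeded Metropolis-within-Gibbs sampler written in vectorised numpy.
   From the posterior: league tables of all pairwise contrasts, rank
   probabilities, **SUCRA** scores, and k-means clustering of treatments on
   a two-endpoint SUCRA plane.
3. **Diagnostics**: Bayesian **node-splitting** (direct vs indirect
   evidence per comparison), the frequentist design-level **Q
   decomposition** `Q_total = Q_het + Q_inc` with **net-heat** contribution
   and detachment matrices, and comparison-adjusted **funnel** data with
   Egger's regression.

Study-level outcome data of the underlying 32 trials (6052 randomized
subjects, ten direct comparisons, five crossover trials) were never
published, so the package ships (a) a transcription of the study-level
metadata as `migranet/data/table1_fixture.csv` and (b) a first-class
simulator that reproduces that network's exact geometry — studies, sizes,
designs, endpoint coverage — with known ground truth, so every stage of
the pipeline is testable end to end.

## Worked example

```bash
migranet simulate --seed 3 --output-dir results       # evidence-base-like network
migranet pairwise --input results/arms.csv --endpoint 9
```

prints, for the withdrawal-due-to-AEs endpoint of the simulated network
(odds ratios with 95% CIs, `k` = number of studies pooled):

```
topiramate vs placebo: 1.311 (1.036, 1.658) k=9
propranolol vs placebo: 0.934 (0.293, 2.973) k=4
gabapentin vs placebo: 1.264 (0.838, 1.906) k=2
amitriptyline vs placebo: 0.630 (0.093, 4.244) k=1
divalproex vs placebo: 0.983 (0.458, 2.108) k=3
valproate vs placebo: 1.281 (0.575, 2.857) k=3
propranolol vs topiramate: 0.694 (0.442, 1.090) k=2
...
```

All true effects are zero under this seed's default scenario; nine of the
ten intervals straddle 1 and the topiramate one marginally excludes it —
the kind of chance finding a 5% error rate produces across ten
comparisons. The full chain for one endpoint:

```bash
migranet nma      --input results/arms.csv --endpoint 9 --seed 1   # league table
migranet rank     --input results/arms.csv --endpoint 9 --seed 1   # SUCRA
migranet nodesplit --input results/arms.csv --endpoint 9 --seed 1
migranet netheat  --input results/arms.csv --endpoint 9
migranet funnel   --input results/arms.csv --endpoint 9
migranet run-all  --input results/arms.csv --seed 1 --output-dir results/full
```

`run-all` executes every stage for every endpoint present and writes
plot-ready CSV/JSON tables plus a `run_report.json` manifest; reruns with
the same seed are bit-identical.

The scripted narrative lives under `analysis/`: `01_evidence_base.py`
(network structure of the packaged 32-study table), `02_simulate_trials.py`
(working dataset with injected efficacy/harm signals),
`03_pairwise_meta_analysis.py`, `04_network_meta_analysis.py` (league
tables, SUCRA, efficacy-vs-safety clusters), `05_consistency_checks.py`,
`06_publication_bias.py`, and `07_calibration_study.py`. For example,
`04_network_meta_analysis.py` prints the top-ranked treatment per
endpoint (`divalproex` tops headache days with SUCRA 0.82 under the
injected truths, placebo tops the harm endpoints) and
`07_calibration_study.py` reports the simulate-and-refit check
(`bias +0.009, RMSE 0.078, 95% CrI coverage 100%` over 10 replicates).

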