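# Methods

## The estimation problem

Seven interventions for migraine prophylaxis are connected by ten direct
head-to-head comparisons across 32 randomized trials, but most pairs of
drugs were never compared in the same trial. Network meta-analysis
borrows strength through common comparators (mostly placebo): if trials
estimate topiramate-vs-placebo and propranolol-vs-placebo, the
topiramate-vs-propranolol contrast is identified indirectly under the
*consistency* assumption — that direct and indirect evidence estimate the
same parameter. The package implements the full chain: per-comparison
pairwise pooling, the joint Bayesian network model, treatment ranking,
and the diagnostics that probe consistency and small-study bias.

## Pairwise random-effects pooling

Per-study effects are raw mean differences (continuous endpoints; the
source trials report these outcomes on a common scale, so no
standardisation is applied) or log odds ratios from the 2×2 table with a
0.5 continuity correction added to all four cells only when a zero cell
occurs. Tables with no events or all events in both arms are
uninformative and are dropped from that endpoint with a logged warning.
Pooling is inverse-variance with the DerSimonian–Laird moment estimator
of the between-study variance τ² and Wald 95% intervals (z = 1.96, no
small-sample adjustment). With a single study the estimate passes through
with Q = τ² = 0. Crossover trials report period-pooled arm summaries and
are pooled as parallel groups by default; `crossover_rho` optionally
shrinks the SE of continuous within-subject contrasts by √(1−ρ) as a
sensitivity analysis, since the within-subject correlation the trials
never reported can only be assumed.

## The Bayesian network model

Arm-level likelihoods: `r_ik ~ Binomial(n_ik, p_ik)` with
`logit(p_ik) = μ_i + δ_ik` for binary endpoints and
`ȳ_ik ~ Normal(μ_i + δ_ik, sd²_ik/n_ik)` for continuous ones, with
`δ = 0` in each study's baseline arm. Trial-specific effects are
exchangeable around the consistency means,
`δ_ik ~ N(d_{t_ik} − d_{t_i1}, τ²)`, with between-arm covariance τ²/2 in
multi-arm trials (all 32 real trials are two-arm, but the simulator can
emit multi-arm designs and the sampler handles them through the
sequential-conditional construction). Consistency holds by construction:
every posterior draw satisfies `contrast(A,C) = contrast(A,B) +
contrast(B,C)` because contrasts are differences of basic parameters.

Priors are deliberately vague and fully exposed in `NMAConfig`:
`d_k ~ N(0, 100²)`, `μ_i ~ N(0, 100²)`, and `τ ~ Uniform(0, 5)` on the
log-odds scale or `Uniform(0, 10)` for mean differences — wide relative
to any plausible treatment effect, so the data dominate.

### Sampler

A seeded Metropolis-within-Gibbs scheme, vectorised across chains:

* per-study random-walk block updates of μ_i and of the study's δ vector,
  accepted independently across studies (their full conditionals factor);
* an exact multivariate-normal Gibbs draw of the basic parameters d given
  the δ's (their full conditional is Gaussian);
* an exact draw of τ² from its truncated inverse-gamma full conditional
  under the uniform prior on τ;
* an interweaved non-centered move that proposes τ on the log scale while
  rescaling all residuals `δ − E[δ]` jointly. The centered Gibbs draw
  alone lets τ track the slowly-moving δ residuals (the usual funnel
  pathology of hierarchical models); the interweaving step restores fast
  mixing — split-chain R̂ on τ drops from ≈1.1 to <1.01 on a 30-study
  network at 8k sweeps.

Random-walk scales adapt every 50 sweeps during burn-in toward ≈30%
acceptance and are frozen afterwards, preserving detailed balance of the
retained draws. Each chain owns a `default_rng([seed, chain_seed])`
stream, so a run is bit-reproducible and two chains given the same chain
seed and start walk identical paths. Defaults (4 chains × 50k sweeps, 10k
burn-in, thin 10) are conservative for seven-treatment networks;
simulation suites in the tests use 4×10k, which already achieves R̂ < 1.05
on the networks of that size. Convergence failure (any split-chain R̂ >
1.05 on d or τ, via arviz) flags the posterior and logs a warning rather
than raising, so long pipeline runs complete and report.

Posterior point estimates are medians; intervals are central 95%
credible intervals; odds-ratio endpoints are exponentiated only at the
reporting layer. League tables follow the row-versus-column convention
with draw-wise reciprocal upper/lower triangles and a significance flag
when the interval excludes the null.

## Ranking

Per posterior draw, treatments are sorted with the better direction
first — each endpoint carries an explicit direction (more-negative MD is
better for headache days/frequency, higher OR is better for the responder
endpoint, lower OR for all harm and withdrawal endpoints), since rank
tables are meaningless without it. Ties break by treatment label. The
rank-probability matrix is doubly stochastic by construction;
SUCRA_k = Σ_{j≤K−1} cum_k(j)/(K−1) and always averages 0.5 across
treatments. Clustering of the treatments on a two-endpoint SUCRA plane
uses k-means with 50 seeded restarts, choosing k ∈ {2,3,4} by maximum
mean silhouette; coincident points are a flagged degenerate case. k-means
with silhouette selection is one defensible choice among several — the
method is a grouping heuristic, and the cluster labels carry no
inferential weight.

## Inconsistency diagnostics

**Node-splitting** refits the network giving the split comparison's
two-arm direct trials their own parameter ω while the basic parameters
carry only the remaining (indirect) evidence; the two-sided Bayesian
p-value is `2·min(P(ω − (d_b − d_a) > 0), P(< 0))` over draws. A
comparison is splittable only when direct evidence and an independent
indirect path both exist; others are skipped with a log entry. Raw
p-values are reported; multiplicity handling across the many comparisons
of a full run is left to the caller.

**Net heat** works on a frequentist weighted-least-squares backbone over
design-level contrasts (a design = a distinct treatment set; studies
within a design are pooled fixed-effect; multi-arm designs enter as
baseline-contrast vectors with their covariance). The per-design network
estimates are `X(XᵀWX)⁻¹XᵀW y` and Cochran's Q splits exactly —
`Q_total = Q_het + Q_inc`, the cross-term vanishing because each design's
pooled contrast is its weighted mean. The contribution matrix is the
row-normalised absolute hat matrix aggregated to design blocks; the
detachment matrix is each design's Q_inc contribution in the full fit
minus its contribution after another design is *detached* (granted its
own parameters, not deleted — deletion would break the Q bookkeeping).
Positive entries mean detaching lowers the inconsistency seen at that
design. The Bayesian node-split and this frequentist machinery coexist
deliberately: the first matches the main model, the second is the
construction the net-heat display presumes. Note that a single loop is
the minimal inconsistency unit: within one triangle every detachment
clears the same Q, so localisation requires at least two loops.

**Funnel data** center each study effect on its own comparison's pooled
direct estimate so all comparisons share one funnel; Egger's regression
of `centered/se` on `1/se` (intercept, SE, two-sided t-test p) is the
quantitative companion to visual inspection, which by itself is
untestable. The regression needs ≥3 studies; below that the centered
data are still emitted.

## The synthetic-trial generator

The generator emulates exactly the data-generating process the model
assumes, plus the features of the real evidence base the model has to
cope with: per-study baselines drawn on the logit scale around
logit(0.3) with SD 0.3 (a plausible adverse-event/responder rate band;
withdrawal endpoints use logit of the dropout rate, default 0.15, as
independent per-arm binomial dropout), trial effects
`θ_i ~ N(Δtrue + offset, τ²)` with the τ²/2 covariance for multi-arm
trials, binomial events or normal arm summaries (observed means at
sd/√n, observed SDs from the χ² sampling distribution around a common
within-arm SD of 2.5 with continuous baselines near 6 — the scale of
monthly headache-day counts), optional additive loop-inconsistency
offsets per edge, and crossover flags. `make_evidence_base_scenario()`
reproduces the real network's geometry exactly — the 32 studies with
their published sizes (split evenly across arms), designs, and per-study
endpoint sets — with configurable per-endpoint true effects.

What the generator does *not* emulate bounds what passing tests show:
real trials differ in follow-up duration, dose, outcome definitions and
baseline severity; crossover data are generated as period-pooled
parallel-like summaries rather than with genuine within-subject
correlation; dropout is independent of outcome (no informative
missingness). Recovery and calibration results therefore demonstrate
correctness of the *estimators under their assumed model*, not
robustness to the messiness of real trial networks.

## Scale of the verification studies

The simulation suites use a 3-treatment triangle (10 trials per edge;
200 per arm for recovery, 500 per arm for node-splitting) with τ = 0.1,
50 replicates per condition, at 4 chains × 10k (recovery) or 6k
(node-split) sweeps; the determinism check runs the full nine-endpoint
pipeline twice at 2 × 2k sweeps, where short-chain convergence warnings
are expected and immaterial to the hash comparison. These sizes make the
whole verification run in a few minutes on one CPU while leaving the
Monte-Carlo error of the measured rates (≈ ±0.04 binomial SE at 50
replicates) well inside the asserted bands.

## Known limitations

* The packaged table transcribes study-level metadata only; the original
  trial outcomes are not public, so the original league tables and
  SUCRA values cannot be numerically reproduced — only the pipeline's
  behaviour under known truth can be verified.
* Dose levels are ignored (trials pooled per drug), as is meta-regression
  on trial-level covariates; informative priors and model-selection
  criteria (e.g. DIC) are out of scope.
* The Egger test inherits its usual low power at small study counts.
* Follow-up durations are stored as printed (units vary across trials)
  and are not used analytically.
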