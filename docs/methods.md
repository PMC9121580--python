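# Methods

## The question being simulated

Given a complete population of FTND responders, how much do six scoring
rules for missing items distort (a) the mean total score and (b) the slope
of the total score on a home-smoking covariate, when item nonresponse is
injected under controlled MAR and MNAR mechanisms? Every quantity the
package reports is a Monte Carlo estimate over replicated sampled datasets;
the "truth" for each replication is computed on that replication's own
complete sample before deletion, so sampling error cancels out of the bias.

## Synthetic population model

Each subject carries covariates drawn independently — gender
(43% male), smoke-where (0.45 / 0.35 / 0.20 for no / outside / inside) and
smoking-allowed (35% yes) — and a latent dependence trait

    eta = 0.04*male + delta_sw[smoke_where] + 0.39*smoking_allowed + Z,
    Z ~ N(0,1),  delta_sw = (-0.04, 0.02, 0.06)

Item *i* is an ordinal discretisation of `y_i = lambda_i * eta + eps_i`
(`eps_i ~ N(0,1)` independent) at fitted thresholds: three cuts for the
0–3 items (1 and 4), one cut for the binary items. Because the covariates
are discrete, `y_i` is marginally a 12-component normal mixture with a
closed-form CDF, so thresholds reproducing any target category
probabilities are solved exactly by root finding; only the loadings require
simulation to tune.

Covariate effect sizes are deliberately small. Home-smoking variables enter
the MAR selection model with large slopes (odds ratios 0.12 and 0.14), so
any sizeable covariate–trait association would make complete case analysis
visibly biased under MAR — contrary to the observed behaviour the study
emulates, where MAR biases of all methods except drop-one are negligible.
The smoking-allowed effect (0.39 trait SD) is calibrated so the true
simple-regression coefficient of the total on smoking-allowed is ≈0.7
points, a magnitude consistent with the absolute-vs-percent headline biases
of that coefficient. The direction of the gender effect is an assumption
(the source statistics do not determine it); it is small enough to be
inconsequential.

## Calibration

Targets: item means (2.0, 0.3, 0.6, 0.9, 0.4, 0.5), item SDs (1.0, 0.4,
0.5, 0.8, 0.5, 0.5), total mean 4.7, total SD 2.3, Cronbach's α 0.59,
item–rest Spearman correlations (0.48, 0.26, 0.35, 0.36, 0.31, 0.31).
Default tolerances: ±0.05 on means and SDs, ±0.02 on α, ±0.05 on
correlations.

Three of the printed targets are mutually inconsistent at face value:

* a 0/1 item with mean 0.30 necessarily has SD 0.458, not 0.4, so the
  binary probabilities are chosen by minimising the larger of the two
  tolerance-normalised violations (landing near p = 0.27 for item 2), and
  any resulting shortfall in the total mean is redistributed over the
  binary items' remaining mean-tolerance headroom;
* the item SDs sum to ≈2.55 of variance, which with total SD 2.3 implies
  α ≈ 0.62; the calibrator therefore gives the 0–3 items a small SD slack
  (inside their ±0.05 tolerance) and targets the total variance at the
  midpoint of the window jointly feasible for total SD ± 0.05 and
  α ± 0.02.

Calibration steps: (1) category probabilities per item as above, with the
0–3 marginals solved as discretised normals matching mean and SD; (2) a
global loading scale solved by bracketing bisection of the simulated total
variance against the feasible-window midpoint, using common random numbers
at 100,000 subjects so the objective is smooth and deterministic;
(3) multiplicative per-item loading adjustments toward the item–rest
correlation targets, iterated twice with re-scaling; (4) a final check on a
fresh draw — any target outside tolerance raises a calibration error naming
the worst offender. The run is deterministic given the seed and takes
about a second. The package ships the calibrated loadings/thresholds as
`default_config()` so ordinary use needs no calibration run.

The calibrated population also reproduces the five dependence-band
proportions (totals 0–2 / 3–4 / 5 / 6–7 / 8–10 ≈ 19.5 / 26.4 / 15.2 /
26.9 / 11.9%) within 3 percentage points of the published split, although
the calibrator does not target them directly.

## Missingness mechanisms

Eligibility is logistic. MAR: slopes 0.20 (gender), −2.12 (smoke outside),
−1.99 (smoke inside), reference level "no". MNAR: slope 0.2 per point of
the true total, so a one-point increase multiplies the eligibility odds by
e^0.2 ≈ 1.22. The intercept is solved by bisection on [−50, 50] so the
*mean* eligibility probability equals p_sub, to 1e−8; monotonicity makes
the root unique. Eligibility is then drawn per subject Bernoulli, and each
item of an eligible subject is deleted Bernoulli(p_item), all six items
equally likely (the equal-rate assumption mirrors the design being
emulated). Covariates are never deleted; MCAR is intentionally not
implemented.

The intercept is re-solved on every replication's sample
(the per-dataset reading of "chosen empirically"); solving it once on the
population is available through `MissingnessConfig.solved_for(population)`
and changes the SE-bias results by only a couple of percentage points
either way.

## Scoring methods — decisions in ambiguous corners

* Proration and item-mean totals are left fractional; no rounding is
  stated anywhere, and rounding would add a discretisation bias.
* Proration with ≥3 observed all-zero items imputes 0 (zero numerator) —
  no special case needed.
* Hot-deck donors must observe all of a recipient's missing items *and*
  every distance variable (the recipient's observed items plus gender and
  smoking-allowed); with both requirements donors are exactly the
  item-complete subjects. Distances tie-broken by including every donor
  tied at the k-th smallest distance, then drawing uniformly — the result
  does not depend on row order. Fewer than k candidates falls back to all
  candidates with a warning (strict mode raises).
* Item means are computed within the current observed dataset, after
  missingness — not from the generator population.

## Performance measures

* Percent bias is guarded: replications with |θ| ≤ 1e−8 contribute to
  bias but not percent bias.
* The 95% Monte Carlo CI is the percentile interval (2.5th/97.5th
  percentiles of the per-replication values, linear interpolation). The
  published intervals this package is checked against are far too wide to
  be mean ± 1.96·SE/√1000, so they summarise the replication distribution;
  a normal-theory interval is selectable (`ci_method="normal"`).
* SE percent bias averages the per-replication ratios
  100(model SE − empirical SE)/empirical SE within a cell, using that
  cell's own empirical SE (the SD of θ̂ over its replications).
* Replications where a method leaves fewer than two usable totals (or a
  constant regressor) are recorded in `n_undefined` and dropped from that
  cell's summaries.
* `power_sample_size` uses exact noncentral-t power with equal groups and
  an integer search from the normal-approximation start; it reproduces the
  design sizes 52 (d = 0.8) and 788 (d = 0.2).

## Reproducibility and problem sizes

Seeding uses `numpy.random.SeedSequence` spawning: master seed → cell →
replication → named streams (sampling, eligibility, item deletion, hot-deck
donor), so any cell or replication can be reproduced in isolation and
results are independent of execution order. The full summary table is a
pure function of (population, grid, master seed).

The packaged acceptance tests rerun the headline slice of the design —
n_obs = 788, p_sub = 0.5, all four p_item levels, both mechanisms, plus the
9%-missing MNAR cell — at 800 replications per cell (the design's
reference analyses use 1000), a size chosen to keep the whole suite a
few minutes long while leaving the Monte Carlo error of cell-level means
well inside the published intervals they are compared to. The acceptance
script regenerates only the population-level descriptives, which need no
replication loop.

## Known limitations

* The generator is a single-factor ordinal model. It reproduces first- and
  second-order moments and the dependence-band split, but it cannot encode
  multi-factor structure or covariate-specific item behaviour
  (differential item functioning) a real sample may have; passing tests
  show the scoring methods behave correctly under the *stated* moment
  structure, not that the original data had no further structure.
* Hot deck here reproduces the published bias behaviour closely but is
  *less* SE-biased than the implementation it emulates (≈−24% vs −38% at
  the heaviest missingness for the SE of the mean); donor-pool mechanics of
  the original R implementation evidently shrink between-replication
  variability more than this one. The graded SE-bias comparison (item
  mean) is unaffected.
* Covariate missingness, longitudinal/monotone patterns, MCAR and multiple
  imputation are out of scope by design.
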