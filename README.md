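# ftndsim

Monte Carlo comparison of six ways to handle missing items on the
Fagerström Test for Nicotine Dependence (FTND).

The FTND is a six-item questionnaire of physiological nicotine dependence:
items 1 and 4 score 0–3, the other four items 0/1, and the total score
(0–10, higher = more dependent) is the sum of the items. When respondents
skip items there is no published rule for how to compute the total, and the
common choices differ in accuracy (bias of the estimate) and precision
(bias of its standard error). `ftndsim` is for biostatisticians and
questionnaire methodologists who want to quantify those trade-offs under
controlled missingness.

## What it does

1. **Synthetic population.** A calibrated generator emulates a large
   quitline sample of complete responders (38,334 subjects by default).
   Each subject has a latent dependence trait η = covariate shift + Z,
   Z ~ N(0,1); item *i* discretises λᵢ·η + εᵢ at fitted thresholds. The
   calibrator matches the printed descriptive moments: item means/SDs,
   total mean 4.7 (SD 2.3), Cronbach's α ≈ 0.59 and moderate item–rest
   Spearman correlations (0.26–0.48). Covariates — gender, "If you smoke at
   home, where?" (0 = No, 1 = Yes outside, 3 = Yes inside) and "Is smoking
   allowed in your home?" — shift the trait. A user-supplied complete CSV
   can replace the generator.
2. **Missingness injection.** Subjects become *eligible* for item
   nonresponse through a logistic selection model: MAR uses
   logit Pr = β₀ + 0.20·gender − 2.12·smoke_outside − 1.99·smoke_inside;
   MNAR uses logit Pr = β₀ + 0.2·FTND (higher dependence → more likely
   eligible). β₀ is solved by bisection so the mean eligibility probability
   equals p_sub; each item of an eligible subject is then deleted
   independently with probability p_item. The default grid
   (p_sub ∈ {0.1, 0.3, 0.5} × p_item ∈ {0.1, 0.3, 0.5, 0.7}) spans 1%–35%
   missing cells.
3. **Scoring methods.** Complete case analysis, drop-one, item-mean
   imputation, half-rule item mean, proration (person-mean imputation
   weighted by each item's maximum score, under the half rule) and a
   k-nearest-neighbour Gower-distance hot deck (k = 5, single donor fills
   all of a recipient's missing items).
4. **Performance measures.** Per replication, bias θ̂ − θ and percent bias
   100(θ̂ − θ)/θ of the mean FTND and of the OLS slope of the total on
   smoking-allowed, where θ comes from the same simulated dataset before
   missingness; percent bias of the model SE against the empirical SE (the
   SD of θ̂ over a cell's replications); means and 95% Monte Carlo
   percentile intervals over replications. Sample sizes n_obs = 52 and 788
   are the exact noncentral-t solutions for 80% power at Cohen's d = 0.8
   and 0.2 (two-sided α = 0.05).

## Worked example

```python
from ftndsim import (MissingnessStudy, SimulationGrid, default_config,
                     generate_population)

population = generate_population(default_config(), size=38334, seed=7)
grid = SimulationGrid(n_obs=(788,), mechanisms=("MNAR",), p_sub=(0.5,),
                      p_item=(0.7,), replications=300)
results = MissingnessStudy(population, grid).run(seed=3)
print(results.summary())
```

prints (excerpt):

```
% bias of mean FTND
-------------------
method                         cca  drop_one  hot_deck  hr_item_mean  item_mean  proration
mechanism p_sub p_item n_obs
MNAR      0.5   0.7    788  -11.07    -10.99     -5.93         -8.07      -6.03      -6.53
```

At the heaviest missingness setting (half the subjects eligible, 70% of
their items deleted, ≈35% of cells missing) complete case analysis
understates the mean FTND by ≈11% (≈0.5 points) because the high-dependence
subjects are the ones losing items under MNAR; proration and hot deck cut
that bias roughly in half. No method reaches the clinically important bias
of 1 point.

The same study is available from the shell:

```bash
ftndsim generate --size 38334 --seed 7 --out population.csv
ftndsim simulate --population population.csv --replications 1000 --out-dir results
ftndsim summarize results/summary.csv
```

## Layout

- `src/ftndsim/generator.py` — synthetic population + moment calibration
- `src/ftndsim/missingness.py` — MAR/MNAR eligibility and deletion draws
- `src/ftndsim/scoring.py` — the six scoring methods and Gower distance
- `src/ftndsim/metrics.py` — bias/SE-bias measures, Monte Carlo CIs, power
- `src/ftndsim/study.py` — replication driver, `MissingnessStudy` /
  `StudyResults`
- `src/ftndsim/cli.py` — `ftndsim generate | simulate | summarize`
- `docs/methods.md` — model details, calibration choices, limitations
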