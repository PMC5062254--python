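# meshreview

Tools for studying how a research proposal's position in keyword space
shapes the scores it receives in scientific peer review — and for validating
every step of that analysis on calibrated synthetic data.

Grant panels routinely show low inter-rater reliability, and one candidate
explanation is structural: the *intellectual distance* between an
evaluator's expertise and a proposal, and the proposal's *novelty* relative
to the published literature, may systematically move scores independent of
quality. `meshreview` implements the full evaluation-analysis machinery for
a randomized review design in which each of $J$ evaluators scores one
randomly assigned block of proposals on a 1–10 scale:

- **Keyword space** (`mesh_space`): proposals are binary vectors over a
  controlled keyword vocabulary (MeSH terms in the motivating setting);
  evaluators are publication-count vectors; a *pair index* records every
  unordered keyword pair occurring in a reference corpus.
- **Measures** (`scoring`): distance is $1-\cos(\mathbf{p}, \mathbf{e})$,
  novelty is the fraction of a proposal's $N(N-1)/2$ keyword pairs absent
  from the pair index; both are rank-transformed to percentiles on $(0,1]$,
  so coefficients read as min-to-max effects.
- **Design** (`design`): stratified recruitment (3 domain-relation groups ×
  2 seniority levels) and balanced block randomization, which makes
  distance exogenous to proposal quality.
- **Estimation** (`estimation`): two-way fixed-effects OLS with
  robust/clustered SEs,

  $$\text{SCORE}_{ij} = \beta\,\text{DISTANCE}_{ij} + \delta_i + \eta_j + \varepsilon_{ij},$$

  covariate-controlled novelty models, quadratic/quintile nonlinear forms,
  distance × moderator interactions, a random-coefficient model
  $\beta_i \sim N(\bar\beta, \sigma_\beta^2)$ fit by ML, and a joint
  mean–variance ML model with residual scale
  $\sigma\, m_{ij}$, $m_{ij} = 1 + \beta^{\varepsilon}\text{DISTANCE}_{ij} +
  \gamma^{\varepsilon}\text{NOVELTY}_j$.
- **Rankings** (`ranking`): panel-mean vs closest-expert orderings,
  noise-corrected scores (evaluator effects and the distance gradient
  removed), and rank-shift/agreement statistics by quality quartile.
- **Synthetic worlds** (`synthetic_data`): a generator that emulates the
  whole study — corpus, roster, proposals with overdispersed keyword sets
  (negative binomial, mean 12.42, s.d. 5.42), block assignment, and an
  additive score process discretized to 1–10 — calibrated to the study's
  printed score moments, with latent truths stored for Monte-Carlo
  parameter-recovery experiments.
- **Pipeline** (`pipeline`): a `meshreview` CLI
  (`simulate`/`fit`/`rank`/`recover`/`run`) driven by a YAML config and a
  single master seed; all outputs are plain delimited/JSON text.

## Worked example

```bash
meshreview run --seed 1 --out runs/demo
```

generates the default synthetic study (150 proposals, 142 evaluators in 10
blocks of 15 → 2,130 pairs), fits the standard model battery, and compares
rankings. Highlights from `runs/demo` (seed 1):

```
variance decomposition:  proposal R² = 0.272, evaluator R² = 0.186
two-way FE:        distance 0.701 (se 0.261)          [generating truth 0.86]
proposal-FE model: distance 0.668 (se 0.256), outside-domain 0.396 (se 0.148)
novelty model:     novelty −2.613 (se 0.149)          [generating truth −2.67]
variance model:    β^ε = 0.026 (se 0.063), γ^ε = 0.036 (se 0.062)  [truth 0]
panel vs closest-expert ranking: mean |Δrank| = 40.1 (s.d. 32.0), ρ = 0.30
```

Each fitted coefficient sits within sampling error of the value the
generator implanted; the variance-model coefficients are correctly null on
homoskedastic data; and replacing the panel average with each proposal's
closest evaluator reorders proposals by ~40 positions on average — rank
instability of the same order the motivating study reports. A single draw
is noisy (hence 0.701 vs 0.86); `meshreview recover --seed 1 --out runs/rec
--reps 20` averages the estimate over 20 replicated worlds.

As a library:

```python
from meshreview import (DGPConfig, generate_world, generate_scores,
                        assemble_analysis_table, fit_ols_robust, distance_spec)

cfg = DGPConfig()
world = generate_world(cfg, seed=1)
draw = generate_scores(world, world.features, cfg, seed=0)
data = assemble_analysis_table(world, draw.table)
fit = fit_ols_robust(data, distance_spec(proposal_fe=True, evaluator_fe=True))
print(fit.params["distance_pct"], fit.bse["distance_pct"])
```

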