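# Methods

This note documents the statistical machinery in `meshreview`: the measures,
the randomized design, the estimators, the synthetic data-generating process
(DGP) and its calibration, and the numerical and design choices that were
genuinely open.

## Measures

**Intellectual distance.** A proposal is a binary vector $\mathbf{p}$ over a
keyword vocabulary (one per attributed term); an evaluator is a count vector
$\mathbf{e}$ ($e_t$ = number of their publications carrying term $t$). Raw
distance is $1 - \mathbf{p}\cdot\mathbf{e} / (\lVert\mathbf{p}\rVert\,
\lVert\mathbf{e}\rVert) \in [0,1]$. An evaluator with no publications has no
direction; such degenerate profiles are assigned maximal distance and
flagged. No keyword-hierarchy expansion or tf-idf weighting is used — the
vectors are deliberately flat.

**Novelty.** For a proposal with $N \ge 2$ terms, the fraction of its
$N(N-1)/2$ unordered term pairs absent from the *pair index* — the set of
all term pairs co-occurring within any record of a reference publication
corpus (optionally bounded by an inclusive cutoff year; the corpus scope is
a configuration choice, not hard-coded). Proposals with fewer than two
terms get a flagged missing value, never a silent zero.

**Percentile transform.** Both raw measures are mapped to $(0,1]$ by
ascending rank $r/n$ with average-rank ties. On distinct inputs the output
is exactly the uniform grid $\{1/n,\dots,1\}$ (s.d.
$\sqrt{(n^2-1)/12n^2} \approx 0.2887$), so regression coefficients read as
the effect of moving from the closest/least-novel to the most
distant/most-novel percentile. Distance percentiles are computed over the
assigned pairs (the analysis units); ranking against all potential
evaluator × proposal pairs is available as an option. Novelty percentiles
are computed across proposals.

## Design

Proposals are partitioned uniformly at random into equal blocks (default:
150 proposals, block size 15) and each evaluator receives one whole block.
"Randomly assigned" is ambiguous between balanced and independent-uniform
block choice; the default is balanced (round-robin over shuffled blocks),
which keeps block loads within one of each other — 142 evaluators over 10
blocks gives loads of 14 or 15 and exactly 14.2 evaluators per proposal on
average — with independent-uniform as an option. The recruitment frame is
3 domain-relation groups × 2 seniority strata with a configurable number of
invitations per stratum (default 30, i.e. 180 invitations) and acceptance
specified as a total count, per-stratum probabilities, or per-stratum
counts.

Note that this block design is *disconnected*: each block's evaluators and
proposals form their own component of the bipartite rating graph. Two-way
fixed effects are therefore identified only up to one free level per block,
and the estimation code deterministically drops one (later-listed) dummy
per redundancy and reports it on the fit.

## Estimators

All fixed-effects models expand indicators explicitly (≈300 columns at the
default scale) and are solved by OLS; an iterated two-way demeaning path
exists as an independent cross-check (Frisch–Waugh agreement to 1e-6 is a
test invariant). Exactly collinear columns are detected by a QR sweep with
first-listed-kept order and reported, never silently absorbed. Robust
standard errors default to HC1; one-way clustering by evaluator or proposal
is available (the robust-SE flavor is underspecified in the motivating
analysis, so it is an explicit option; point estimates are unaffected).

**Random-coefficient model.** A linear mixed model, fit by ML (not REML),
with fixed intercept, distance term, and proposal dummies, and a random
(intercept, slope) pair per evaluator; $\bar\beta$ is the fixed distance
coefficient and $\sigma_\beta$ the random-slope s.d. The exact fixed-effect
structure of this specification was not fully pinned down in the source
analysis; this is our reading, and an `include_outside` option adds the
outside-domain indicator as a fixed term for data in which evaluator-level
score shifts co-vary with distance across evaluators (with random rather
than fixed intercepts, such shifts otherwise contaminate the mean slope).

**Heteroskedastic ML.** The joint mean–variance model redefines the error
as $m_{ij}\,\varepsilon_{ij}$ with $m_{ij} = 1 + \beta^{\varepsilon}
d_{ij} + \gamma^{\varepsilon} \nu_j$. For fixed variance coefficients the
mean coefficients solve weighted least squares and $\sigma$ has a closed
form, so the likelihood is concentrated to the variance coefficients and
maximized by Nelder–Mead from the null start plus 3 seeded random restarts;
steps with any $m_{ij} \le 0$ are penalized, never NaN. SEs for the
variance coefficients come from the profile-likelihood Hessian (finite
differences); with the multiplier pinned at zero the fit reduces exactly to
OLS with the homoskedastic Gaussian likelihood (a test invariant at 1e-8,
and the log-likelihood itself is checked against hand-summed normal
densities at 1e-10).

**Variance decomposition.** The unadjusted $R^2$ of scores on one factor's
indicators equals the between-group share SSB/SST and is computed that way.

## Rankings

Panel ranking aggregates by mean score; the counterfactual ranking takes
each proposal's $k$ intellectually closest assigned evaluators (default
$k=1$; ties by evaluator id). Dense ranks with deterministic proposal-id
tie-breaks; tied groups are reported. Noise-corrected scores subtract the
fitted evaluator effects (centered to mean zero so the scale is preserved)
and the fitted distance gradient. Rank-shift statistics: mean and s.d. of
absolute rank displacement, Spearman correlation, and mean displacement
within quality quartiles defined on the panel-mean aggregate (quartile
count configurable). The exact expert definition, displacement computation
and noise-correction details in the source analysis are not public; all
three are config-exposed defaults here, and reproducing its specific
displacement value is out of scope (the confidential study data would be
required). On default synthetic data the panel vs closest-expert shift
comes out near 40 positions with s.d. ≈ 32 — the same order of magnitude
as reported for the study data.

## Synthetic data-generating process

**World.** The vocabulary is laid out as [domain | bridge | tail] terms
(defaults 90/90/320 of 500) with Zipf-like base popularity. Corpus records
draw terms from base popularity; proposals tilt toward domain and bridge
terms, and each proposal has a "novelty dial" — a Beta-distributed
propensity to draw from an inverse-popularity law — so novelty is an
*emergent* property of the generated term sets scored against the generated
corpus, not an assigned number. Keyword-set sizes are negative binomial
with mean 12.42 and s.d. 5.42 (the study's reported moments), truncated
below at 2. Evaluator publication counts are Poisson with mean 101 (the
roster's reported mean); in-domain evaluators draw terms mostly from the
domain set, linked evaluators from the bridge set with zero domain mass,
outside evaluators from the tail — producing a monotone group → distance
gradient, and an outside-domain indicator (zero publications on the domain
set) covering linked + outside ≈ 2/3 of the roster, matching the study's
0.65 share. Term sets are sampled without replacement via the Gumbel-top-k
trick for speed.

**Scores.** With $d$ = distance percentile, $\nu$ = novelty percentile:

$$y^*_{ij} = \mu + \beta_i d_{ij} + \beta_2 d_{ij}^2 + \gamma \nu_j +
\gamma_2 \nu_j^2 + \lambda\,\text{outside}_i + \zeta' X_j + P_j + E_i +
m_{ij}\sigma z_{ij}, \qquad y_{ij} = \mathrm{clip}(\mathrm{round}(y^*_{ij}),
1, 10),$$

with $\beta_i \sim N(\beta_D, \text{slope\_sd}^2)$ per evaluator and
$z$ standard normal. The generator reports the clip fraction and raises
above 10 %.

**Pinned (conditional) simulation.** Under the default `pin_moments=True`,
effect draws are centered and rescaled to their exact configured s.d.
within each dataset, and orthogonalized in sequence: covariate effects
against novelty; the residual proposal effect against (novelty, covariate
effects); the evaluator effect against (outside-domain, mean assigned
distance); the residual against both factor-mean spaces (iterated two-way
demeaning, `pin_residual_factor_means`). The variance decomposition of a
generated dataset is then set by the configuration rather than fluctuating
chi-square-style across seeds, which is what makes single-dataset moment
checks meaningful. Two caveats are deliberate: (i) factor-mean projection
of the residual is exactly neutral for dummy-based OLS (any direction
orthogonal to the dummy space is untouched) but violates the iid
assumption of the mixed model, so the random-coefficient recovery
experiment switches it off; (ii) pinning makes draws conditionally
dependent, which is immaterial at $n = 2130$ for the estimators studied.

**Covariates.** Proposal covariates (words, references, figures, intro
flag, author publications/citations, keyword count) are generated with
realistic skewed marginals and a strong publications–citations dependence.
Their score effects are specified per standard deviation of the
standardized covariate, with signs following the fitted covariate model of
the motivating analysis but magnitudes sized to the calibrated
proposal-variance budget: at the printed coefficient × covariate-s.d.
scales, the covariate channel alone would far exceed the proposal variance
share implied by the printed $R^2$, so fidelity to the variance
decomposition was preferred. Slope-recovery experiments are invariant to
this choice because the fitted models control for the covariates.

**Calibration.** `calibrate_defaults` moment-matches $(\mu, \tau_P, \tau_E,
\sigma)$ by a seeded fixed-point search on pilot simulations against four
printed targets: score mean 5.7, proposal-dummy $R^2$ 0.26,
evaluator-dummy $R^2$ 0.19, and residual s.d. 1.7 after two-way fixed
effects. The resulting values ($\mu = 6.3756$, $\tau_P = 0.6341$,
$\tau_E = 0.9335$, $\sigma = 1.7671$) are frozen as `DGPConfig` defaults.
Two tensions are worth stating plainly. First, the printed unconditional
score s.d. of 2.6 is not jointly attainable with the other four moments
under an additive Gaussian process ($0.26 + 0.19 = 0.45$ of variance
explained vs $1-(1.7/2.6)^2 = 0.57$); the calibration targets the four
moments above and the unconditional s.d. lands near 2.35. Second, with
mean 5.7 and that dispersion on a 1–10 scale, about 3–4 % of rounded
latents fall outside the scale, so clipping cannot be pushed below 2 %
without abandoning the printed moments. Clipping mildly attenuates slope
estimates (a few percent) and more strongly attenuates the estimated
across-evaluator slope s.d. in the random-coefficient model (~20 %; the
same estimator on the continuous latent scores recovers it almost exactly,
and rounding alone is harmless). `override_effects` changes slope truths
while re-centering $\mu$ so the score level — and hence the clipping
regime — stays at the calibrated conditions.

**What the generator does not emulate.** Real score distributions are
skewed with a modal pile-up (mode 7 in the study) rather than
discretized-Gaussian; real novelty–distance dependence is matched only
loosely (the study reports a 0.10 correlation); evaluator covariates are
independent of expertise by default; and there is no strategic or
behavioral response in the score process. Passing recovery tests therefore
demonstrates that the estimators are correct and unbiased under the
assumed additive process at the study's design size — not that the
substantive findings would replicate on other data.

## Monte-Carlo recovery and validation experiments

`mc_recovery` simulates replicates (fresh or pre-built worlds; scores
redrawn per replicate), fits a supplied estimator, and reports per
parameter the MC mean, MC standard error, bias, bias z-score, and 95 %
robust-interval coverage; failed fits are recorded and excluded, with >20 %
failures an error. The canonical experiments (`experiments.py`) implant
published point estimates as truths: distance slope 1.10 (proposal-dummy
specification), 0.86 (two-way FE), outside-domain shift 0.37 (bivariate
specification, direct distance slope zero), novelty slope −2.67 (evaluator
dummies + covariate controls, proposal effects carried entirely by
observed covariates), and random-coefficient pair (1.48, 0.61). Twenty
replicates of the full 2,130-pair design are used per experiment — small
enough to run a full validation in about a minute, large enough that the
3-MC-s.e. unbiasedness criterion is meaningful. A separate 200-replicate
small-design experiment checks robust-interval coverage (90–99 % band) and
randomization validity (null slope recovered without bias).

## Numerical choices

Seeded `numpy` Generators throughout; no global RNG state; world and score
seeds are combined through `SeedSequence` so regeneration is bit-identical.
Collinearity tolerance 1e-9 on the scaled QR diagonal. Mixed models use
statsmodels `MixedLM` (ML, lbfgs with a fallback, maxiter 500); convergence
flags are propagated, never swallowed. Nelder–Mead tolerances 1e-6/1e-9
with penalty 1e12 outside the feasible multiplier region. Iterated
demeaning runs to max|update| < 1e-12. File outputs sort keys and rows so
byte-identical reruns are a test invariant.
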