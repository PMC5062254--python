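"""Estimation suite vs explicit linear-algebra and likelihood oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from meshreview import estimation as est
from meshreview import synthetic_data as sd


def toy_frame(rng=None):
    """12-row toy with one 3-level factor and one continuous regressor."""
    rng = rng or np.random.default_rng(5)
    x = rng.normal(size=12)
    grp = np.repeat(["a", "b", "c"], 4)
    shift = {"a": 0.0, "b": 1.0, "c": -2.0}
    y = 1.5 + 2.0 * x + np.array([shift[g] for g in grp]) + rng.normal(0, 0.3, 12)
    return pd.DataFrame({"score": y, "x": x, "g": grp})


# ---------------------------------------------------------------------------
# OLS


def test_ols_exact_interpolation():
    # zero-noise line y = 2 + 3x is recovered to machine precision
    x = np.arange(10, dtype=float)
    data = pd.DataFrame({"score": 2.0 + 3.0 * x, "x": x})
    fit = est.fit_ols_robust(data, est.ModelSpec(continuous=("x",)))
    assert fit.params["const"] == pytest.approx(2.0, abs=1e-10)
    assert fit.params["x"] == pytest.approx(3.0, abs=1e-10)
    assert fit.r2 == pytest.approx(1.0)


def test_ols_matches_normal_equations_oracle():
    data = toy_frame()
    fit = est.fit_ols_robust(
        data, est.ModelSpec(continuous=("x",), categorical=("g",))
    )
    # brute-force dummy expansion and explicit normal-equations solve
    X = np.column_stack(
        [
            np.ones(len(data)),
            data["x"],
            (data["g"] == "b").astype(float),
            (data["g"] == "c").astype(float),
        ]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ data["score"].to_numpy())
    got = fit.params[["const", "x", "g[b]", "g[c]"]].to_numpy()
    assert np.allclose(got, beta, atol=1e-8)


def test_ols_oracle_on_synthetic_design(small_data):
    """Full dummy fit equals the explicit least-squares solve (<=60 params)."""
    spec = est.distance_spec(proposal_fe=True, evaluator_fe=True)
    fit = est.fit_ols_robust(small_data, spec)
    X, dropped = est.build_design_matrix(small_data, spec)
    beta, *_ = np.linalg.lstsq(
        X.to_numpy(float), small_data["score"].to_numpy(float), rcond=None
    )
    assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)


def test_ols_cluster_se_options(small_data):
    spec_hc1 = est.distance_spec(proposal_fe=True)
    spec_cl = est.distance_spec(proposal_fe=True, se_type="cluster_by_evaluator")
    f1 = est.fit_ols_robust(small_data, spec_hc1)
    f2 = est.fit_ols_robust(small_data, spec_cl)
    # identical point estimates, different variance estimator
    assert np.allclose(f1.params.to_numpy(), f2.params.to_numpy())
    assert f1.bse["distance_pct"] != f2.bse["distance_pct"]


def test_ols_reports_deterministic_collinear_drop(small_data):
    # outside_domain is evaluator-level: with evaluator dummies present the
    # design is rank-deficient and a later-listed dummy is dropped, never the
    # earlier-listed continuous term
    spec = est.ModelSpec(
        continuous=("distance_pct", "outside_domain"),
        categorical=("proposal_id", "evaluator_id"),
    )
    fit = est.fit_ols_robust(small_data, spec)
    assert fit.dropped, "expected a collinear column to be reported"
    assert all(name.startswith("evaluator_id[") for name in fit.dropped)
    assert "distance_pct" in fit.params.index


def test_ols_errors_when_underdetermined():
    data = pd.DataFrame({"score": [1.0, 2.0], "x": [0.0, 1.0], "z": [3.0, 1.0]})
    with pytest.raises(ValueError, match="n_obs"):
        est.fit_ols_robust(data, est.ModelSpec(continuous=("x", "z")))


def test_frisch_waugh_two_way_demeaning(default_data):
    """Distance coefficient from explicit dummies equals the iterated
    within-transform regression."""
    fit = est.fit_ols_robust(
        default_data, est.distance_spec(proposal_fe=True, evaluator_fe=True)
    )
    dm = est.within_transform(default_data, ["score", "distance_pct"])
    beta = float(
        (dm["score"] * dm["distance_pct"]).sum() / (dm["distance_pct"] ** 2).sum()
    )
    assert fit.params["distance_pct"] == pytest.approx(beta, abs=1e-6)


def test_r2_monotone_in_nested_models(small_data):
    specs = [
        est.outside_domain_spec(),
        est.distance_spec(proposal_fe=False),
        est.distance_spec(proposal_fe=True),
        est.distance_spec(proposal_fe=True, evaluator_fe=True),
    ]
    r2s = [est.fit_ols_robust(small_data, s).r2 for s in specs]
    assert all(a <= b + 1e-12 for a, b in zip(r2s, r2s[1:]))


# ---------------------------------------------------------------------------
# variance decomposition


def test_variance_decomposition_perfect_within_proposal():
    data = pd.DataFrame(
        {
            "proposal_id": ["p1"] * 3 + ["p2"] * 3,
            "score": [4.0, 4.0, 4.0, 7.0, 7.0, 7.0],
        }
    )
    assert est.variance_decomposition(data, "proposal") == pytest.approx(1.0)


def test_variance_decomposition_anova_identity():
    # balanced two-group toy: R^2 must equal SSB/SST computed by hand
    y = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
    data = pd.DataFrame({"proposal_id": ["a"] * 3 + ["b"] * 3, "score": y})
    grand = y.mean()
    ssb = 3 * ((2.0 - grand) ** 2 + (8.0 - grand) ** 2)
    sst = ((y - grand) ** 2).sum()
    assert est.variance_decomposition(data, "proposal") == pytest.approx(ssb / sst)


def test_variance_decomposition_matches_dummy_regression(small_data):
    r2 = est.variance_decomposition(small_data, "evaluator")
    fit = est.fit_ols_robust(
        small_data, est.ModelSpec(categorical=("evaluator_id",))
    )
    assert r2 == pytest.approx(fit.r2, abs=1e-10)


def test_variance_decomposition_single_level_errors():
    data = pd.DataFrame({"proposal_id": ["p"] * 4, "score": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError):
        est.variance_decomposition(data, "proposal")


# ---------------------------------------------------------------------------
# nonlinear expansions


def test_quadratic_expansion():
    df = pd.DataFrame({"distance_pct": [0.5], "novelty_pct": [0.2]})
    out, terms = est.expand_nonlinear(df, "quadratic")
    assert out.loc[0, "distance_pct_sq"] == pytest.approx(0.25)
    assert set(terms) == {"distance_pct_sq", "novelty_pct_sq"}


def test_quintile_bins_even_split():
    df = pd.DataFrame(
        {
            "distance_pct": np.linspace(0.1, 1.0, 10),
            "novelty_pct": np.linspace(0.1, 1.0, 10),
        }
    )
    out, terms = est.expand_nonlinear(df, "quintile")
    ind = out[[t for t in terms if t.startswith("distance")]]
    assert ind.to_numpy().sum(axis=0).tolist() == [2.0, 2.0, 2.0, 2.0]
    # lowest quintile is the reference: its two rows have all-zero indicators
    assert ind.iloc[:2].to_numpy().sum() == 0.0


def test_quintile_requires_five_distinct():
    df = pd.DataFrame({"distance_pct": [0.1, 0.2] * 5, "novelty_pct": [0.3] * 10})
    with pytest.raises(ValueError, match="distinct"):
        est.expand_nonlinear(df, "quintile", variables=("novelty_pct",))


# ---------------------------------------------------------------------------
# random-coefficient model


def test_random_slope_degenerate_vs_heterogeneous(default_world):
    """With slope_sd = 0 the estimated sigma_beta sits near its weakly
    identified floor and well below the estimate under strong heterogeneity
    on the same worlds; the mean slope agrees with the explicit-dummy OLS
    fit.  (sigma_beta is noisy per dataset at 15 scores per evaluator, so
    the check is paired and averaged over draws.)"""
    import dataclasses

    base = dataclasses.replace(
        default_world.config, pin_residual_factor_means=False
    )
    hetero = dataclasses.replace(base, slope_sd=1.5)
    nulls, bigs, gaps = [], [], []
    for s in range(3):
        for cfg, sink in ((base, nulls), (hetero, bigs)):
            draw = sd.generate_scores(
                default_world, default_world.features, cfg, seed=s
            )
            data = sd.assemble_analysis_table(default_world, draw.table)
            fit = est.fit_random_slope(data)
            sink.append(fit.extra["sigma_beta"])
            if cfg is base:
                ols = est.fit_ols_robust(
                    data, est.distance_spec(proposal_fe=True, evaluator_fe=True)
                )
                gaps.append(
                    abs(fit.extra["beta_bar"] - float(ols.params["distance_pct"]))
                    / float(ols.bse["distance_pct"])
                )
    assert np.mean(nulls) < 0.7, nulls
    assert np.mean(nulls) < np.mean(bigs) - 0.3, (nulls, bigs)
    assert float(np.median(gaps)) < 3.0, gaps


def test_per_evaluator_slopes_identified_without_noise(small_world):
    """On noiseless data each evaluator's separate OLS slope equals their
    generating slope, validating what the mixed model shrinks toward."""
    import dataclasses

    cfg = dataclasses.replace(
        small_world.config,
        sigma=0.0,
        tau_p=0.0,
        tau_e=0.0,
        gamma_n=0.0,
        lambda_o=0.0,
        slope_sd=0.8,
        covariate_effects={},
        mu=5.5,
        pin_moments=True,
    )
    draw = sd.generate_scores(small_world, small_world.features, cfg, seed=9)
    data = sd.assemble_analysis_table(small_world, draw.table)
    data = data.assign(latent=draw.latent)
    for eid, sub in data.groupby("evaluator_id"):
        x = sub["distance_pct"].to_numpy()
        y = sub["latent"].to_numpy()
        x_c = x - x.mean()
        slope = float((x_c * y).sum() / (x_c**2).sum())
        assert slope == pytest.approx(
            float(draw.evaluator_slopes[eid]), abs=1e-8
        )


# ---------------------------------------------------------------------------
# heteroskedastic ML


def test_hetero_loglik_matches_hand_summed_densities(rng):
    """Model log-likelihood equals a scipy.stats normal-density oracle."""
    n, p = 40, 3
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = np.array([1.0, -0.5, 0.25])
    var_X = rng.uniform(0, 1, size=(n, 2))
    theta = np.array([0.3, -0.2])
    sigma = 1.3
    y = rng.normal(size=n) + X @ beta
    got = est.heteroskedastic_loglik(y, X, beta, sigma, var_X, theta)
    m = 1.0 + var_X @ theta
    expected = float(norm.logpdf(y, loc=X @ beta, scale=sigma * m).sum())
    assert got == pytest.approx(expected, abs=1e-10)


def test_hetero_loglik_rejects_nonpositive_multiplier(rng):
    X = np.ones((4, 1))
    with pytest.raises(ValueError):
        est.heteroskedastic_loglik(
            np.zeros(4), X, np.zeros(1), 1.0, np.ones((4, 1)), np.array([-2.0])
        )


def test_variance_model_null_reduces_to_ols(small_data):
    """With the multiplier pinned at zero, the ML fit is exactly OLS and the
    log-likelihood equals the homoskedastic Gaussian value at the OLS
    solution."""
    spec = est.distance_spec(proposal_fe=True, evaluator_fe=True)
    null = est.fit_variance_model(small_data, spec, fix_null=True)
    ols = est.fit_ols_robust(small_data, spec)
    assert np.allclose(
        null.params.to_numpy(), ols.params.to_numpy(), atol=1e-8
    )
    assert null.loglik == pytest.approx(ols.loglik, abs=1e-8)


def test_variance_model_homoskedastic_truth_near_zero(small_world, small_config):
    """On homoskedastic data the variance coefficients are small relative to
    their standard errors."""
    draw = sd.generate_scores(small_world, small_world.features, small_config, seed=11)
    data = sd.assemble_analysis_table(small_world, draw.table)
    fit = est.fit_variance_model(
        data, est.distance_spec(proposal_fe=True), seed=0
    )
    assert fit.converged
    for term, v in fit.extra["var_coefs"].items():
        se = fit.extra["var_coefs_se"][term]
        assert abs(v) < 3.5 * se, (term, v, se)


# ---------------------------------------------------------------------------
# interactions


def test_interactions_run_jointly_without_rank_failure(small_data):
    fit = est.fit_interactions(
        small_data, ("novelty_pct", "senior", "years_since_degree", "female")
    )
    for mod in ("novelty_pct", "senior", "years_since_degree", "female"):
        assert f"distance_pct:{mod}" in fit.params.index


def test_interactions_reject_constant_moderator(small_data):
    data = small_data.assign(flat=1.0)
    with pytest.raises(ValueError, match="no variation"):
        est.fit_interactions(data, ("flat",))
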