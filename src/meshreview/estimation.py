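"""Regression suite for pair-level evaluation scores.

Four estimators cover every specification the analysis needs:

* :func:`fit_ols_robust` — OLS with heteroskedasticity-robust (HC1) or
  one-way clustered standard errors, with fixed effects entered as explicit
  indicator columns (proposal and/or evaluator dummies).
* :func:`fit_random_slope` — ML linear mixed model in which each
  evaluator's distance slope is a draw from N(beta_bar, sigma_beta^2), with a
  random intercept per evaluator and proposal indicators as fixed terms.
* :func:`fit_variance_model` — joint Gaussian ML of the mean equation and a
  linear variance multiplier m_ij = 1 + b_eps*distance + g_eps*novelty on the
  residual scale, estimated by concentrating the mean coefficients and
  residual scale out of the likelihood.
* :func:`variance_decomposition` — unadjusted R^2 of the score on a single
  factor's indicators (the one-way variance share).

Collinear design columns are dropped deterministically (first-listed kept)
and reported on the result, so a specification such as the two-way
fixed-effects model with an evaluator-level regressor fails softly into the
identified model the way a practitioner would expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression specification."""

    response: str = "score"
    continuous: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    estimator: str = "ols_robust"  # ols_robust | random_slope_ml | hetero_ml
    se_type: str = "HC1"  # HC1 | cluster_by_evaluator | cluster_by_proposal

    def __post_init__(self) -> None:
        terms = list(self.continuous) + list(self.categorical)
        if len(terms) != len(set(terms)):
            raise ValueError("duplicate terms in model spec")
        if self.estimator not in ("ols_robust", "random_slope_ml", "hetero_ml"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        known = set(terms)
        for a, b in self.interactions:
            if a not in known or b not in known:
                raise ValueError(f"interaction ({a}, {b}) references undeclared terms")


@dataclass
class FitResult:
    """Named coefficients plus inference and diagnostics from any estimator."""

    params: pd.Series
    bse: pd.Series
    vcov: pd.DataFrame
    n_obs: int
    r2: float | None = None
    adj_r2: float | None = None
    loglik: float | None = None
    dropped: tuple[str, ...] = ()
    converged: bool = True
    se_type: str = "HC1"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "n_obs": int(self.n_obs),
            "r2": None if self.r2 is None else float(self.r2),
            "adj_r2": None if self.adj_r2 is None else float(self.adj_r2),
            "loglik": None if self.loglik is None else float(self.loglik),
            "dropped": list(self.dropped),
            "converged": bool(self.converged),
            "se_type": self.se_type,
            "extra": {
                k: (float(v) if np.isscalar(v) else v)
                for k, v in self.extra.items()
            },
        }


# ---------------------------------------------------------------------------
# design-matrix construction


def dummy_name(column: str, level: object) -> str:
    return f"{column}[{level}]"


def build_design_matrix(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, list[str]]:
    """Expand a spec into a numeric design matrix (with intercept).

    Categorical terms become indicator columns with the first (sorted) level
    as reference.  Columns that are exactly collinear with earlier columns
    are dropped (earlier-listed columns win) and returned in the second
    element.
    """
    cols: dict[str, np.ndarray] = {"const": np.ones(len(data))}
    for name in spec.continuous:
        v = np.asarray(data[name], dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in term {name!r}")
        cols[name] = v
    for a, b in spec.interactions:
        cols[f"{a}:{b}"] = np.asarray(data[a], dtype=float) * np.asarray(
            data[b], dtype=float
        )
    for name in spec.categorical:
        levels = sorted(pd.unique(data[name]).tolist())
        if len(levels) < 2:
            raise ValueError(f"categorical term {name!r} has a single level")
        for lev in levels[1:]:
            cols[dummy_name(name, lev)] = (data[name] == lev).to_numpy(float)
    X = pd.DataFrame(cols, index=data.index)
    return drop_collinear(X)


def drop_collinear(
    X: pd.DataFrame, tol: float = 1e-9
) -> tuple[pd.DataFrame, list[str]]:
    """Remove columns linearly dependent on earlier columns (QR sweep)."""
    A = X.to_numpy(float)
    scale = np.linalg.norm(A, axis=0)
    scale[scale == 0] = 1.0
    dropped: list[str] = []
    keep = list(range(A.shape[1]))
    while True:
        R = np.linalg.qr((A[:, keep] / scale[keep]), mode="r")
        diag = np.abs(np.diag(R))
        bad = np.nonzero(diag < tol)[0]
        if bad.size == 0:
            break
        # drop the first dependent column and re-factor
        j = keep[bad[0]]
        dropped.append(X.columns[j])
        keep.remove(j)
    return X.iloc[:, keep], dropped


def _cov_kwargs(spec: ModelSpec, data: pd.DataFrame) -> dict:
    if spec.se_type == "HC1":
        return {"cov_type": "HC1"}
    if spec.se_type == "cluster_by_evaluator":
        return {"cov_type": "cluster", "cov_kwds": {"groups": data["evaluator_id"]}}
    if spec.se_type == "cluster_by_proposal":
        return {"cov_type": "cluster", "cov_kwds": {"groups": data["proposal_id"]}}
    raise ValueError(f"unknown se_type {spec.se_type!r}")


# ---------------------------------------------------------------------------
# estimators


def fit_ols_robust(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """OLS point estimates with robust (HC1) or one-way clustered SEs."""
    if spec.estimator != "ols_robust":
        raise ValueError("spec estimator must be 'ols_robust'")
    y = np.asarray(data[spec.response], dtype=float)
    X, dropped = build_design_matrix(data, spec)
    if set(dropped) & set(spec.continuous):
        raise ValueError(
            f"continuous term(s) {sorted(set(dropped) & set(spec.continuous))} "
            "are rank-deficient in this design"
        )
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"n_obs={len(y)} does not exceed n_params={X.shape[1]}"
        )
    res = sm.OLS(y, X).fit(**_cov_kwargs(spec, data))
    return FitResult(
        params=res.params,
        bse=res.bse,
        vcov=pd.DataFrame(
            res.cov_params(), index=X.columns, columns=X.columns
        ),
        n_obs=int(res.nobs),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        loglik=float(res.llf),
        dropped=tuple(dropped),
        se_type=spec.se_type,
        extra={"resid_sd": float(np.std(res.resid))},
    )


def variance_decomposition(
    data: pd.DataFrame, factor: str, response: str = "score"
) -> float:
    """Unadjusted R^2 of the response on one factor's indicators alone.

    Identically the between-group share of the total sum of squares
    (SSB/SST), computed by group means rather than an explicit dummy fit.
    """
    if factor not in ("proposal", "evaluator") and factor not in data.columns:
        raise ValueError(f"unknown factor {factor!r}")
    col = {"proposal": "proposal_id", "evaluator": "evaluator_id"}.get(factor, factor)
    y = np.asarray(data[response], dtype=float)
    groups = data[col]
    if groups.nunique() < 2:
        raise ValueError(f"factor {col!r} has a single level")
    grand = y.mean()
    means = data.groupby(col, sort=False)[response].transform("mean").to_numpy()
    sst = float(np.sum((y - grand) ** 2))
    ssb = float(np.sum((means - grand) ** 2))
    if sst == 0.0:
        raise ValueError("response has zero variance")
    return ssb / sst


def expand_nonlinear(
    features: pd.DataFrame,
    kind: str,
    variables: Sequence[str] = ("distance_pct", "novelty_pct"),
) -> tuple[pd.DataFrame, list[str]]:
    """Augment a feature table with quadratic or quintile-bin terms.

    ``quadratic`` adds ``<var>_sq`` columns; ``quintile`` adds four
    indicator columns per variable (lowest quintile is the reference),
    with bins cut on ranked values.
    """
    out = features.copy()
    new_terms: list[str] = []
    if kind == "quadratic":
        for v in variables:
            name = f"{v}_sq"
            out[name] = np.asarray(out[v], dtype=float) ** 2
            new_terms.append(name)
    elif kind == "quintile":
        for v in variables:
            vals = np.asarray(out[v], dtype=float)
            if len(np.unique(vals)) < 5:
                raise ValueError(
                    f"{v!r} has fewer than 5 distinct values; cannot form quintiles"
                )
            ranks = pd.Series(vals).rank(method="average")
            bins = pd.qcut(ranks, 5, labels=False)
            for q in range(1, 5):
                name = f"{v}_q{q + 1}"
                out[name] = (bins == q).astype(float)
                new_terms.append(name)
    else:
        raise ValueError(f"unknown expansion kind {kind!r}")
    return out, new_terms


def fit_random_slope(
    data: pd.DataFrame,
    response: str = "score",
    slope: str = "distance_pct",
    group: str = "evaluator_id",
    proposal_fe: bool = True,
    include_outside: bool = False,
) -> FitResult:
    """ML mixed model with a per-evaluator random intercept and distance slope.

    The fixed part is an intercept, the distance term (its coefficient is
    the population mean slope beta_bar) and, by default, proposal
    indicators; the random part per evaluator is (intercept, slope), so the
    estimated slope s.d. sigma_beta measures how heterogeneously evaluators
    respond to distance.  ``include_outside`` adds the outside-domain
    indicator as a fixed term — useful when evaluator-level score shifts
    co-vary with distance across evaluators, since intercepts are random
    rather than fixed here and such shifts otherwise leak into the mean
    slope.  Non-convergence is flagged, never silent.
    """
    import warnings

    cont = [slope]
    if include_outside and "outside_domain" in data.columns:
        cont.append("outside_domain")
    spec = ModelSpec(
        response=response,
        continuous=tuple(cont),
        categorical=("proposal_id",) if proposal_fe else (),
    )
    y = np.asarray(data[response], dtype=float)
    X, dropped = build_design_matrix(data, spec)
    exog_re = X[["const", slope]]
    model = sm.MixedLM(y, X, groups=data[group], exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=500)
        except Exception:
            res = model.fit(reml=False, maxiter=500)
    cov_re = np.asarray(res.cov_re)
    sigma_beta = float(np.sqrt(max(cov_re[1, 1], 0.0)))
    converged = bool(getattr(res, "converged", True))
    fe_names = list(X.columns)
    return FitResult(
        params=pd.Series(np.asarray(res.fe_params), index=fe_names),
        bse=pd.Series(np.asarray(res.bse_fe), index=fe_names),
        vcov=pd.DataFrame(
            np.asarray(res.cov_params())[: len(fe_names), : len(fe_names)],
            index=fe_names,
            columns=fe_names,
        ),
        n_obs=int(res.nobs),
        loglik=float(res.llf),
        dropped=tuple(dropped),
        converged=converged,
        se_type="ml",
        extra={
            "beta_bar": float(np.asarray(res.fe_params)[fe_names.index(slope)]),
            "beta_bar_se": float(np.asarray(res.bse_fe)[fe_names.index(slope)]),
            "sigma_beta": sigma_beta,
            "sigma": float(np.sqrt(res.scale)),
            "re_cov": cov_re.tolist(),
        },
    )


def heteroskedastic_loglik(
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    sigma: float,
    var_X: np.ndarray,
    var_coefs: np.ndarray,
) -> float:
    """Gaussian log-likelihood with residual scale sigma * m_i.

    m_i = 1 + var_X @ var_coefs must be positive at every observation.
    """
    m = 1.0 + np.asarray(var_X, float) @ np.asarray(var_coefs, float)
    if np.any(m <= 0):
        raise ValueError("variance multiplier non-positive at some observation")
    r = np.asarray(y, float) - np.asarray(X, float) @ np.asarray(beta, float)
    return float(
        -0.5
        * np.sum(np.log(2.0 * np.pi * sigma**2 * m**2) + (r / (sigma * m)) ** 2)
    )


def fit_variance_model(
    data: pd.DataFrame,
    mean_spec: ModelSpec,
    var_terms: Sequence[str] = ("distance_pct", "novelty_pct"),
    n_restarts: int = 3,
    seed: int = 0,
    fix_null: bool = False,
) -> FitResult:
    """Joint ML of the mean equation and a linear variance multiplier.

    For fixed variance coefficients theta the mean coefficients solve a
    weighted least-squares problem and the residual scale has a closed
    form, so the likelihood is concentrated down to ``len(var_terms)``
    parameters and maximized by Nelder–Mead from the null plus seeded
    random restarts.  Steps where any m_i <= 0 are penalized, never NaN.
    With ``fix_null=True`` the multiplier is pinned at zero and the fit
    reduces exactly to OLS with homoskedastic Gaussian likelihood.
    """
    y = np.asarray(data[mean_spec.response], dtype=float)
    X, dropped = build_design_matrix(data, mean_spec)
    Xv = X.to_numpy(float)
    Z = np.column_stack([np.asarray(data[t], float) for t in var_terms])
    n = len(y)

    def inner(theta: np.ndarray):
        m = 1.0 + Z @ theta
        if np.min(m) <= 1e-8:
            return None
        w = 1.0 / m
        beta, *_ = np.linalg.lstsq(Xv * w[:, None], y * w, rcond=None)
        r = (y - Xv @ beta) / m
        s2 = float(np.mean(r**2))
        nll = 0.5 * n * np.log(2.0 * np.pi * s2) + float(np.sum(np.log(m))) + 0.5 * n
        return nll, beta, np.sqrt(s2)

    def objective(theta: np.ndarray) -> float:
        res = inner(theta)
        if res is None:
            m = 1.0 + Z @ theta
            return 1e12 + 1e6 * float(np.sum(np.minimum(m, 0.0) ** 2))
        return res[0]

    k = Z.shape[1]
    if fix_null:
        theta_hat = np.zeros(k)
        converged = True
    else:
        rng = np.random.default_rng(seed)
        starts = [np.zeros(k)] + [
            rng.uniform(-0.4, 0.4, size=k) for _ in range(n_restarts)
        ]
        best = None
        converged = False
        for x0 in starts:
            opt = optimize.minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 1000},
            )
            if best is None or opt.fun < best.fun:
                best = opt
        assert best is not None
        theta_hat = best.x
        converged = bool(best.success)

    nll, beta_hat, sigma_hat = inner(theta_hat)  # type: ignore[misc]
    loglik = -nll

    # SEs: profile-likelihood curvature for theta; ML covariance for beta.
    if fix_null:
        theta_se = np.full(k, np.nan)
    else:
        hess = _numerical_hessian(objective, theta_hat)
        try:
            theta_cov = np.linalg.inv(hess)
            theta_se = np.sqrt(np.clip(np.diag(theta_cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            theta_se = np.full(k, np.nan)
            converged = False
    m = 1.0 + Z @ theta_hat
    XtWX = (Xv / m[:, None]).T @ (Xv / m[:, None])
    beta_cov = sigma_hat**2 * np.linalg.pinv(XtWX)

    names = list(X.columns)
    params = pd.Series(beta_hat, index=names)
    bse = pd.Series(np.sqrt(np.clip(np.diag(beta_cov), 0, np.inf)), index=names)
    extra = {
        "sigma": float(sigma_hat),
        "var_terms": list(var_terms),
        "var_coefs": {t: float(v) for t, v in zip(var_terms, theta_hat)},
        "var_coefs_se": {t: float(v) for t, v in zip(var_terms, theta_se)},
    }
    return FitResult(
        params=params,
        bse=bse,
        vcov=pd.DataFrame(beta_cov, index=names, columns=names),
        n_obs=n,
        loglik=float(loglik),
        dropped=tuple(dropped),
        converged=converged,
        se_type="ml",
        extra=extra,
    )


def _numerical_hessian(
    f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4
) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def fit_interactions(
    data: pd.DataFrame,
    moderators: Sequence[str],
    base_slope: str = "distance_pct",
    response: str = "score",
    se_type: str = "HC1",
) -> FitResult:
    """Two-way FE model with distance × moderator product terms added.

    Moderators must be numeric columns with variation (indicator-code
    categorical attributes first, e.g. ``senior``/``female``).
    """
    for mod in moderators:
        v = np.asarray(data[mod], dtype=float)
        if np.nanstd(v) == 0:
            raise ValueError(f"moderator {mod!r} has no variation")
    spec = ModelSpec(
        response=response,
        continuous=(base_slope, *moderators),
        categorical=("proposal_id", "evaluator_id"),
        interactions=tuple((base_slope, m) for m in moderators),
        se_type=se_type,
    )
    # evaluator-level moderators are collinear with evaluator dummies: the
    # dummies absorb their main effects, so drop the redundant main terms
    # rather than erroring.
    y = np.asarray(data[response], dtype=float)
    X, dropped = build_design_matrix(data, spec)
    res = sm.OLS(y, X).fit(**_cov_kwargs(replace(spec, se_type=se_type), data))
    return FitResult(
        params=res.params,
        bse=res.bse,
        vcov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        n_obs=int(res.nobs),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        loglik=float(res.llf),
        dropped=tuple(dropped),
        se_type=se_type,
    )


# ---------------------------------------------------------------------------
# canonical specifications


def outside_domain_spec(se_type: str = "HC1") -> ModelSpec:
    """Score on the outside-domain indicator alone."""
    return ModelSpec(continuous=("outside_domain",), se_type=se_type)


def distance_spec(
    proposal_fe: bool = True,
    evaluator_fe: bool = False,
    include_outside: bool = True,
    se_type: str = "HC1",
) -> ModelSpec:
    """Distance-percentile models, optionally with either set of dummies.

    With both dummy sets this is the preferred two-way fixed-effects
    specification (the outside-domain indicator, an evaluator-level
    constant, is absorbed by the evaluator dummies and dropped).
    """
    cont = ["distance_pct"]
    if include_outside and not evaluator_fe:
        cont.append("outside_domain")
    cat = []
    if proposal_fe:
        cat.append("proposal_id")
    if evaluator_fe:
        cat.append("evaluator_id")
    return ModelSpec(continuous=tuple(cont), categorical=tuple(cat), se_type=se_type)


PROPOSAL_COVARIATES = (
    "words",
    "num_refs",
    "num_figs",
    "intro_section",
    "author_pubs",
    "author_cites",
    "n_terms",
)


def novelty_covariate_spec(
    include_distance: bool = False, se_type: str = "HC1"
) -> ModelSpec:
    """Novelty percentile + evaluator dummies + proposal covariate controls."""
    cont = ["novelty_pct"]
    if include_distance:
        cont.append("distance_pct")
    cont.extend(PROPOSAL_COVARIATES)
    return ModelSpec(
        continuous=tuple(cont),
        categorical=("evaluator_id",),
        se_type=se_type,
    )


# ---------------------------------------------------------------------------
# cross-check utilities


def within_transform(
    data: pd.DataFrame,
    columns: Sequence[str],
    by: Sequence[str] = ("proposal_id", "evaluator_id"),
    tol: float = 1e-12,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Iterated two-way demeaning (the Frisch–Waugh partialling path).

    Alternately subtracts group means for each factor in ``by`` until the
    update is below ``tol``; used as an independent cross-check of the
    explicit-dummy fixed-effects fits.
    """
    out = data[list(columns)].astype(float).copy()
    for _ in range(max_iter):
        delta = 0.0
        for factor in by:
            means = out.groupby(data[factor], sort=False).transform("mean")
            out = out - means
            delta = max(delta, float(means.abs().to_numpy().max()))
        if delta < tol:
            break
    return out
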