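"""Counterfactual award rankings: panel averages vs closest experts.

The award process ranks proposals by their panel-average score.  An
alternative scheme ranks them by the scores of each proposal's
intellectually closest assigned evaluator(s).  This module builds both
rankings, a noise-corrected variant of the scores (evaluator fixed effects
and the distance gradient removed), and summary statistics of how far the
two orderings diverge — overall and within quality strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .estimation import FitResult


@dataclass
class RankingResult:
    """A complete ordering of proposals under one aggregation scheme.

    ``table`` has columns proposal_id, aggregate, rank; rank 1 is best.
    Ties in the aggregate are broken by proposal id (deterministic), and
    tied groups are recorded in ``ties``.
    """

    scheme: str
    table: pd.DataFrame
    tie_policy: str = "proposal_id"
    ties: tuple[tuple[str, ...], ...] = ()

    @property
    def ranks(self) -> pd.Series:
        return self.table.set_index("proposal_id")["rank"]

    @property
    def aggregates(self) -> pd.Series:
        return self.table.set_index("proposal_id")["aggregate"]


@dataclass
class RankComparison:
    """Divergence between two rankings of the same proposal set."""

    mean_abs_shift: float
    sd_abs_shift: float
    spearman: float
    per_stratum: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_abs_shift": self.mean_abs_shift,
            "sd_abs_shift": self.sd_abs_shift,
            "spearman": self.spearman,
            "per_stratum": dict(self.per_stratum),
            "n": self.n,
        }


def _rank_table(scheme: str, agg: pd.Series) -> RankingResult:
    df = (
        agg.rename("aggregate")
        .rename_axis("proposal_id")
        .reset_index()
        .sort_values(["aggregate", "proposal_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    df["rank"] = np.arange(1, len(df) + 1)
    tied = [
        tuple(sub["proposal_id"])
        for _, sub in df.groupby("aggregate")
        if len(sub) > 1
    ]
    return RankingResult(
        scheme=scheme, table=df, ties=tuple(sorted(tied))
    )


def rank_by_panel_mean(
    evals: pd.DataFrame, score_col: str = "score"
) -> RankingResult:
    """Rank proposals by their mean score over all assigned evaluators."""
    if evals.empty:
        raise ValueError("no evaluations to rank")
    counts = evals.groupby("proposal_id")[score_col].size()
    if (counts == 0).any():
        raise ValueError("proposal with zero scores")
    means = evals.groupby("proposal_id")[score_col].mean()
    return _rank_table("panel_mean", means)


def rank_by_closest_expert(
    evals: pd.DataFrame,
    features: pd.DataFrame,
    k: int = 1,
    score_col: str = "score",
) -> RankingResult:
    """Rank proposals by the mean score of their k closest assigned evaluators.

    Closeness is the distance percentile from the feature table; distance
    ties are broken by evaluator id.  With k equal to the full panel size
    this reproduces :func:`rank_by_panel_mean` exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    merged = evals.merge(
        features[["evaluator_id", "proposal_id", "distance_pct"]],
        on=["evaluator_id", "proposal_id"],
        how="left",
        validate="one_to_one",
    )
    if merged["distance_pct"].isna().any():
        missing = merged.loc[
            merged["distance_pct"].isna(), ["evaluator_id", "proposal_id"]
        ]
        raise KeyError(
            f"no distance feature for pairs: {missing.to_records(index=False)}"
        )
    short = merged.groupby("proposal_id").size()
    too_few = short[short < k]
    if not too_few.empty:
        raise ValueError(
            f"k={k} exceeds panel size for proposal(s) {list(too_few.index)}"
        )
    chosen = (
        merged.sort_values(["proposal_id", "distance_pct", "evaluator_id"])
        .groupby("proposal_id")
        .head(k)
    )
    agg = chosen.groupby("proposal_id")[score_col].mean()
    return _rank_table(f"closest_expert_k{k}", agg)


def denoise_scores(
    evals: pd.DataFrame,
    features: pd.DataFrame,
    fit: FitResult,
    slope: str = "distance_pct",
) -> pd.DataFrame:
    """Remove evaluator fixed effects and the distance gradient from scores.

    ``fit`` must be a two-way fixed-effects result whose evaluator-dummy
    coefficients cover every evaluator in ``evals`` (the reference level's
    coefficient is zero).  Evaluator effects are centered to mean zero
    across evaluators before subtraction so the score scale is preserved:

        adjusted = score − (delta_hat − mean delta_hat) − beta_hat · distance.

    Returns the evaluation table with an ``adjusted_score`` column.
    """
    beta = float(fit.params.get(slope, 0.0))
    eval_ids = sorted(evals["evaluator_id"].unique())
    prefix = "evaluator_id["
    named = {
        name[len(prefix) : -1]: float(v)
        for name, v in fit.params.items()
        if name.startswith(prefix) and name.endswith("]")
    }
    has_dummies = bool(named)
    if has_dummies:
        # zero-coefficient evaluators: the global reference level (first
        # sorted, no dummy built) and per-block references whose dummies the
        # rank sweep dropped — the block design is disconnected, so two-way
        # fixed effects have one free level per block, not one overall
        allowed = {
            name[len(prefix) : -1]
            for name in fit.dropped
            if name.startswith(prefix) and name.endswith("]")
        }
        allowed.add(min(eval_ids))
        unknown = [e for e in eval_ids if e not in named and e not in allowed]
        if unknown:
            raise KeyError(
                f"evaluator(s) {unknown} absent from the fitted model"
            )
    delta = pd.Series({e: named.get(e, 0.0) for e in eval_ids})
    delta = delta - delta.mean() if has_dummies else delta
    merged = evals.merge(
        features[["evaluator_id", "proposal_id", slope]],
        on=["evaluator_id", "proposal_id"],
        how="left",
        validate="one_to_one",
    )
    out = evals.copy()
    out["adjusted_score"] = (
        merged["score"].to_numpy(float)
        - delta.reindex(merged["evaluator_id"]).to_numpy(float)
        - beta * merged[slope].to_numpy(float)
    )
    return out


def rank_shift(
    r1: RankingResult,
    r2: RankingResult,
    n_strata: int = 4,
    strata_from: RankingResult | None = None,
) -> RankComparison:
    """Mean/s.d. of absolute rank displacement, Spearman correlation, and
    per-quality-stratum agreement.

    Strata (quartiles by default) are defined on the aggregate score of
    ``strata_from`` (defaulting to ``r1``, conventionally the panel-mean
    ranking); stratum 1 collects the top-ranked proposals.
    """
    a = r1.ranks
    b = r2.ranks
    if set(a.index) != set(b.index):
        raise ValueError("rankings cover different proposal sets")
    b = b.reindex(a.index)
    diff = (a - b).abs().astype(float)
    rho = float(spearmanr(a.to_numpy(), b.to_numpy()).statistic) if len(a) > 1 else 1.0
    per: dict[str, float] = {}
    if n_strata >= 2 and len(a) >= n_strata:
        base = (strata_from or r1).ranks.reindex(a.index)
        labels = pd.qcut(base, n_strata, labels=False, duplicates="drop")
        for q in sorted(pd.unique(labels)):
            per[f"q{int(q) + 1}"] = float(diff[labels == q].mean())
    return RankComparison(
        mean_abs_shift=float(diff.mean()),
        sd_abs_shift=float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
        spearman=rho,
        per_stratum=per,
        n=len(a),
    )
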