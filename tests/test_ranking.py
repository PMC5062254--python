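"""Panel vs closest-expert rankings, denoising, and rank-shift statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from meshreview import estimation as est
from meshreview import ranking
from meshreview import synthetic_data as sd


def evals_from(scores: dict[str, list[float]]) -> pd.DataFrame:
    rows = [
        (f"e{i}", pid, s)
        for pid, vals in scores.items()
        for i, s in enumerate(vals)
    ]
    return pd.DataFrame(rows, columns=["evaluator_id", "proposal_id", "score"])


def features_from(dist: dict[tuple[str, str], float]) -> pd.DataFrame:
    rows = [(e, p, d) for (e, p), d in dist.items()]
    return pd.DataFrame(rows, columns=["evaluator_id", "proposal_id", "distance_pct"])


def test_panel_mean_hand_sort():
    r = ranking.rank_by_panel_mean(
        evals_from({"P1": [7], "P2": [5], "P3": [9]})
    )
    assert dict(r.ranks) == {"P3": 1, "P1": 2, "P2": 3}


def test_panel_mean_all_tied_breaks_by_id():
    r = ranking.rank_by_panel_mean(evals_from({"P2": [5], "P1": [5], "P3": [5]}))
    assert dict(r.ranks) == {"P1": 1, "P2": 2, "P3": 3}
    assert r.ties == (("P1", "P2", "P3"),)


def test_single_proposal_rank_one():
    r = ranking.rank_by_panel_mean(evals_from({"P1": [3]}))
    assert dict(r.ranks) == {"P1": 1}


def test_closest_expert_min_distance_selection():
    evals = pd.DataFrame(
        {
            "evaluator_id": ["e1", "e2"],
            "proposal_id": ["P1", "P1"],
            "score": [3, 8],
        }
    )
    feats = features_from({("e1", "P1"): 0.2, ("e2", "P1"): 0.9})
    r = ranking.rank_by_closest_expert(evals, feats, k=1)
    assert float(r.aggregates["P1"]) == 3.0


def test_closest_expert_full_panel_equals_panel_mean(small_world, small_config):
    # 24 evaluators over 6 blocks -> every proposal has exactly 4 raters
    draw = sd.generate_scores(
        small_world, small_world.features, small_config, seed=3
    )
    sizes = draw.table.groupby("proposal_id").size()
    assert (sizes == 4).all()
    panel = ranking.rank_by_panel_mean(draw.table)
    expert_all = ranking.rank_by_closest_expert(
        draw.table, small_world.features, k=4
    )
    pd.testing.assert_series_equal(panel.ranks, expert_all.ranks)


def test_closest_expert_k_too_large_errors():
    evals = evals_from({"P1": [5, 6]})
    feats = features_from({("e0", "P1"): 0.1, ("e1", "P1"): 0.5})
    with pytest.raises(ValueError, match="P1"):
        ranking.rank_by_closest_expert(evals, feats, k=3)


# ---------------------------------------------------------------------------
# denoising


def make_fit(params: dict) -> est.FitResult:
    s = pd.Series(params, dtype=float)
    return est.FitResult(
        params=s,
        bse=s * 0,
        vcov=pd.DataFrame(np.zeros((len(s), len(s))), index=s.index, columns=s.index),
        n_obs=10,
    )


def test_denoise_identity_when_no_effects():
    evals = pd.DataFrame(
        {
            "evaluator_id": ["e1", "e2"],
            "proposal_id": ["P1", "P1"],
            "score": [4, 6],
        }
    )
    feats = features_from({("e1", "P1"): 0.3, ("e2", "P1"): 0.7})
    fit = make_fit({"const": 5.0, "distance_pct": 0.0, "evaluator_id[e2]": 0.0})
    out = ranking.denoise_scores(evals, feats, fit)
    assert np.allclose(out["adjusted_score"], evals["score"])


def test_denoise_subtracts_centered_evaluator_effect():
    evals = pd.DataFrame(
        {
            "evaluator_id": ["e1", "e2"],
            "proposal_id": ["P1", "P1"],
            "score": [4.0, 6.0],
        }
    )
    feats = features_from({("e1", "P1"): 0.0, ("e2", "P1"): 0.0})
    fit = make_fit({"const": 5.0, "distance_pct": 0.0, "evaluator_id[e2]": 1.0})
    out = ranking.denoise_scores(evals, feats, fit).set_index("evaluator_id")
    # centered effects are (-0.5, +0.5): e2's scores drop by 1 relative to e1
    assert out.loc["e1", "adjusted_score"] == pytest.approx(4.5)
    assert out.loc["e2", "adjusted_score"] == pytest.approx(5.5)


def test_denoise_missing_evaluator_errors():
    evals = pd.DataFrame(
        {
            "evaluator_id": ["e1", "e2", "e3"],
            "proposal_id": ["P1", "P1", "P1"],
            "score": [4, 6, 5],
        }
    )
    feats = features_from(
        {("e1", "P1"): 0.1, ("e2", "P1"): 0.2, ("e3", "P1"): 0.3}
    )
    fit = make_fit({"const": 5.0, "evaluator_id[e3]": 1.0})  # e2 unaccounted
    with pytest.raises(KeyError):
        ranking.denoise_scores(evals, feats, fit)


def test_denoise_perfect_limit_constant_within_proposal(small_world):
    """Zero-noise scores: after removing evaluator effects and the distance
    term, adjusted latent scores are constant within proposal."""
    import dataclasses

    cfg = dataclasses.replace(
        small_world.config,
        sigma=0.0,
        tau_e=1.0,
        slope_sd=0.0,
        gamma_n=0.0,
        lambda_o=0.0,
        covariate_effects={},
    )
    draw = sd.generate_scores(small_world, small_world.features, cfg, seed=2)
    data = sd.assemble_analysis_table(small_world, draw.table)
    data = data.assign(score=draw.latent)  # continuous, pre-discretization
    fit = est.fit_ols_robust(
        data, est.distance_spec(proposal_fe=True, evaluator_fe=True)
    )
    out = ranking.denoise_scores(
        data[["evaluator_id", "proposal_id", "score"]],
        small_world.features,
        fit,
    )
    spread = out.groupby("proposal_id")["adjusted_score"].agg(lambda s: s.max() - s.min())
    assert float(spread.max()) < 1e-8


# ---------------------------------------------------------------------------
# rank shift


def ranking_of(order: list[str]) -> ranking.RankingResult:
    n = len(order)
    table = pd.DataFrame(
        {
            "proposal_id": order,
            "aggregate": np.linspace(10, 1, n),
            "rank": np.arange(1, n + 1),
        }
    )
    return ranking.RankingResult(scheme="fixed", table=table)


def test_rank_shift_identical_is_zero():
    r = ranking_of(["P1", "P2", "P3"])
    cmp = ranking.rank_shift(r, r)
    assert cmp.mean_abs_shift == 0.0
    assert cmp.spearman == pytest.approx(1.0)


def test_rank_shift_full_reversal_of_150():
    ids = [f"P{i:03d}" for i in range(150)]
    cmp = ranking.rank_shift(ranking_of(ids), ranking_of(ids[::-1]))
    # closed form: mean |n + 1 - 2i| = n/2 for even n
    assert cmp.mean_abs_shift == pytest.approx(75.0)
    assert cmp.spearman == pytest.approx(-1.0)


def test_rank_shift_adjacent_swap():
    ids = [f"P{i}" for i in range(10)]
    swapped = ids.copy()
    swapped[3], swapped[4] = swapped[4], swapped[3]
    cmp = ranking.rank_shift(ranking_of(ids), ranking_of(swapped))
    assert cmp.mean_abs_shift == pytest.approx(2.0 / 10.0)


def test_rank_shift_mismatched_sets_error():
    with pytest.raises(ValueError):
        ranking.rank_shift(ranking_of(["P1", "P2"]), ranking_of(["P1", "P3"]))


@given(st.permutations(list(range(8))))
def test_rank_shift_symmetric_and_zero_iff_identical(perm):
    ids = [f"P{i}" for i in range(8)]
    permuted = [ids[i] for i in perm]
    a, b = ranking_of(ids), ranking_of(permuted)
    ab = ranking.rank_shift(a, b, n_strata=0)
    ba = ranking.rank_shift(b, a, n_strata=0)
    assert ab.mean_abs_shift == pytest.approx(ba.mean_abs_shift)
    assert (ab.mean_abs_shift == 0.0) == (permuted == ids)


def test_expert_ranking_converges_to_truth_as_noise_vanishes(small_world):
    """With evaluator noise and the distance effect removed, the expert
    ranking recovers the true quality ordering (Spearman -> 1)."""
    import dataclasses

    cfg = dataclasses.replace(
        small_world.config,
        sigma=0.0,
        tau_e=0.0,
        slope_sd=0.0,
        beta_d=0.0,
        gamma_n=0.0,
        lambda_o=0.0,
        covariate_effects={},
        tau_p=1.0,
    )
    draw = sd.generate_scores(small_world, small_world.features, cfg, seed=6)
    table = draw.table.assign(score=draw.latent)
    expert = ranking.rank_by_closest_expert(table, small_world.features, k=1)
    truth = draw.proposal_effects.rank(ascending=False, method="first")
    rho = np.corrcoef(
        expert.ranks.sort_index().to_numpy(),
        truth.sort_index().to_numpy(),
    )[0, 1]
    assert rho == pytest.approx(1.0, abs=1e-12)
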