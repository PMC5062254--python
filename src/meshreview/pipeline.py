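"""Command-line orchestration: generate → score → fit → rank → report.

A single YAML experiment config drives every stage; all outputs are plain
delimited or JSON text so runs are diffable, and every random draw flows
from one master seed.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import click
import pandas as pd
import yaml

from . import estimation, ranking, synthetic_data
from .estimation import (
    distance_spec,
    fit_ols_robust,
    fit_random_slope,
    fit_variance_model,
    novelty_covariate_spec,
    outside_domain_spec,
    variance_decomposition,
)
from .mesh_space import write_publications
from .scoring import write_features
from .synthetic_data import (
    DGPConfig,
    assemble_analysis_table,
    generate_scores,
    generate_world,
    mc_recovery,
)

log = logging.getLogger("meshreview")

DEFAULT_MODELS = (
    "outside_only",
    "distance_proposal_fe",
    "two_way_fe",
    "novelty_covariates",
    "random_slope",
    "variance_model",
)


@dataclass
class ExperimentConfig:
    """Everything one end-to-end run needs, resolvable from YAML."""

    seed: int
    out_dir: str
    generate: dict = field(default_factory=dict)
    models: Sequence[str] = DEFAULT_MODELS
    ranking: dict = field(default_factory=lambda: {"k": 1, "quartiles": 4})
    recovery: dict | None = None  # e.g. {"reps": 20, "model": "two_way_fe"}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        obj = yaml.safe_load(Path(path).read_text())
        if "seed" not in obj:
            raise ValueError("experiment config must set a seed")
        known = {f.name for f in fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**obj)

    def dgp_config(self) -> DGPConfig:
        return replace(DGPConfig(), **self.generate)


def _fit_model(name: str, data: pd.DataFrame, seed: int):
    if name == "outside_only":
        return fit_ols_robust(data, outside_domain_spec())
    if name == "distance_proposal_fe":
        return fit_ols_robust(data, distance_spec(proposal_fe=True))
    if name == "two_way_fe":
        return fit_ols_robust(
            data, distance_spec(proposal_fe=True, evaluator_fe=True)
        )
    if name == "novelty_covariates":
        return fit_ols_robust(data, novelty_covariate_spec())
    if name == "novelty_and_distance":
        return fit_ols_robust(data, novelty_covariate_spec(include_distance=True))
    if name == "random_slope":
        return fit_random_slope(data)
    if name == "variance_model":
        return fit_variance_model(
            data,
            distance_spec(proposal_fe=True, evaluator_fe=True),
            seed=seed,
        )
    if name == "interactions":
        return estimation.fit_interactions(
            data, ("novelty_pct", "senior", "years_since_degree", "female")
        )
    raise ValueError(f"unknown model {name!r}")


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute every stage and write the report bundle under ``out_dir``.

    Returns the manifest (stage timings, seeds, headline numbers).  Any
    stage failure propagates with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    stage = "generate"
    try:
        t0 = time.time()
        cfg = config.dgp_config()
        world = generate_world(cfg, config.seed)
        draw = generate_scores(world, world.features, cfg, seed=0)
        data = assemble_analysis_table(world, draw.table)
        world.vocabulary.to_file(out / "vocabulary.txt")
        write_publications(world.corpus, out / "corpus.jsonl")
        world.pair_index.to_file(out / "pair_index.tsv")
        world.assignment.to_file(out / "assignment.csv")
        write_features(world.features, out / "features.csv")
        draw.table.to_csv(out / "evaluations.csv", index=False)
        data.to_csv(out / "analysis_table.csv", index=False)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "n_pairs": len(data),
            "clip_fraction": draw.clip_fraction,
        }
        log.info("stage %s done (%d pairs)", stage, len(data))

        stage = "fit"
        t0 = time.time()
        fits = {}
        fit_dir = out / "fits"
        fit_dir.mkdir(exist_ok=True)
        for name in config.models:
            res = _fit_model(name, data, config.seed)
            fits[name] = res
            (fit_dir / f"{name}.json").write_text(
                json.dumps(res.to_dict(), indent=2, sort_keys=True)
            )
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "models": list(config.models),
        }

        stage = "decompose"
        manifest["variance_decomposition"] = {
            "proposal_r2": variance_decomposition(data, "proposal"),
            "evaluator_r2": variance_decomposition(data, "evaluator"),
        }

        stage = "rank"
        t0 = time.time()
        k = int(config.ranking.get("k", 1))
        quartiles = int(config.ranking.get("quartiles", 4))
        panel = ranking.rank_by_panel_mean(draw.table)
        expert = ranking.rank_by_closest_expert(draw.table, world.features, k=k)
        shift = ranking.rank_shift(panel, expert, n_strata=quartiles)
        summary = {"panel_vs_expert": shift.to_dict()}
        if "two_way_fe" in fits:
            adj = ranking.denoise_scores(draw.table, world.features, fits["two_way_fe"])
            adj_tab = adj.drop(columns=["score"]).rename(
                columns={"adjusted_score": "score"}
            )[["evaluator_id", "proposal_id", "score"]]
            expert_adj = ranking.rank_by_closest_expert(
                adj_tab, world.features, k=k
            )
            summary["panel_vs_denoised_expert"] = ranking.rank_shift(
                panel, expert_adj, n_strata=quartiles
            ).to_dict()
        pd.concat(
            [
                panel.table.assign(scheme=panel.scheme),
                expert.table.assign(scheme=expert.scheme),
            ]
        ).to_csv(out / "rankings.csv", index=False)
        (out / "ranking_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        manifest["ranking"] = summary["panel_vs_expert"]

        if config.recovery:
            stage = "recover"
            t0 = time.time()
            reps = int(config.recovery.get("reps", 20))
            model = str(config.recovery.get("model", "two_way_fe"))
            truth = {"distance_pct": cfg.beta_d}
            rec = mc_recovery(
                cfg,
                lambda d: _fit_model(model, d, config.seed),
                truth,
                n_reps=reps,
                seed=config.seed,
            )
            rec.to_csv(out / "recovery.csv")
            manifest["stages"][stage] = {
                "seconds": round(time.time() - t0, 3),
                "reps": reps,
            }

        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        return manifest
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def read_evaluations(path: str | Path) -> pd.DataFrame:
    """Read and validate a score table (evaluator_id, proposal_id, score)."""
    df = pd.read_csv(path)
    required = {"evaluator_id", "proposal_id", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"evaluation table missing columns {sorted(missing)}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = df.index[
        scores.isna() | (scores % 1 != 0) | (scores < 1) | (scores > 10)
    ]
    if len(bad):
        rows = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
        raise ValueError(
            f"scores must be integers in 1..10; offending file row(s) {rows}"
        )
    df["score"] = scores.astype(int)
    return df


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log stage progress.")
def cli(verbose: bool) -> None:
    """Distance/novelty peer-review analysis pipeline."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        stream=sys.stderr,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _load_config(config_path: str | None, seed: int | None, out: str | None):
    if config_path:
        cfg = ExperimentConfig.from_yaml(config_path)
        if seed is not None:
            cfg.seed = seed
        if out is not None:
            cfg.out_dir = out
    else:
        if seed is None or out is None:
            raise click.UsageError("--seed and --out are required without --config")
        cfg = ExperimentConfig(seed=seed, out_dir=out)
    return cfg


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
def run(config_path, seed, out) -> None:
    """Run the full experiment: generate, fit, rank, report."""
    cfg = _load_config(config_path, seed, out)
    manifest = run_experiment(cfg)
    click.echo(json.dumps(manifest, indent=2, sort_keys=True))


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
def simulate(config_path, seed, out) -> None:
    """Generate a synthetic world and score set only."""
    cfg = _load_config(config_path, seed, out)
    cfg.models = ()
    cfg.recovery = None
    manifest = run_experiment(cfg)
    click.echo(json.dumps(manifest["stages"], indent=2, sort_keys=True))


@cli.command()
@click.option("--data", type=click.Path(exists=True), required=True,
              help="Pair-level analysis table (CSV).")
@click.option("--model", type=click.Choice(
    DEFAULT_MODELS + ("novelty_and_distance", "interactions")), required=True)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default=None)
def fit(data, model, seed, out) -> None:
    """Fit one model specification on an existing analysis table."""
    table = pd.read_csv(data)
    res = _fit_model(model, table, seed)
    text = json.dumps(res.to_dict(), indent=2, sort_keys=True)
    if out:
        Path(out).write_text(text)
    click.echo(text)


@cli.command()
@click.option("--evals", type=click.Path(exists=True), required=True)
@click.option("--features", "features_path", type=click.Path(exists=True),
              required=True)
@click.option("--k", type=int, default=1, help="Closest evaluators averaged.")
@click.option("--quartiles", type=int, default=4)
def rank(evals, features_path, k, quartiles) -> None:
    """Compare panel-mean and closest-expert rankings."""
    from .scoring import read_features

    ev = read_evaluations(evals)
    feats = read_features(features_path)
    panel = ranking.rank_by_panel_mean(ev)
    expert = ranking.rank_by_closest_expert(ev, feats, k=k)
    shift = ranking.rank_shift(panel, expert, n_strata=quartiles)
    click.echo(json.dumps(shift.to_dict(), indent=2, sort_keys=True))


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
@click.option("--reps", type=int, default=20)
@click.option("--model", type=click.Choice(DEFAULT_MODELS), default="two_way_fe")
def recover(config_path, seed, out, reps, model) -> None:
    """Monte-Carlo recovery of the distance slope under the default DGP."""
    cfg = _load_config(config_path, seed, out)
    cfg.recovery = {"reps": reps, "model": model}
    cfg.models = ()
    manifest = run_experiment(cfg)
    rec = pd.read_csv(Path(cfg.out_dir) / "recovery.csv")
    click.echo(rec.to_string(index=False))


if __name__ == "__main__":
    cli()
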