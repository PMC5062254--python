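"""Stratified recruitment and block-randomized evaluator–proposal assignment.

The study design partitions the proposal pool into equal-size blocks and
hands each evaluator one whole, randomly chosen block to score.  Because
block membership is random, the intellectual distance an evaluator faces is
independent of proposal quality — the source of the design's causal
leverage.  The default ``balanced`` assignment keeps block loads within one
evaluator of each other (142 evaluators over 10 blocks → loads of 14 or 15,
mean 14.2 per proposal); an independent-uniform option is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("in_domain", "linked", "outside")
SENIORITIES = ("junior", "senior")


def _as_rng(rng_seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


@dataclass
class Assignment:
    """Evaluator → proposal-block mapping and the induced pair list."""

    blocks: dict[str, tuple[str, ...]]
    evaluator_block: dict[str, str]

    def __post_init__(self) -> None:
        all_props = [p for blk in self.blocks.values() for p in blk]
        if len(all_props) != len(set(all_props)):
            raise ValueError("blocks are not disjoint")
        unknown = set(self.evaluator_block.values()) - set(self.blocks)
        if unknown:
            raise ValueError(f"evaluators mapped to unknown blocks {sorted(unknown)}")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """(evaluator_id, proposal_id) pairs: each evaluator × their block."""
        return [
            (eid, pid)
            for eid, blk in sorted(self.evaluator_block.items())
            for pid in self.blocks[blk]
        ]

    @property
    def n_pairs(self) -> int:
        return sum(len(self.blocks[b]) for b in self.evaluator_block.values())

    def block_loads(self) -> dict[str, int]:
        loads = {b: 0 for b in self.blocks}
        for blk in self.evaluator_block.values():
            loads[blk] += 1
        return loads

    def evaluators_per_proposal(self) -> pd.Series:
        loads = self.block_loads()
        data = {
            pid: loads[b] for b, props in self.blocks.items() for pid in props
        }
        return pd.Series(data, name="n_evaluators").sort_index()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (eid, pid, self.evaluator_block[eid]) for eid, pid in self.pairs
        ]
        return pd.DataFrame(rows, columns=["evaluator_id", "proposal_id", "block_id"])

    def to_file(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Assignment":
        blocks: dict[str, tuple[str, ...]] = {}
        for bid, sub in df.groupby("block_id", sort=True):
            blocks[str(bid)] = tuple(sorted(sub["proposal_id"].unique()))
        evaluator_block = {
            str(e): str(b)
            for e, b in df.drop_duplicates("evaluator_id")[
                ["evaluator_id", "block_id"]
            ].itertuples(index=False)
        }
        return cls(blocks=blocks, evaluator_block=evaluator_block)

    @classmethod
    def from_file(cls, path) -> "Assignment":
        return cls.from_frame(pd.read_csv(path, dtype=str))


@dataclass
class RecruitmentFrame:
    """Stratified roster: 3 domain-relation groups × 2 seniority levels."""

    invitations_per_stratum: int
    roster: pd.DataFrame  # evaluator_id, group, seniority

    @property
    def n_invited(self) -> int:
        return len(GROUPS) * len(SENIORITIES) * self.invitations_per_stratum

    @property
    def n_accepted(self) -> int:
        return len(self.roster)

    def stratum_counts(self) -> pd.Series:
        return self.roster.groupby(["group", "seniority"]).size()


def partition_blocks(
    proposal_ids: Sequence[str],
    block_size: int,
    rng_seed: int | np.random.Generator,
) -> dict[str, tuple[str, ...]]:
    """Uniformly random partition of proposals into equal-size blocks."""
    ids = list(proposal_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate proposal ids")
    n = len(ids)
    if block_size < 1 or n % block_size != 0:
        raise ValueError(
            f"{n} proposals are not divisible into blocks of {block_size} "
            f"(remainder {n % block_size})"
        )
    rng = _as_rng(rng_seed)
    perm = rng.permutation(n)
    n_blocks = n // block_size
    width = max(2, len(str(n_blocks - 1)))
    return {
        f"B{b:0{width}d}": tuple(
            ids[i] for i in perm[b * block_size : (b + 1) * block_size]
        )
        for b in range(n_blocks)
    }


def assign_evaluators(
    evaluator_ids: Sequence[str],
    blocks: Mapping[str, tuple[str, ...]],
    rng_seed: int | np.random.Generator,
    balanced: bool = True,
) -> Assignment:
    """Randomly assign each evaluator one proposal block.

    ``balanced=True`` (default) round-robins shuffled evaluators over
    shuffled blocks so loads differ by at most one; ``balanced=False``
    draws each evaluator's block independently and uniformly.
    """
    evals = list(evaluator_ids)
    if not evals:
        raise ValueError("empty evaluator list")
    if len(evals) != len(set(evals)):
        raise ValueError("duplicate evaluator ids")
    if not blocks:
        raise ValueError("no blocks to assign")
    rng = _as_rng(rng_seed)
    block_ids = sorted(blocks)
    if balanced:
        order = rng.permutation(len(evals))
        cycle = [block_ids[i] for i in rng.permutation(len(block_ids))]
        mapping = {
            evals[order[k]]: cycle[k % len(cycle)] for k in range(len(evals))
        }
    else:
        draws = rng.integers(0, len(block_ids), size=len(evals))
        mapping = {e: block_ids[d] for e, d in zip(evals, draws)}
    return Assignment(blocks=dict(blocks), evaluator_block=mapping)


def recruit_frame(
    invitations_per_stratum: int,
    acceptance: int | float | Mapping[tuple[str, str], int],
    rng_seed: int | np.random.Generator,
) -> RecruitmentFrame:
    """Build a stratified evaluator roster from an invitation frame.

    ``acceptance`` is either a total accepted count (sampled without
    replacement from all invitees), a per-stratum acceptance probability,
    or a mapping (group, seniority) → accepted count.
    """
    import warnings

    rng = _as_rng(rng_seed)
    strata = [(g, s) for g in GROUPS for s in SENIORITIES]
    invited = [
        (f"E{i:03d}", g, s)
        for i, (g, s) in enumerate(
            (gs for gs in strata for _ in range(invitations_per_stratum))
        )
    ]
    n_invited = len(invited)

    if isinstance(acceptance, Mapping):
        rows = []
        for g, s in strata:
            pool = [r for r in invited if r[1] == g and r[2] == s]
            k = int(acceptance.get((g, s), 0))
            if k > len(pool):
                raise ValueError(
                    f"stratum ({g}, {s}): accepted {k} > invited {len(pool)}"
                )
            keep = rng.choice(len(pool), size=k, replace=False)
            rows.extend(pool[i] for i in sorted(keep))
    elif isinstance(acceptance, float) and 0.0 <= acceptance <= 1.0:
        mask = rng.random(n_invited) < acceptance
        rows = [r for r, m in zip(invited, mask) if m]
    elif isinstance(acceptance, int):
        if acceptance > n_invited:
            raise ValueError(
                f"accepted count {acceptance} exceeds {n_invited} invitations"
            )
        keep = sorted(rng.choice(n_invited, size=acceptance, replace=False))
        rows = [invited[i] for i in keep]
    else:
        raise TypeError("acceptance must be an int count, a probability, or a map")

    if not rows:
        warnings.warn("recruitment produced an empty roster", stacklevel=2)
    roster = pd.DataFrame(rows, columns=["evaluator_id", "group", "seniority"])
    return RecruitmentFrame(
        invitations_per_stratum=invitations_per_stratum, roster=roster
    )
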