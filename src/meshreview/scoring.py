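"""The two pair-level measures: intellectual distance and proposal novelty.

Distance is one minus the cosine between a proposal's binary keyword vector
and an evaluator's publication-count keyword vector; novelty is the fraction
of a proposal's unordered keyword pairs that never occur in the reference
pair index.  Both raw measures are rank-transformed to percentiles on
(0, 1], so a regression coefficient reads as the effect of moving from the
closest (most precedented) to the most distant (most novel) percentile.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .mesh_space import EvaluatorProfile, PairIndex, ProposalDoc, term_pairs

FEATURE_COLUMNS = (
    "evaluator_id",
    "proposal_id",
    "distance_raw",
    "distance_pct",
    "novelty_raw",
    "novelty_pct",
    "outside_domain",
)


def cosine_distance_raw(
    proposal_terms: Iterable[str], profile: EvaluatorProfile
) -> float:
    """1 − cosine(binary proposal vector, evaluator count vector), in [0, 1].

    A degenerate all-zero profile (no publications) has no direction; such
    evaluators are maximally distant by convention and a warning is issued.
    """
    terms = set(proposal_terms)
    if not terms:
        raise ValueError("proposal term set is empty; distance undefined")
    e_norm = profile.norm
    if e_norm == 0.0:
        warnings.warn(
            f"evaluator {profile.evaluator_id}: zero publication vector; "
            "returning maximal distance",
            stacklevel=2,
        )
        return 1.0
    dot = float(sum(profile.term_counts.get(t, 0) for t in terms))
    p_norm = float(len(terms)) ** 0.5
    cos = dot / (p_norm * e_norm)
    # clamp tiny numerical overshoot
    return float(min(1.0, max(0.0, 1.0 - cos)))


def novelty_raw(proposal_terms: Iterable[str], index: PairIndex) -> float:
    """Fraction of the proposal's N(N−1)/2 keyword pairs absent from the index.

    With fewer than two terms no pair exists; NaN is returned (a flagged
    missing value) rather than a silent zero.
    """
    pairs = term_pairs(proposal_terms)
    if not pairs:
        warnings.warn("proposal has < 2 terms; novelty undefined", stacklevel=2)
        return float("nan")
    unseen = sum(1 for p in pairs if p not in index.pairs)
    return unseen / len(pairs)


def percentile_transform(
    values: Sequence[float] | np.ndarray, tie_policy: str = "average"
) -> np.ndarray:
    """Map values to percentile ranks on (0, 1]: rank r (ascending) → r/n.

    Ties share their average rank by default, keeping the transform
    order-preserving and deterministic.  On n distinct inputs the output is
    the uniform grid {1/n, …, 1} with s.d. √((n²−1)/(12n²)).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty value list")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values cannot be percentile-ranked")
    return rankdata(arr, method=tie_policy) / arr.size


def pair_features(
    assignment,
    proposals: Sequence[ProposalDoc] | Mapping[str, ProposalDoc],
    profiles: Sequence[EvaluatorProfile] | Mapping[str, EvaluatorProfile],
    index: PairIndex,
    domain_terms: Iterable[str] = (),
    pct_reference: str = "assigned",
) -> pd.DataFrame:
    """Score every assigned evaluator–proposal pair.

    Parameters
    ----------
    assignment
        A :class:`meshreview.design.Assignment` (anything with a ``pairs``
        attribute of (evaluator_id, proposal_id) tuples).
    proposals, profiles
        The documents and evaluator profiles referenced by the assignment.
    index
        Pair index defining the novelty baseline.
    domain_terms
        Terms defining the grant's domain; an evaluator with zero
        publication counts on this set is flagged ``outside_domain``.
    pct_reference
        ``"assigned"`` (default) ranks distance within the assigned pairs —
        the analysis units; ``"all"`` ranks against every potential
        evaluator × proposal pair.

    Returns
    -------
    DataFrame with one row per assigned pair, ordered by
    (proposal_id, evaluator_id), columns :data:`FEATURE_COLUMNS`.
    Novelty columns are constant within proposal; novelty percentiles are
    computed across proposals.
    """
    if pct_reference not in ("assigned", "all"):
        raise ValueError(f"unknown pct_reference {pct_reference!r}")
    prop_map = (
        dict(proposals)
        if isinstance(proposals, Mapping)
        else {p.proposal_id: p for p in proposals}
    )
    prof_map = (
        dict(profiles)
        if isinstance(profiles, Mapping)
        else {p.evaluator_id: p for p in profiles}
    )

    pairs = sorted(assignment.pairs, key=lambda pe: (pe[1], pe[0]))
    bad_prop = sorted({p for _, p in pairs if p not in prop_map})
    bad_eval = sorted({e for e, _ in pairs if e not in prof_map})
    if bad_prop or bad_eval:
        raise KeyError(
            f"unresolvable ids in assignment: proposals {bad_prop}, "
            f"evaluators {bad_eval}"
        )

    domain = set(domain_terms)
    outside = {
        eid: int(prof.domain_pub_count(domain) == 0) if domain else 0
        for eid, prof in prof_map.items()
    }

    nov_ids = sorted(prop_map)
    nov_raw = {
        pid: novelty_raw(prop_map[pid].mesh_terms, index)
        if len(prop_map[pid].mesh_terms) >= 2
        else float("nan")
        for pid in nov_ids
    }
    nov_vals = np.array([nov_raw[p] for p in nov_ids])
    finite = np.isfinite(nov_vals)
    nov_pct = np.full(len(nov_ids), np.nan)
    if finite.any():
        nov_pct[finite] = percentile_transform(nov_vals[finite])
    nov_pct_map = dict(zip(nov_ids, nov_pct))

    dist = np.array(
        [
            cosine_distance_raw(prop_map[p].mesh_terms, prof_map[e])
            for e, p in pairs
        ]
    )
    if pct_reference == "assigned":
        dist_pct = percentile_transform(dist)
    else:
        keys = [
            (eid, pid) for pid in sorted(prop_map) for eid in sorted(prof_map)
        ]
        all_vals = np.array(
            [
                cosine_distance_raw(prop_map[pid].mesh_terms, prof_map[eid])
                for eid, pid in keys
            ]
        )
        pct_map = dict(zip(keys, percentile_transform(all_vals)))
        dist_pct = np.array([pct_map[(e, p)] for e, p in pairs])

    return pd.DataFrame(
        {
            "evaluator_id": [e for e, _ in pairs],
            "proposal_id": [p for _, p in pairs],
            "distance_raw": dist,
            "distance_pct": dist_pct,
            "novelty_raw": [nov_raw[p] for _, p in pairs],
            "novelty_pct": [nov_pct_map[p] for _, p in pairs],
            "outside_domain": [outside[e] for e, _ in pairs],
        }
    )


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns {sorted(missing)}")
    return df
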