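"""Keyword-space representation of publications, proposals and evaluators.

Research proposals and evaluator publication histories are both described by
controlled-vocabulary keywords (MeSH terms in the motivating application).
This module holds the domain types for that representation and two derived
structures:

* :class:`PairIndex` — the set of unordered keyword pairs observed anywhere
  in a reference publication corpus.  A proposal whose keyword pairs are
  absent from this index is combining ideas that the existing literature has
  not combined before; the index is therefore the baseline against which
  combinatorial novelty is scored.
* :class:`EvaluatorProfile` — per-term publication counts for one evaluator,
  the count vector whose angle to a proposal's binary keyword vector defines
  intellectual distance.

Terms are opaque canonical strings; no keyword hierarchy is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class CorpusFormatError(ValueError):
    """A corpus line could not be parsed into (doc_id, year, terms)."""


class VocabularyError(ValueError):
    """A record refers to terms outside the supplied vocabulary."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair ``{a, b}`` in canonical (lexicographic) order."""
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid term pair")
    return (a, b) if a < b else (b, a)


def term_pairs(terms: Iterable[str]) -> set[tuple[str, str]]:
    """All N(N-1)/2 unordered pairs of distinct terms, canonically ordered."""
    return {canonical_pair(a, b) for a, b in combinations(sorted(set(terms)), 2)}


@dataclass(frozen=True)
class MeshVocabulary:
    """A controlled keyword vocabulary (a set of canonical term identifiers)."""

    terms: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))
        if any((not t) or (not isinstance(t, str)) for t in self.terms):
            raise VocabularyError("vocabulary terms must be non-empty strings")
        if len(self.terms) < 2:
            raise VocabularyError("vocabulary needs at least 2 terms")

    @property
    def size(self) -> int:
        return len(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: object) -> bool:
        return term in self.terms

    @classmethod
    def from_file(cls, path: str | Path) -> "MeshVocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(frozenset(t.strip() for t in lines if t.strip()))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "\n".join(sorted(self.terms)) + "\n", encoding="utf-8"
        )


@dataclass(frozen=True)
class PublicationRecord:
    """One indexed publication: identifier, year, and its keyword set."""

    doc_id: str
    year: int
    mesh_terms: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mesh_terms", frozenset(self.mesh_terms))
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not self.mesh_terms:
            raise ValueError(f"record {self.doc_id}: empty term set")


@dataclass(frozen=True)
class ProposalDoc:
    """A research proposal: keyword set plus observable covariates."""

    proposal_id: str
    mesh_terms: frozenset[str]
    words: int = 0
    num_refs: int = 0
    num_figs: int = 0
    intro_section: bool = False
    author_pubs: int = 0
    author_cites: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mesh_terms", frozenset(self.mesh_terms))
        for name in ("words", "num_refs", "num_figs", "author_pubs", "author_cites"):
            if getattr(self, name) < 0:
                raise ValueError(f"proposal {self.proposal_id}: {name} negative")

    @property
    def n_terms(self) -> int:
        return len(self.mesh_terms)


@dataclass(frozen=True)
class PairIndex:
    """Unordered keyword pairs observed in a reference corpus.

    ``pairs`` holds each pair once, in lexicographic order.  ``source_size``
    is the number of corpus records the index was built from;
    ``cutoff_year`` records the inclusive year bound, if one was applied.
    """

    pairs: frozenset[tuple[str, str]]
    source_size: int
    cutoff_year: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        for a, b in self.pairs:
            if not a < b:
                raise ValueError(f"pair {(a, b)!r} is not in canonical order")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: object) -> bool:
        a, b = pair  # type: ignore[misc]
        return canonical_pair(a, b) in self.pairs

    def to_file(self, path: str | Path) -> None:
        """Write the index as sorted two-column TSV (diffable, bit-stable)."""
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in sorted(self.pairs):
                fh.write(f"{a}\t{b}\n")

    @classmethod
    def from_file(
        cls, path: str | Path, source_size: int = 0, cutoff_year: int | None = None
    ) -> "PairIndex":
        pairs = set()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: expected two tab-separated terms"
                    )
                pairs.add(canonical_pair(*parts))
        return cls(frozenset(pairs), source_size=source_size, cutoff_year=cutoff_year)


@dataclass
class EvaluatorProfile:
    """An evaluator's publication-count keyword vector plus roster attributes.

    ``term_counts[t]`` is the number of distinct publications by this
    evaluator carrying term ``t`` (so each count is at most ``n_pubs``).
    A profile with ``n_pubs == 0`` is a valid, degenerate all-zero vector.
    """

    evaluator_id: str
    term_counts: dict[str, int] = field(default_factory=dict)
    n_pubs: int = 0
    group: str = "outside"  # in_domain | linked | outside
    seniority: str = "junior"  # junior | senior
    gender: str = "unknown"
    years_since_degree: int = 0

    _GROUPS = ("in_domain", "linked", "outside")
    _SENIORITIES = ("junior", "senior")

    def __post_init__(self) -> None:
        if self.group not in self._GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.seniority not in self._SENIORITIES:
            raise ValueError(f"unknown seniority {self.seniority!r}")
        if self.years_since_degree < 0:
            raise ValueError("years_since_degree must be non-negative")
        for t, c in self.term_counts.items():
            if c < 0 or c > self.n_pubs:
                raise ValueError(
                    f"profile {self.evaluator_id}: count for {t!r} is {c}, "
                    f"outside [0, n_pubs={self.n_pubs}]"
                )

    @property
    def degenerate(self) -> bool:
        """True when the evaluator has no publications (all-zero vector)."""
        return self.n_pubs == 0 or not any(self.term_counts.values())

    @property
    def norm(self) -> float:
        return float(sum(c * c for c in self.term_counts.values())) ** 0.5

    def domain_pub_count(self, domain_terms: Iterable[str]) -> int:
        """Total term-count mass on a domain-defining term set."""
        return sum(self.term_counts.get(t, 0) for t in domain_terms)


# ---------------------------------------------------------------------------
# operations


def load_publications(
    path: str | Path,
    vocabulary: MeshVocabulary | None = None,
    lenient: bool = False,
) -> list[PublicationRecord]:
    """Read a line-delimited JSON corpus of publication records.

    Each line must be an object with keys ``doc_id``, ``year`` and
    ``mesh_terms``.  When a ``vocabulary`` is supplied, terms outside it
    raise :class:`VocabularyError` (or are reported and dropped per-record
    under ``lenient=True``); invalid terms are never silently ignored.
    """
    import warnings

    records: list[PublicationRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: invalid JSON ({exc})")
            missing = {"doc_id", "year", "mesh_terms"} - set(obj)
            if missing:
                raise CorpusFormatError(
                    f"{path}:{lineno}: missing field(s) {sorted(missing)}"
                )
            if not isinstance(obj["year"], int):
                raise CorpusFormatError(f"{path}:{lineno}: year must be an integer")
            terms = obj["mesh_terms"]
            if not isinstance(terms, list) or not terms:
                raise CorpusFormatError(
                    f"{path}:{lineno}: mesh_terms must be a non-empty list"
                )
            if vocabulary is not None:
                unknown = sorted(t for t in terms if t not in vocabulary)
                if unknown:
                    msg = f"{path}:{lineno}: unknown term(s) {unknown}"
                    if not lenient:
                        raise VocabularyError(msg)
                    warnings.warn(msg, stacklevel=2)
                    terms = [t for t in terms if t in vocabulary]
                    if not terms:
                        continue
            records.append(
                PublicationRecord(str(obj["doc_id"]), obj["year"], frozenset(terms))
            )
    return records


def write_publications(records: Iterable[PublicationRecord], path: str | Path) -> None:
    """Write records as line-delimited JSON (terms sorted, so output is stable)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "doc_id": rec.doc_id,
                        "year": rec.year,
                        "mesh_terms": sorted(rec.mesh_terms),
                    }
                )
                + "\n"
            )


def build_pair_index(
    records: Sequence[PublicationRecord], cutoff_year: int | None = None
) -> PairIndex:
    """Index every unordered keyword pair occurring within some record.

    A record with N distinct terms contributes N(N-1)/2 pairs; single-term
    records contribute none.  ``cutoff_year`` (inclusive) restricts the
    corpus, emulating "the literature up to year Y".
    """
    if len(records) == 0:
        raise ValueError("cannot build a pair index from an empty record list")
    used = 0
    pairs: set[tuple[str, str]] = set()
    for rec in records:
        if cutoff_year is not None and rec.year > cutoff_year:
            continue
        used += 1
        terms = sorted(rec.mesh_terms)
        pairs.update(
            (terms[i], terms[j])
            for i in range(len(terms))
            for j in range(i + 1, len(terms))
        )
    return PairIndex(frozenset(pairs), source_size=used, cutoff_year=cutoff_year)


def build_profile(
    evaluator_id: str,
    records: Sequence[PublicationRecord],
    *,
    group: str,
    seniority: str,
    gender: str = "unknown",
    years_since_degree: int = 0,
) -> EvaluatorProfile:
    """Aggregate an evaluator's publications into a term-count profile.

    ``term_counts[t]`` counts distinct records containing ``t``; duplicate
    ``doc_id`` values are an error (they would double-count papers).  An
    empty record list yields a degenerate all-zero profile.
    """
    seen: set[str] = set()
    counts: dict[str, int] = {}
    for rec in records:
        if rec.doc_id in seen:
            raise ValueError(
                f"profile {evaluator_id}: duplicate doc_id {rec.doc_id!r}"
            )
        seen.add(rec.doc_id)
        for t in rec.mesh_terms:
            counts[t] = counts.get(t, 0) + 1
    return EvaluatorProfile(
        evaluator_id=evaluator_id,
        term_counts=counts,
        n_pubs=len(records),
        group=group,
        seniority=seniority,
        gender=gender,
        years_since_degree=years_since_degree,
    )


def profile_from_counts(
    evaluator_id: str,
    term_counts: Mapping[str, int],
    n_pubs: int,
    **attrs: object,
) -> EvaluatorProfile:
    """Build a profile directly from per-term counts (generator fast path)."""
    return EvaluatorProfile(
        evaluator_id=evaluator_id,
        term_counts=dict(term_counts),
        n_pubs=n_pubs,
        **attrs,  # type: ignore[arg-type]
    )
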