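"""BLAST-hit classification: simple and optimized weighted rescoring,
identity tiers, 1%-deviation candidate counting and rank-level assignment.

The input is an offline hit table in an outfmt-6-like TSV dialect extended
with taxonomy columns (see HIT_COLUMNS). Two ranking methods are provided:

* ``simple`` — the top 10 hits ordered by bit score;
* ``optimized`` — the top 100 hits re-ranked by the weighted score
  ``max_score * (query_cover / identity)``, which boosts hits whose coverage
  exceeds their identity.

A query is then assigned to a taxonomic rank by combining the identity tier
of the best candidate (High >=95%, Medium >=90%, Low <90%; the source tiers
overlap at the boundaries and the upper bound wins here) with the set of
species whose score lies within a 1% deviation of the best score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .exceptions import DomainError, SchemaError

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "species",
    "genus",
    "family",
    "bitscore",
    "qcovs",
    "pident",
]

RANKS = ("species", "species_group", "genus", "family", "unassigned")
TIERS = ("High", "Medium", "Low")


@dataclass(frozen=True)
class HitRecord:
    """One candidate hit for a query, with taxonomy and scoring fields."""

    query_id: str
    subject_id: str
    subject_species: str
    genus: str
    family: str
    max_score: float
    query_cover: float
    identity: float

    def __post_init__(self):
        if self.max_score < 0:
            raise SchemaError(f"{self.query_id}: negative bit score")
        if not (0 <= self.query_cover <= 100):
            raise SchemaError(f"{self.query_id}: query cover out of [0,100]")
        if not (0 < self.identity <= 100):
            raise SchemaError(f"{self.query_id}: identity out of (0,100]")


@dataclass(frozen=True)
class Assignment:
    """Rank-level taxonomic call for one query."""

    query_id: str
    rank: str
    taxon: str
    tier: str | None
    n_candidate_species: int
    method: str
    genus: str | None = None
    family: str | None = None


def read_hit_table(path) -> list[HitRecord]:
    """Read an extended outfmt-6 TSV (header row, HIT_COLUMNS) into records."""
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"hit table missing columns: {sorted(missing)}")
    if df.empty:
        logger.warning("empty hit table: %s", path)
        return []
    return [
        HitRecord(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            subject_species=str(r.species),
            genus=str(r.genus),
            family=str(r.family),
            max_score=float(r.bitscore),
            query_cover=float(r.qcovs),
            identity=float(r.pident),
        )
        for r in df.itertuples()
    ]


def write_hit_table(hits, path) -> None:
    rows = [
        (
            h.query_id,
            h.subject_id,
            h.subject_species,
            h.genus,
            h.family,
            h.max_score,
            h.query_cover,
            h.identity,
        )
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def weighted_score(hit: HitRecord) -> float:
    """Optimized-method rescoring: max_score * (query_cover / identity)."""
    if hit.identity == 0:
        raise DomainError("identity must be positive")
    return hit.max_score * (hit.query_cover / hit.identity)


def identity_tier(identity: float) -> str:
    """High >= 95, Medium in [90, 95), Low < 90 (upper bound wins at 90/95)."""
    if identity >= 95:
        return "High"
    if identity >= 90:
        return "Medium"
    return "Low"


def candidate_set(hits, method: str) -> list[HitRecord]:
    """Ordered candidate hits for one query.

    simple: top 10 by bit score. optimized: top 100 by bit score, then
    re-ranked by :func:`weighted_score`. Ties break by identity (descending)
    then subject species name (ascending).
    """
    hits = list(hits)
    if not hits:
        raise DomainError("candidate_set needs at least one hit")
    if method not in ("simple", "optimized"):
        raise DomainError(f"unknown method: {method!r}")
    by_max = sorted(
        hits, key=lambda h: (-h.max_score, -h.identity, h.subject_species)
    )
    if method == "simple":
        return by_max[:10]
    top = by_max[:100]
    return sorted(
        top, key=lambda h: (-weighted_score(h), -h.identity, h.subject_species)
    )


def _ranking_score(hit: HitRecord, method: str) -> float:
    return hit.max_score if method == "simple" else weighted_score(hit)


def species_within_deviation(candidates, method: str, deviation: float = 0.01):
    """Distinct species whose ranking score is within ``deviation`` of the best.

    The active method's ranking score is used (bit score for simple, weighted
    score for optimized). Returns species in first-seen candidate order.
    """
    best = _ranking_score(candidates[0], method)
    if best <= 0:
        return [candidates[0].subject_species]
    cutoff = (1.0 - deviation) * best
    seen: list[str] = []
    for h in candidates:
        if _ranking_score(h, method) >= cutoff and h.subject_species not in seen:
            seen.append(h.subject_species)
    return seen


def assign(query_id, hits, method="optimized", synonym_groups=None,
           deviation=0.01) -> Assignment:
    """Rank-level taxonomic call for one query via a five-rule ladder.

    1. tier High and exactly one species within deviation -> species;
    2. all deviation species inside one synonym group, tier High/Medium ->
       species_group labeled with the group;
    3. all within one genus, tier High/Medium -> genus;
    4. all within one family (any tier, including Low when unanimous) ->
       family;
    5. otherwise unassigned.

    An empty hit list yields unassigned with zero candidate species.
    """
    synonym_groups = synonym_groups or {}
    hits = [h for h in hits if h.query_id == query_id] if hits else []
    if not hits:
        return Assignment(query_id, "unassigned", "", None, 0, method)
    cands = candidate_set(hits, method)
    tier = identity_tier(cands[0].identity)
    dev_species = species_within_deviation(cands, method, deviation)
    by_species = {h.subject_species: h for h in cands}
    genera = {by_species[s].genus for s in dev_species}
    families = {by_species[s].family for s in dev_species}
    n = len(dev_species)
    lineage = dict(
        genus=genera.copy().pop() if len(genera) == 1 else None,
        family=families.copy().pop() if len(families) == 1 else None,
    )

    if tier == "High" and n == 1:
        sp = dev_species[0]
        return Assignment(query_id, "species", sp, tier, n, method, **lineage)
    if tier in ("High", "Medium"):
        groups = {synonym_groups.get(s) for s in dev_species}
        if len(groups) == 1 and None not in groups:
            return Assignment(
                query_id, "species_group", groups.pop(), tier, n, method, **lineage
            )
        if len(genera) == 1:
            return Assignment(
                query_id, "genus", genera.pop(), tier, n, method, **lineage
            )
    if len(families) == 1:
        return Assignment(
            query_id, "family", families.pop(), tier, n, method, **lineage
        )
    return Assignment(query_id, "unassigned", "", tier, n, method, **lineage)


def assign_all(hits, method="optimized", synonym_groups=None, deviation=0.01):
    """Group a hit list by query and assign each query."""
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return [
        assign(q, qh, method=method, synonym_groups=synonym_groups,
               deviation=deviation)
        for q, qh in sorted(by_query.items())
    ]


_SPECIFICITY = {r: i for i, r in enumerate(RANKS)}


def _project(a: Assignment, rank: str) -> str | None:
    """Taxon that assignment ``a`` implies at coarser rank ``rank``."""
    if a.rank == "unassigned":
        return None
    if _SPECIFICITY[a.rank] > _SPECIFICITY[rank]:
        return None  # cannot sharpen a coarse call
    if a.rank == rank:
        return a.taxon
    if rank == "genus":
        return a.genus
    if rank == "family":
        return a.family
    return None


def consensus_assignment(member_assignments, query_id, label) -> Assignment:
    """Combination-level call: the most specific rank on which a strict
    majority of member-marker assignments agree on the same taxon.

    Member calls project upward (a species call votes for its genus at the
    genus rank). Ranks where no taxon reaches a strict majority degrade to
    the next coarser rank; no consensus at any rank yields unassigned.
    """
    members = list(member_assignments)
    half = len(members) / 2.0
    for rank in ("species", "species_group", "genus", "family"):
        votes: dict[str, int] = {}
        for a in members:
            taxon = _project(a, rank)
            if taxon:
                votes[taxon] = votes.get(taxon, 0) + 1
        if votes:
            top_taxon, top_count = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
            if top_count > half:
                donors = [a for a in members if _project(a, rank) == top_taxon]
                return Assignment(
                    query_id,
                    rank,
                    top_taxon,
                    donors[0].tier,
                    donors[0].n_candidate_species,
                    donors[0].method,
                    genus=donors[0].genus,
                    family=donors[0].family,
                )
    return Assignment(query_id, "unassigned", "", None, 0,
                      members[0].method if members else "optimized")


def summarize_efficiency(assignments_by_label) -> pd.DataFrame:
    """Percent of queries assigned at each rank, per marker/combination label.

    ``assignments_by_label`` maps a label to its list of assignments. Rows
    sum to 100 per label (the discrimination-efficiency table structure).
    """
    rows = []
    for label, assignments in assignments_by_label.items():
        total = len(assignments)
        counts = {r: 0 for r in RANKS}
        for a in assignments:
            counts[a.rank] += 1
        row = {"label": label}
        for r in RANKS:
            row[r] = 100.0 * counts[r] / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows, columns=["label", *RANKS])
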