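"""Rank-resolved taxon calls from best-hit mismatch scores.

Calibrated thresholds translate a best-hit mismatch score into the
finest taxonomic rank the hit supports: scores strictly under 0.3%
indicate the same species, under 2.0% the same genus, under 4% the
same family; anything at or above 4% is left unassigned. All hits
whose score falls inside the winning band vote on the taxon; if they
disagree at that rank the call is demoted to their lowest common rank
(a lowest-common-ancestor consensus), dropping to unassigned when even
the families conflict.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from sklearn.base import BaseEstimator

from .align import AlignmentResult, search
from .seqio import QueryFragment, ReferenceDB

RANKS = ("species", "genus", "family")


@dataclass(frozen=True)
class AssignmentThresholds:
    """Strict upper bounds on mismatch score per rank (fractions)."""

    species_max: float = 0.003
    genus_max: float = 0.020
    family_max: float = 0.040

    def __post_init__(self) -> None:
        if not (0 < self.species_max < self.genus_max < self.family_max):
            raise ValueError("thresholds must satisfy 0 < species < genus < family")

    def band(self, score: float) -> str:
        """Finest rank whose (strict) threshold contains the score."""
        if score < self.species_max:
            return "species"
        if score < self.genus_max:
            return "genus"
        if score < self.family_max:
            return "family"
        return "unassigned"

    def band_max(self, rank: str) -> float:
        return {"species": self.species_max, "genus": self.genus_max, "family": self.family_max}[rank]


@dataclass
class Assignment:
    """Rank-resolved call for one query."""

    query_id: str
    assigned_rank: str  # species | genus | family | unassigned
    assigned_taxon: str | None
    best_score: float | None
    supporting_refs: list[str] = field(default_factory=list)
    #: taxon names at each rank at or above the assigned rank
    lineage: dict[str, str] = field(default_factory=dict)

    @property
    def is_assigned(self) -> bool:
        return self.assigned_rank != "unassigned"


def _unassigned(query_id: str, score: float | None = None) -> Assignment:
    return Assignment(query_id, "unassigned", None, score)


def assign(
    hits: list[AlignmentResult],
    db: ReferenceDB,
    thresholds: AssignmentThresholds = AssignmentThresholds(),
) -> Assignment:
    """Convert a ranked hit list into one taxon call.

    ``hits`` must be sorted ascending by mismatch score (as produced by
    :func:`dietbarcode.align.search`). Empty hits yield an unassigned
    call with undefined score.
    """
    if not hits:
        return Assignment("?", "unassigned", None, None)
    query_id = hits[0].query_id
    best = hits[0].mismatch_score
    rank = thresholds.band(best)
    if rank == "unassigned":
        return _unassigned(query_id, best)

    band_max = thresholds.band_max(rank)
    voters = [h for h in hits if h.mismatch_score < band_max]
    lineages = [db.lineage(h.ref_id) for h in voters]

    # demote to the lowest common rank among the voters
    for try_rank in RANKS[RANKS.index(rank):]:
        names = {lin[try_rank] for lin in lineages}
        if len(names) == 1:
            taxon = names.pop()
            idx = RANKS.index(try_rank)
            lineage = {r: lineages[0][r] for r in RANKS[idx:]}
            return Assignment(
                query_id=query_id,
                assigned_rank=try_rank,
                assigned_taxon=taxon,
                best_score=best,
                supporting_refs=[h.ref_id for h in voters],
                lineage=lineage,
            )
    return _unassigned(query_id, best)


def assign_query(
    query: QueryFragment,
    db: ReferenceDB,
    thresholds: AssignmentThresholds = AssignmentThresholds(),
) -> Assignment:
    """Search the reference and assign in one step."""
    return assign(search(query, db), db, thresholds)


def tally_assignments(assignments: list[Assignment]) -> dict:
    """Per-rank query counts and distinct-taxon counts.

    ``queries_per_rank`` counts calls at each resolution.
    ``distinct_taxa`` counts each taxon once regardless of how many
    queries hit it (the minimum number of candidate taxa); a call at a
    fine rank also contributes its coarser ranks, so three queries all
    assigned to one species contribute one species, one genus and one
    family.
    """
    queries_per_rank = Counter(a.assigned_rank for a in assignments)
    distinct: dict[str, set] = {r: set() for r in RANKS}
    for a in assignments:
        for rank in RANKS:
            if rank in a.lineage:
                distinct[rank].add(a.lineage[rank])
    return {
        "queries_per_rank": {r: queries_per_rank.get(r, 0) for r in (*RANKS, "unassigned")},
        "distinct_taxa": {r: len(distinct[r]) for r in RANKS},
    }


class BarcodeTaxonomyClassifier(BaseEstimator):
    """Threshold-based barcode classifier with a scikit-learn surface.

    Fit on a reference database, predict rank-resolved taxon calls for
    query fragments.

    Parameters
    ----------
    species_max, genus_max, family_max : float
        Strict mismatch-score thresholds per rank.
    min_coverage : float
        Minimum query coverage for an alignment to count as a hit.

    Attributes
    ----------
    db_ : ReferenceDB
        The fitted reference database.
    n_reference_ : int
        Number of reference sequences.
    """

    def __init__(
        self,
        species_max: float = 0.003,
        genus_max: float = 0.020,
        family_max: float = 0.040,
        min_coverage: float = 0.5,
    ):
        self.species_max = species_max
        self.genus_max = genus_max
        self.family_max = family_max
        self.min_coverage = min_coverage

    def _thresholds(self) -> AssignmentThresholds:
        return AssignmentThresholds(self.species_max, self.genus_max, self.family_max)

    def fit(self, X: ReferenceDB, y=None):
        """Store and validate the reference database."""
        if not isinstance(X, ReferenceDB):
            raise TypeError("X must be a ReferenceDB")
        if len(X) == 0:
            raise ValueError("reference database is empty")
        self._thresholds()  # validates ordering
        self.db_ = X
        self.n_reference_ = len(X)
        return self

    def predict(self, X: list[QueryFragment]) -> list[Assignment]:
        """Assign each query fragment to a taxon (or unassigned)."""
        if not hasattr(self, "db_"):
            raise RuntimeError("classifier is not fitted")
        thresholds = self._thresholds()
        out = []
        for q in X:
            hits = search(q, self.db_, min_coverage=self.min_coverage)
            a = assign(hits, self.db_, thresholds)
            a.query_id = q.seq_id
            out.append(a)
        return out
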