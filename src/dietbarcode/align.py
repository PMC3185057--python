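"""Local alignment of barcode fragments and the mismatch statistic.

A query is compared to a reference by Smith-Waterman local alignment
(match +1, mismatch -1, gap open -2, gap extend -1). The distance used
throughout the pipeline is the *mismatch score*

    (gap openings + mismatched columns) / alignment length

computed over the aligned region, where a gap opening is the start of
a maximal run of gap characters in either row. Because dung-fibre
fragments have unknown orientation, both strands are aligned and the
orientation with the lower mismatch score is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Seq import reverse_complement

from .seqio import QueryFragment, ReferenceDB

_PLAIN_BASES = frozenset("ACGT")

#: Hits covering less than this fraction of the query are rejected as
#: spurious local matches ("no hit").
MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class AlignmentResult:
    """One query-reference local alignment and its mismatch statistic."""

    query_id: str
    ref_id: str
    alignment_length: int
    n_mismatches: int
    n_gap_openings: int
    coverage: float
    mismatch_score: float
    strand: str = "+"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def _count_gap_openings(row: str) -> int:
    openings = 0
    in_gap = False
    for ch in row:
        if ch == "-":
            if not in_gap:
                openings += 1
            in_gap = True
        else:
            in_gap = False
    return openings


def _walk_columns(qrow: str, rrow: str) -> tuple[int, int, int]:
    """Return (alignment_length, n_mismatches, n_gap_openings).

    A column counts as a mismatch when both rows hold a base and the
    bases differ, or when either base is an ambiguity code (ambiguity
    codes never count as matches, even against themselves).
    """
    n_mismatches = 0
    for qc, rc in zip(qrow, rrow):
        if qc == "-" or rc == "-":
            continue
        if qc != rc or qc not in _PLAIN_BASES or rc not in _PLAIN_BASES:
            n_mismatches += 1
    n_gaps = _count_gap_openings(qrow) + _count_gap_openings(rrow)
    return len(qrow), n_mismatches, n_gaps


def _align_one_strand(query: str, reference: str) -> tuple[float, int, int, int, int] | None:
    """Best local alignment on the given strand.

    Returns (mismatch_score, alignment_length, n_mismatches,
    n_gap_openings, aligned_query_bases), or None when nothing aligns
    with positive score.
    """
    alignments = _ALIGNER.align(query, reference)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    best = alignments[0]  # deterministic: first optimal traceback
    qrow, rrow = str(best[0]), str(best[1])
    length, n_mm, n_gap = _walk_columns(qrow, rrow)
    aligned_query = sum(1 for ch in qrow if ch != "-")
    score = (n_gap + n_mm) / length
    return score, length, n_mm, n_gap, aligned_query


def align_pair(
    query: str,
    reference: str,
    query_id: str = "query",
    ref_id: str = "ref",
    min_coverage: float = MIN_COVERAGE,
    both_strands: bool = True,
) -> AlignmentResult | None:
    """Align one query against one reference; None means "no hit".

    The mismatch score of the better-scoring orientation is reported;
    ties favour the forward strand. A hit must cover at least
    ``min_coverage`` of the query to count.
    """
    if not query or not reference:
        raise ValueError("sequences must be nonempty")
    query = query.upper()
    reference = reference.upper()

    strands = [(0, "+", query)]
    if both_strands:
        strands.append((1, "-", reverse_complement(query)))
    candidates = []
    for order, strand, seq in strands:
        stats = _align_one_strand(seq, reference)
        if stats is None:
            continue
        coverage = stats[4] / len(query)
        if coverage < min_coverage:  # spurious short local match
            continue
        candidates.append((stats[0], order, strand, stats, coverage))
    if not candidates:
        return None
    score, _, strand, stats, coverage = min(candidates, key=lambda c: (c[0], c[1]))
    _, length, n_mm, n_gap, _ = stats
    return AlignmentResult(
        query_id=query_id,
        ref_id=ref_id,
        alignment_length=length,
        n_mismatches=n_mm,
        n_gap_openings=n_gap,
        coverage=coverage,
        mismatch_score=score,
        strand=strand,
    )


def search(
    query: QueryFragment,
    db: ReferenceDB,
    top_k: int | None = None,
    min_coverage: float = MIN_COVERAGE,
) -> list[AlignmentResult]:
    """Rank every reference by mismatch score against one query.

    Results are sorted by ascending mismatch score, ties broken by
    ref_id, and truncated to ``top_k`` when given. The query must have
    passed QC.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    hits = []
    for ref_id in db:
        res = align_pair(
            query.sequence,
            db.records[ref_id],
            query_id=query.seq_id,
            ref_id=ref_id,
            min_coverage=min_coverage,
        )
        if res is not None:
            hits.append(res)
    hits.sort(key=lambda h: (h.mismatch_score, h.ref_id))
    return hits[:top_k] if top_k is not None else hits
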