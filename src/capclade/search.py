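"""Local alignment and the iterative, query-expanding family census.

The census emulates the BLAST-based survey with an in-repo Smith-Waterman
(affine gaps, BLOSUM62) plus Karlin-Altschul e-values, so the whole
procedure is self-contained and deterministic.  Acceptance keeps the
survey's thresholds: e-value <= 1e-10 and > 130 aligned residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from . import seqio
from .seqio import SeqRecord


@dataclass(frozen=True)
class SearchParams:
    """Thresholds and scoring parameters for the census.

    The affine gap cost of a length-k gap is ``gap_open + (k-1)*gap_extend``.
    ``lam`` and ``K`` are the Karlin-Altschul parameters for gapped
    BLOSUM62 11/1 scoring.
    """

    evalue_cutoff: float = 1e-10
    min_aligned_length: int = 130
    gap_open: float = 11.0
    gap_extend: float = 1.0
    scoring_matrix: str = "BLOSUM62"
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self):
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.min_aligned_length < 1:
            raise ValueError("min_aligned_length must be >= 1")
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("need gap_open >= gap_extend > 0")


@dataclass(frozen=True)
class LocalHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float
    aligned_length: int
    query_span: tuple[int, int]    # 0-based half-open
    subject_span: tuple[int, int]


@dataclass
class CensusRow:
    member_id: str
    species: str
    group: str
    best_hit: LocalHit
    round_found: int


def _aligner(params: SearchParams, mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = seqio.blosum62()
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if mode == "global":
        # free end gaps
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    return aligner


def local_score(query: SeqRecord, subject: SeqRecord, params: SearchParams) -> float:
    """Optimal Smith-Waterman score only (cheaper than a full traceback)."""
    if not query.residues or not subject.residues:
        return 0.0
    return float(_aligner(params).score(query.residues, subject.residues))


def local_align(
    query: SeqRecord, subject: SeqRecord, params: SearchParams | None = None,
    db_residues: int | None = None,
) -> LocalHit | None:
    """Optimal local alignment of two protein sequences.

    Returns ``None`` when the optimum is 0 (no positively scoring local
    alignment).  ``db_residues`` sets the Karlin-Altschul search-space n;
    it defaults to the subject length.
    """
    params = params or SearchParams()
    if not query.residues or not subject.residues:
        return None
    aligner = _aligner(params)
    score = float(aligner.score(query.residues, subject.residues))
    if score <= 0:
        return None
    aln = next(iter(aligner.align(query.residues, subject.residues)))
    blocks_q, blocks_s = aln.aligned
    qspan = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
    sspan = (int(blocks_s[0][0]), int(blocks_s[-1][1]))
    ncols = int(aln.shape[1])
    n = db_residues if db_residues is not None else len(subject.residues)
    e = evalue(score, len(query.residues), n, params)
    return LocalHit(
        query_id=query.id,
        subject_id=subject.id,
        score=score,
        evalue=e,
        aligned_length=ncols,
        query_span=qspan,
        subject_span=sspan,
    )


def evalue(score: float, query_len: int, db_residues: int, params: SearchParams | None = None) -> float:
    """Karlin-Altschul expected hit count: E = K * m * n * exp(-lambda*S)."""
    params = params or SearchParams()
    if score < 0 or query_len < 1 or db_residues < 1:
        raise ValueError("need score >= 0 and lengths >= 1")
    return params.K * query_len * db_residues * math.exp(-params.lam * score)


def iterative_census(
    seed_queries: list[SeqRecord],
    databases: list[list[SeqRecord]],
    params: SearchParams | None = None,
) -> list[CensusRow]:
    """Query-expanding census: accepted hits become queries for the next
    round, iterating to a fixpoint.

    A subject is accepted when some query reaches both thresholds
    (e-value and aligned length).  ``round_found`` records the first
    accepting round.  Novelty is by exact subject id.  The result is
    independent of database concatenation order (set of member ids).
    """
    params = params or SearchParams()
    if not seed_queries:
        raise ValueError("need at least one seed query")
    subjects: dict[str, SeqRecord] = {}
    for db in databases:
        for rec in db:
            if rec.id in subjects:
                raise ValueError(f"duplicate subject id {rec.id!r} across databases")
            subjects[rec.id] = rec
    db_residues = sum(len(r) for r in subjects.values())
    if db_residues == 0:
        return []

    accepted: dict[str, CensusRow] = {}
    queries = list(seed_queries)
    round_no = 0
    while queries:
        round_no += 1
        newly: list[SeqRecord] = []
        # stable iteration order: insertion order of the subject dict
        for sid, subj in subjects.items():
            if sid in accepted:
                continue
            best: LocalHit | None = None
            for q in sorted(queries, key=lambda r: r.id):
                score = local_score(q, subj, params)
                if score <= 0:
                    continue
                e = evalue(score, len(q), db_residues, params)
                if e > params.evalue_cutoff:
                    continue
                hit = local_align(q, subj, params, db_residues=db_residues)
                if hit is None or hit.aligned_length < params.min_aligned_length:
                    continue
                if best is None or hit.score > best.score:
                    best = hit
            if best is not None:
                accepted[sid] = CensusRow(
                    member_id=sid,
                    species=subj.species,
                    group=subj.group,
                    best_hit=best,
                    round_found=round_no,
                )
                newly.append(subj)
        queries = newly
    return list(accepted.values())


def census_table(rows: list[CensusRow]) -> pd.DataFrame:
    """Census as the census.tsv table (one row per accepted member)."""
    return pd.DataFrame(
        [
            {
                "member_id": r.member_id,
                "species": r.species,
                "group": r.group,
                "best_query": r.best_hit.query_id,
                "score": r.best_hit.score,
                "evalue": r.best_hit.evalue,
                "aligned_length": r.best_hit.aligned_length,
                "round_found": r.round_found,
            }
            for r in rows
        ],
        columns=[
            "member_id", "species", "group", "best_query",
            "score", "evalue", "aligned_length", "round_found",
        ],
    )
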