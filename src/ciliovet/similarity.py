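"""Protein similarity search: local alignment, E-values, top-k retention.

This is the pipeline's stand-in for BLASTP/TBlastN-style searching: optimal
Smith–Waterman–Gotoh local alignment (BLOSUM62, affine gaps) with
Karlin–Altschul E-values computed from fixed ungapped parameters. The
E-values serve only to apply the pipeline's retention cutoffs (1e-30 strict,
1e-4 permissive), not to reproduce database statistics.

Identity is reported in the cd-hit convention — identities over the length
of the SHORTER sequence — because the subtraction screen's 80% threshold is
short-sequence-relative; per-aligned-column identity is kept alongside for
diagnostics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import Align
from Bio.Align import substitution_matrices

# fixed ungapped Karlin-Altschul parameters for BLOSUM62 (approximation;
# E-values are used for thresholding only)
LAMBDA = 0.267
K_PARAM = 0.041


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    raw_score: float
    bitscore: float
    evalue: float
    identity_fraction: float      # identities / len(shorter sequence)
    column_identity: float        # identities / aligned columns
    q_span: tuple                 # 0-based half-open on query
    s_span: tuple                 # 0-based half-open on subject


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load(matrix)
    a.open_gap_score = -(gap_open + gap_extend)
    a.extend_gap_score = -gap_extend
    return a


def bitscore_of(raw_score: float, lambda_: float = LAMBDA, k: float = K_PARAM) -> float:
    return (lambda_ * raw_score - math.log(k)) / math.log(2.0)


def evalue_of(
    raw_score: float, m: int, n: int, lambda_: float = LAMBDA, k: float = K_PARAM
) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λS)."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    if lambda_ <= 0 or k <= 0:
        raise ValueError("lambda and K must be positive")
    return k * m * n * math.exp(-lambda_ * raw_score)


def align_pair_local(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    subject_id: str = "subject",
    aligner: Optional[Align.PairwiseAligner] = None,
) -> Optional[SimilarityHit]:
    """Optimal local affine-gap alignment of two protein sequences.

    Returns None when the optimal local score is <= 0 (no positively scoring
    segment pair: "no hit").
    """
    if not a or not b:
        raise ValueError("empty sequence")
    al = aligner if aligner is not None else _make_aligner(matrix, gap_open, gap_extend)
    score = al.score(a, b)
    if score <= 0:
        return None
    aln = al.align(a, b)[0]
    counts = aln.counts()
    identities = counts.identities
    columns = counts.identities + counts.mismatches
    blocks_a, blocks_b = aln.aligned
    q_span = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    s_span = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    return SimilarityHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=float(score),
        bitscore=bitscore_of(score),
        evalue=evalue_of(score, len(a), len(b)),
        identity_fraction=identities / min(len(a), len(b)),
        column_identity=identities / columns if columns else 0.0,
        q_span=q_span,
        s_span=s_span,
    )


def _kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search(
    queries: Iterable,
    db: Iterable,
    evalue_cutoff: float = 1e-30,
    max_hits: int = 6,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    prefilter_k: Optional[int] = 5,
) -> list[SimilarityHit]:
    """Many-vs-many search with per-query top-k retention.

    Per query, hits with evalue <= cutoff are sorted by ascending E-value,
    then descending bitscore, then subject id (stable tie-break), and
    truncated to ``max_hits``. The k-mer prefilter only ever skips pairs
    sharing zero k-mers; set ``prefilter_k=None`` for exhaustive search.
    """
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    queries = list(queries)
    db = list(db)
    al = _make_aligner(matrix, gap_open, gap_extend)
    index = None
    if prefilter_k is not None:
        index = {}
        for j, s in enumerate(db):
            for km in _kmers(s.seq, prefilter_k):
                index.setdefault(km, set()).add(j)
    out: list[SimilarityHit] = []
    for q in queries:
        if index is not None:
            cand: set = set()
            for km in _kmers(q.seq, prefilter_k):
                cand |= index.get(km, set())
            candidates = sorted(cand)
        else:
            candidates = range(len(db))
        hits = []
        for j in candidates:
            s = db[j]
            score = al.score(q.seq, s.seq)
            if score <= 0:
                continue
            if evalue_of(score, len(q.seq), len(s.seq)) > evalue_cutoff:
                continue
            hit = align_pair_local(
                q.seq, s.seq, query_id=q.id, subject_id=s.id, aligner=al
            )
            if hit is not None:
                hits.append(hit)
        hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        out.extend(hits[:max_hits])
    return out
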