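"""Ortholog filtering and desk-scale local alignment.

Candidate orthologous sequences come from BLAST tabular hits and are kept
when e-value < 0.01 and percent identity >= 80 (per HSP). A built-in
Smith-Waterman aligner (BLASTN-like scoring: match +2, mismatch -3, gap
open -5, extend -2) supports small ad-hoc checks without running BLAST;
statistics stay with BLAST, though a Karlin-Altschul-style e-value can be
attached when an effective search-space size is supplied. Accepted
orthologs plus the query are exported as multi-FASTA for external
sequence-structure alignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import Align
from scipy.optimize import brentq

from .ioformats import BlastTabRow, SequenceRecord, write_fasta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologParams:
    max_evalue: float = 0.01
    min_identity_pct: float = 80.0

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if not 0 < self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be in (0, 100]")


@dataclass(frozen=True)
class OrthologHit:
    species_or_subject: str
    identity_pct: float
    evalue: float
    query_interval: tuple[int, int]  # 0-based half-open
    subject_interval: tuple[int, int]


@dataclass(frozen=True)
class AlignerScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0  # score of the first gapped position
    gap_extend: float = -2.0  # each additional gapped position
    max_len: int = 20_000  # O(nm) cost cap


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    identity_pct: float  # matches / alignment columns (incl. gaps) * 100
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    n_columns: int
    n_matches: int
    evalue: float | None = None


def filter_ortholog_hits(
    rows: list[BlastTabRow], params: OrthologParams = OrthologParams()
) -> list[OrthologHit]:
    """Apply the e-value/identity filter and keep the best hit per subject.

    Best = lowest e-value, ties broken by highest bitscore then by subject
    id. BLAST 1-based inclusive coordinates are converted to 0-based
    half-open (minus-strand subject coordinates are normalised so that
    start < end).
    """
    passing = [
        r for r in rows if r.evalue < params.max_evalue and r.identity_pct >= params.min_identity_pct
    ]
    best: dict[str, BlastTabRow] = {}
    for row in passing:
        cur = best.get(row.subject_id)
        if cur is None or (row.evalue, -row.bitscore) < (cur.evalue, -cur.bitscore):
            best[row.subject_id] = row
    hits = []
    for subject in sorted(best):
        r = best[subject]
        q0, q1 = sorted((r.q_start, r.q_end))
        s0, s1 = sorted((r.s_start, r.s_end))
        hits.append(
            OrthologHit(
                species_or_subject=subject,
                identity_pct=r.identity_pct,
                evalue=r.evalue,
                query_interval=(q0 - 1, q1),
                subject_interval=(s0 - 1, s1),
            )
        )
    return hits


def _make_aligner(scoring: AlignerScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def karlin_altschul_lambda(scoring: AlignerScoring, background: float = 0.25) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for a uniform background."""

    def f(lam: float) -> float:
        # 4 matching and 12 mismatching base pairs under uniform composition
        return (
            4 * background**2 * math.exp(lam * scoring.match)
            + 12 * background**2 * math.exp(lam * scoring.mismatch)
            - 1.0
        )

    return brentq(f, 1e-6, 10.0)


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    scoring: AlignerScoring = AlignerScoring(),
    search_space: float | None = None,
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Identity uses alignment columns (including gap columns) as denominator,
    matching BLAST tabular semantics. When ``search_space`` (an effective
    m*n database size) is given, a Karlin-Altschul-style e-value
    E = K * space * exp(-lambda * S) with K = 0.1 is attached; otherwise
    only raw score and identity are reported.
    """
    if not query.seq or not subject.seq:
        raise ValueError("both sequences must be non-empty")
    if len(query.seq) > scoring.max_len or len(subject.seq) > scoring.max_len:
        raise ValueError(
            f"sequence exceeds the {scoring.max_len} nt aligner cap; "
            "run BLAST externally for inputs of this size"
        )
    aligner = _make_aligner(scoring)
    alignments = aligner.align(query.seq, subject.seq)
    if alignments.score <= 0:
        return LocalAlignment(0.0, 0.0, (0, 0), (0, 0), 0, 0, None)
    best = alignments[0]
    q_blocks, s_blocks = best.aligned
    n_matches = 0
    aligned_cols = 0
    for (qa, qb), (sa, sb) in zip(q_blocks, s_blocks):
        aligned_cols += qb - qa
        n_matches += sum(
            1 for qc, sc in zip(query.seq[qa:qb], subject.seq[sa:sb]) if qc == sc
        )
    # gap columns: unaligned stretches between consecutive blocks
    gap_cols = 0
    for i in range(1, len(q_blocks)):
        gap_cols += (q_blocks[i][0] - q_blocks[i - 1][1]) + (s_blocks[i][0] - s_blocks[i - 1][1])
    n_columns = aligned_cols + gap_cols
    evalue = None
    if search_space is not None:
        lam = karlin_altschul_lambda(scoring)
        evalue = 0.1 * search_space * math.exp(-lam * best.score)
    return LocalAlignment(
        score=float(best.score),
        identity_pct=100.0 * n_matches / n_columns if n_columns else 0.0,
        query_interval=(int(q_blocks[0][0]), int(q_blocks[-1][1])),
        subject_interval=(int(s_blocks[0][0]), int(s_blocks[-1][1])),
        n_columns=n_columns,
        n_matches=n_matches,
        evalue=evalue,
    )


def export_ortholog_fasta(
    hits: list[OrthologHit],
    sequences: Mapping[str, SequenceRecord],
    query: SequenceRecord,
    path: str | Path,
) -> int:
    """Write query + accepted ortholog sequences as multi-FASTA for external
    structure alignment. Returns the number of records written."""
    missing = [h.species_or_subject for h in hits if h.species_or_subject not in sequences]
    if missing:
        raise KeyError(f"no sequence available for ortholog hit(s): {sorted(set(missing))}")
    seen: set[str] = set()
    records = [query]
    for h in hits:
        sid = h.species_or_subject
        if sid in seen:
            logger.warning("duplicate ortholog subject %s deduplicated", sid)
            continue
        seen.add(sid)
        records.append(sequences[sid])
    if not hits:
        logger.warning("no orthologs accepted; structure alignment not meaningful")
    write_fasta(records, path)
    return len(records)
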