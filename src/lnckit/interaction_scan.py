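"""RNA-RNA interaction prediction by complementarity alignment.

A duplex between two RNAs is modelled as an antiparallel local alignment
under a complementarity scoring scheme: Watson-Crick pairs (A:U, G:C) score
+5, G:U wobble +1, other juxtapositions -3, with affine gaps (open -9,
extend -4; a gap of length L costs open + (L-1)*extend). A per-pair additive
energy (G:C -3, A:U -2, G:U -1 kcal/mol) accompanies each hit — a stacking-
and loop-free simplification, so the energy threshold operates on this
model's scale.

Long query RNAs are split into overlapping snippets (default 50 nt, step
25), each snippet is aligned against each target, and passing hits are
back-mapped to full-query coordinates and merged when they overlap. miRNA
queries are short enough to scan whole. Default reporting thresholds:
score >= 120 for miRNA hits; score >= 160 and energy <= -72 kcal/mol for
mRNA hits (the energy filter applies to the mRNA scan only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .ioformats import FormatError, InteractionRecord, SequenceRecord

logger = logging.getLogger(__name__)

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}
#: sequestering a masked position must never pay, hence the large penalty
_MASK_SCORE = -10_000.0


@dataclass(frozen=True)
class ScanParameters:
    """Scoring scheme, snippet geometry and reporting thresholds."""

    snippet_len: int = 50
    snippet_step: int = 25
    min_snippet_len: int = 20
    score_threshold_mirna: float = 120.0
    score_threshold_mrna: float = 160.0
    energy_threshold_kcal: float = -72.0  # mRNA scan only
    match_wc: float = 5.0
    match_wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    energy_gc: float = -3.0
    energy_au: float = -2.0
    energy_gu: float = -1.0
    max_hits_per_pair: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.min_snippet_len <= self.snippet_len:
            raise ValueError("need 0 < min_snippet_len <= snippet_len")
        if not 0 < self.snippet_step <= self.snippet_len:
            raise ValueError("need 0 < snippet_step <= snippet_len")

    def pair_energy(self, q: str, t: str) -> float:
        if (q, t) in _WOBBLE_PAIRS:
            return self.energy_gu
        if (q, t) in _WC_PAIRS:
            return self.energy_gc if "G" in (q, t) else self.energy_au
        return 0.0


@dataclass(frozen=True)
class DuplexHit:
    """A scored complementarity alignment in full-sequence coordinates."""

    query_id: str
    target_id: str
    query_interval: tuple[int, int]  # 0-based half-open, native 5'->3'
    target_interval: tuple[int, int]
    score: float
    energy_kcal: float
    n_paired: int


def _substitution_matrix(params: ScanParameters) -> substitution_matrices.Array:
    alphabet = "ACGUN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                m[a, b] = _MASK_SCORE
            elif (a, b) in _WC_PAIRS:
                m[a, b] = params.match_wc
            elif (a, b) in _WOBBLE_PAIRS:
                m[a, b] = params.match_wobble
            else:
                m[a, b] = params.mismatch
    return m


def _make_aligner(params: ScanParameters) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _substitution_matrix(params)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def split_snippets(
    seq: SequenceRecord, params: ScanParameters = ScanParameters()
) -> list[tuple[tuple[int, int], str]]:
    """Tile a sequence into overlapping windows.

    Windows start at multiples of ``snippet_step`` and span up to
    ``snippet_len`` bases; trailing windows shorter than
    ``min_snippet_len`` are dropped, except the window at offset 0, which
    is always kept so no sequence silently yields nothing. For any sequence
    of length >= min_snippet_len the windows cover every base.
    """
    n = len(seq.seq)
    out = []
    start = 0
    reached = 0
    while start < n:
        end = min(start + params.snippet_len, n)
        if end - start >= params.min_snippet_len or start == 0:
            out.append(((start, end), seq.seq[start:end]))
            reached = max(reached, end)
        if end == n:
            break
        start += params.snippet_step
    if reached < n:  # dropped tail: re-anchor a final full-width window at the end
        a = max(0, n - params.snippet_len)
        if not out or out[-1][0] != (a, n):
            out.append(((a, n), seq.seq[a:n]))
    return out


def _validate_rna(rec: SequenceRecord) -> None:
    if rec.moltype != "RNA":
        raise FormatError(f"duplex scanning requires RNA sequences; {rec.id!r} is {rec.moltype}")


def duplex_align(
    query_rna: SequenceRecord,
    target_rna: SequenceRecord,
    params: ScanParameters = ScanParameters(),
    min_score: float = 1.0,
) -> list[DuplexHit]:
    """All non-overlapping duplex alignments between two RNAs, best first.

    The query is reversed internally so both strands are processed 5'->3'
    in antiparallel register; reported intervals are in each molecule's
    native 5'->3' coordinates. After the optimal alignment is found its
    target footprint is masked and the scan repeats, yielding suboptimal
    non-overlapping hits down to ``min_score`` (or ``max_hits_per_pair``).
    """
    _validate_rna(query_rna)
    _validate_rna(target_rna)
    aligner = _make_aligner(params)
    rev_query = query_rna.seq[::-1]
    target = list(target_rna.seq)
    lq = len(rev_query)
    hits: list[DuplexHit] = []
    for _ in range(params.max_hits_per_pair):
        alignments = aligner.align(rev_query, "".join(target))
        try:
            score = float(alignments.score)
        except (AttributeError, OverflowError):
            break
        if score < min_score or score <= 0:
            break
        best = alignments[0]
        q_blocks, t_blocks = best.aligned
        n_paired = 0
        energy = 0.0
        for (qa, qb), (ta, tb) in zip(q_blocks, t_blocks):
            for qc, tc in zip(rev_query[qa:qb], target[ta:tb]):
                if (qc, tc) in _WC_PAIRS or (qc, tc) in _WOBBLE_PAIRS:
                    n_paired += 1
                    energy += params.pair_energy(qc, tc)
        q0, q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
        t0, t1 = int(t_blocks[0][0]), int(t_blocks[-1][1])
        hits.append(
            DuplexHit(
                query_id=query_rna.id,
                target_id=target_rna.id,
                query_interval=(lq - q1, lq - q0),  # back to native 5'->3'
                target_interval=(t0, t1),
                score=score,
                energy_kcal=energy,
                n_paired=n_paired,
            )
        )
        for i in range(t0, t1):  # mask the footprint, rescan for suboptimals
            target[i] = "N"
    return hits


def _merge_hits(hits: list[DuplexHit]) -> list[DuplexHit]:
    """Merge hits on the same target whose full-coordinate query intervals
    overlap: interval union, maximum score, most stable energy."""
    by_target: dict[str, list[DuplexHit]] = {}
    for h in hits:
        by_target.setdefault(h.target_id, []).append(h)
    merged: list[DuplexHit] = []
    for target_id in sorted(by_target):
        group = sorted(by_target[target_id], key=lambda h: h.query_interval)
        current = group[0]
        for nxt in group[1:]:
            if nxt.query_interval[0] < current.query_interval[1]:
                current = DuplexHit(
                    query_id=current.query_id,
                    target_id=target_id,
                    query_interval=(
                        min(current.query_interval[0], nxt.query_interval[0]),
                        max(current.query_interval[1], nxt.query_interval[1]),
                    ),
                    target_interval=(
                        min(current.target_interval[0], nxt.target_interval[0]),
                        max(current.target_interval[1], nxt.target_interval[1]),
                    ),
                    score=max(current.score, nxt.score),
                    energy_kcal=min(current.energy_kcal, nxt.energy_kcal),
                    n_paired=max(current.n_paired, nxt.n_paired),
                )
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    merged.sort(key=lambda h: (-h.score, h.target_id, h.query_interval))
    return merged


def scan_lncrna_vs_transcripts(
    lncrna: SequenceRecord,
    targets: Sequence[SequenceRecord],
    params: ScanParameters = ScanParameters(),
) -> list[DuplexHit]:
    """Snippet-scan a lncRNA against mRNA transcripts.

    Each snippet is duplex-aligned against each target; hits passing the
    mRNA score and energy thresholds are back-mapped to full lncRNA
    coordinates, and overlapping hits on the same target are merged.
    """
    if not targets:
        logger.warning("empty target list; nothing to scan")
        return []
    passing: list[DuplexHit] = []
    for (offset, _end), snippet_seq in split_snippets(lncrna, params):
        snippet = SequenceRecord(lncrna.id, snippet_seq, "RNA")
        for target in targets:
            for hit in duplex_align(
                snippet, target, params, min_score=params.score_threshold_mrna
            ):
                if (
                    hit.score >= params.score_threshold_mrna
                    and hit.energy_kcal <= params.energy_threshold_kcal
                ):
                    passing.append(
                        replace(
                            hit,
                            query_interval=(
                                hit.query_interval[0] + offset,
                                hit.query_interval[1] + offset,
                            ),
                        )
                    )
    return _merge_hits(passing)


def scan_mirnas_vs_lncrna(
    mirnas: Sequence[SequenceRecord],
    lncrna: SequenceRecord,
    params: ScanParameters = ScanParameters(),
) -> list[DuplexHit]:
    """Duplex-align each miRNA against the whole lncRNA.

    Short queries need no snippeting. Hits must reach the miRNA score
    threshold; no energy filter is applied here.
    """
    hits: list[DuplexHit] = []
    for mirna in mirnas:
        if len(mirna.seq) > 30:
            raise ValueError(f"miRNA {mirna.id!r} longer than 30 nt")
        hits.extend(
            h
            for h in duplex_align(mirna, lncrna, params, min_score=params.score_threshold_mirna)
            if h.score >= params.score_threshold_mirna
        )
    hits.sort(key=lambda h: (-h.score, h.query_id, h.target_interval))
    return hits


@dataclass(frozen=True)
class CatRapidFilterParams:
    """Confidence cut-offs for external protein-interaction predictions."""

    min_star_rating: float = 2.5
    min_discriminative_power_pct: float = 75.0


def filter_protein_predictions(
    table: pd.DataFrame,
    params: CatRapidFilterParams = CatRapidFilterParams(),
    lncrna_id: str = "query",
) -> list[InteractionRecord]:
    """Keep high-confidence protein predictions: star rating >= 2.5 and
    discriminative power strictly > 75%."""
    required = {"protein_id", "star_rating", "discriminative_power_pct"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"protein prediction table missing column(s): {sorted(missing)}")
    kept = table[
        (table["star_rating"] >= params.min_star_rating)
        & (table["discriminative_power_pct"] > params.min_discriminative_power_pct)
    ]
    return [
        InteractionRecord(
            source_id=lncrna_id,
            target_id=str(row.protein_id),
            target_type="protein",
            evidence="predicted",
            provenance="protein-prediction-filter",
        )
        for row in kept.itertuples()
    ]


def hits_to_frame(hits: Iterable[DuplexHit]) -> pd.DataFrame:
    rows = [
        {
            "query_id": h.query_id,
            "target_id": h.target_id,
            "query_start": h.query_interval[0],
            "query_end": h.query_interval[1],
            "target_start": h.target_interval[0],
            "target_end": h.target_interval[1],
            "score": h.score,
            "energy_kcal": h.energy_kcal,
            "n_paired": h.n_paired,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "target_id",
            "query_start",
            "query_end",
            "target_start",
            "target_end",
            "score",
            "energy_kcal",
            "n_paired",
        ],
    )


def write_hits(hits: Iterable[DuplexHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def write_hits_bed(hits: Iterable[DuplexHit], path: str | Path) -> None:
    """Target intervals as BED (target as chrom, score column rounded)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.target_id}\t{h.target_interval[0]}\t{h.target_interval[1]}\t"
                f"{h.query_id}\t{int(round(h.score))}\t+\n"
            )
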