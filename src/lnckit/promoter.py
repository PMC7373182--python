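"""Promoter extraction and position-weight-matrix TFBS scanning.

The promoter of a gene is the strand-aware window from -2000 to +500 bp
around the transcription start site. PWM scanning scores every window of a
matrix's width on both strands with log-odds scores against a background
distribution (uniform by default, pseudocount 0.01), and converts each
window score S into a matrix dissimilarity

    100 * (S_max - S) / (S_max - S_min)

where S_max / S_min are the best and worst attainable scores of the matrix.
At the default 0% maximum dissimilarity only windows achieving the matrix's
maximum score are reported — the consensus-match regime that minimises
false positives. The dissimilarity is invariant to affine rescaling of the
log-odds scores, so matrices from different sources are comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ioformats import GeneRecord, InteractionRecord, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class PromoterParameters:
    upstream_bp: int = 2000
    downstream_bp: int = 500
    max_dissimilarity_pct: float = 0.0
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("promoter extents must be >= 0")
        if not 0 <= self.max_dissimilarity_pct <= 100:
            raise ValueError("max_dissimilarity_pct must be in [0, 100]")


@dataclass(frozen=True)
class PromoterSequence:
    """An extracted promoter with its genomic provenance."""

    record: SequenceRecord
    gene_id: str
    chrom: str
    strand: str
    genomic_interval: tuple[int, int]  # 0-based half-open, forward strand
    truncated: bool


@dataclass(frozen=True)
class PWM:
    """A TF binding motif as per-position log-odds scores.

    Built either from a count/frequency matrix (against a background, with
    pseudocounts) or directly from log-odds scores.
    """

    tf_name: str
    log_odds: np.ndarray  # (width, 4) over A,C,G,T

    def __post_init__(self) -> None:
        object.__setattr__(self, "log_odds", np.asarray(self.log_odds, dtype=float))
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 4:
            raise ValueError("log_odds must be (width, 4)")

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def s_max(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def s_min(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def consensus(self) -> str:
        """Highest-scoring base per column (first of tied maxima)."""
        return "".join(_BASES[i] for i in self.log_odds.argmax(axis=1))

    @classmethod
    def from_counts(
        cls,
        tf_name: str,
        counts: np.ndarray,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        pseudocount: float = 0.01,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be (width, 4) over A,C,G,T")
        if counts.shape[0] < 4:
            raise ValueError("PWM width must be >= 4")
        totals = counts.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError(f"PWM {tf_name!r}: every column must have a positive total")
        freq = (counts + pseudocount) / (totals + 4 * pseudocount)[:, None]
        bg = np.asarray(background, dtype=float)
        return cls(tf_name, np.log2(freq / bg[None, :]))


@dataclass(frozen=True)
class TFBSHit:
    tf_name: str
    promoter_id: str
    offset: int  # 0-based leftmost position on the forward promoter sequence
    strand: str  # + | -
    score: float
    dissimilarity_pct: float


def extract_promoter(
    gene: GeneRecord,
    genome: Mapping[str, SequenceRecord],
    params: PromoterParameters = PromoterParameters(),
) -> PromoterSequence:
    """Extract the strand-aware promoter window around the TSS.

    Plus strand: genomic [tss - upstream, tss + downstream) as-is; minus
    strand: genomic [tss - downstream + 1, tss + upstream + 1) reverse-
    complemented, so the returned sequence always reads 5'->3' from -2000
    to +500 relative to transcription. Windows crossing a chromosome end
    are truncated and flagged.
    """
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} not in genome")
    chrom_seq = genome[gene.chrom].seq
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss - params.upstream_bp, tss + params.downstream_bp
    else:
        lo, hi = tss - params.downstream_bp + 1, tss + params.upstream_bp + 1
    clipped_lo, clipped_hi = max(0, lo), min(len(chrom_seq), hi)
    if clipped_hi <= clipped_lo:
        raise ValueError(
            f"promoter of {gene.gene_id!r} lies entirely outside chromosome {gene.chrom!r}"
        )
    truncated = (clipped_lo, clipped_hi) != (lo, hi)
    seq = chrom_seq[clipped_lo:clipped_hi]
    if gene.strand == "-":
        seq = reverse_complement(seq, "DNA")
    return PromoterSequence(
        record=SequenceRecord(f"{gene.gene_id}|promoter", seq, "DNA"),
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        genomic_interval=(clipped_lo, clipped_hi),
        truncated=truncated,
    )


def _window_scores(seq: str, pwm: PWM) -> np.ndarray:
    """Log-odds score of every window; N bases contribute the column minimum."""
    w = pwm.width
    n = len(seq)
    col_min = pwm.log_odds.min(axis=1)
    per_pos = np.empty((n, w))
    for j in range(w):
        col = pwm.log_odds[j]
        per_pos[:, j] = [col[_BASE_INDEX[c]] if c in _BASE_INDEX else col_min[j] for c in seq]
    # score of window at offset i = sum_j per_pos[i + j, j]
    scores = np.zeros(n - w + 1)
    for j in range(w):
        scores += per_pos[j : n - w + 1 + j, j]
    return scores


def scan_pwm(
    promoter: SequenceRecord | PromoterSequence,
    pwms: Sequence[PWM],
    params: PromoterParameters = PromoterParameters(),
) -> list[TFBSHit]:
    """Scan a promoter with PWMs and report hits at or below the maximum
    matrix dissimilarity, on both strands by default.

    Offsets are 0-based leftmost positions on the forward promoter
    sequence for both strands. PWMs wider than the promoter are skipped
    with a warning.
    """
    record = promoter.record if isinstance(promoter, PromoterSequence) else promoter
    seq = record.seq
    hits: list[TFBSHit] = []
    for pwm in pwms:
        if pwm.width > len(seq):
            logger.warning(
                "PWM %s (width %d) wider than promoter %s; skipped",
                pwm.tf_name,
                pwm.width,
                record.id,
            )
            continue
        span = pwm.s_max - pwm.s_min
        strands = [("+", seq)]
        if params.scan_both_strands:
            strands.append(("-", reverse_complement(seq, "DNA")))
        for strand, scan_seq in strands:
            scores = _window_scores(scan_seq, pwm)
            for i, s in enumerate(scores):
                dissim = 0.0 if span == 0 else 100.0 * (pwm.s_max - s) / span
                if dissim <= params.max_dissimilarity_pct + 1e-9:
                    offset = i if strand == "+" else len(seq) - pwm.width - i
                    hits.append(
                        TFBSHit(
                            tf_name=pwm.tf_name,
                            promoter_id=record.id,
                            offset=offset,
                            strand=strand,
                            score=float(s),
                            dissimilarity_pct=float(max(0.0, dissim)),
                        )
                    )
    hits.sort(key=lambda h: (h.dissimilarity_pct, h.tf_name, h.offset, h.strand))
    return hits


def combine_tf_with_interactors(
    hits: Sequence[TFBSHit],
    protein_interactors: Sequence[InteractionRecord],
) -> pd.DataFrame:
    """Outer join of promoter-binding TFs with protein interaction partners.

    Rows flagged in both columns (a TF that binds the promoter AND
    interacts with the lncRNA) are the top regulatory candidates.
    """
    tf_names = {h.tf_name for h in hits}
    interactor_names = {r.target_id for r in protein_interactors}
    rows = []
    for name in sorted(tf_names | interactor_names):
        has_site = name in tf_names
        is_interactor = name in interactor_names
        rows.append(
            {
                "tf_name": name,
                "has_binding_site": has_site,
                "is_interactor": is_interactor,
                "top_candidate": has_site and is_interactor,
            }
        )
    return pd.DataFrame(
        rows, columns=["tf_name", "has_binding_site", "is_interactor", "top_candidate"]
    )


# ---------------------------------------------------------------------------
# JASPAR-style PWM text I/O
#
#   >MA0001.1 TFNAME
#   A  [ 4 19  0  0 ]
#   C  [16  0 20  0 ]
#   G  [ 0  1  0 20 ]
#   T  [ 0  0  0  0 ]


def read_pwms(path: str | Path, background=(0.25, 0.25, 0.25, 0.25)) -> list[PWM]:
    """Read JASPAR-style count matrices and convert to log-odds PWMs."""
    pwms = []
    name = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh] + [">"]
    for line in lines:
        if line.startswith(">"):
            if name is not None:
                if set(rows) != set(_BASES):
                    raise ValueError(f"PWM {name!r}: need one row per base A,C,G,T")
                counts = np.array([rows[b] for b in _BASES]).T
                pwms.append(PWM.from_counts(name, counts, background=background))
            parts = line[1:].split()
            name = parts[-1] if parts else None
            rows = {}
        elif line.strip():
            base, rest = line.split(None, 1)
            values = rest.replace("[", " ").replace("]", " ").split()
            rows[base.upper()] = [float(v) for v in values]
    return pwms


def write_pwm_counts(pwms_counts: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, counts in pwms_counts.items():
            fh.write(f">{name} {name}\n")
            counts = np.asarray(counts)
            for i, base in enumerate(_BASES):
                values = " ".join(str(int(v)) for v in counts[:, i])
                fh.write(f"{base} [ {values} ]\n")


def hits_to_frame(hits: Sequence[TFBSHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [h.__dict__ for h in hits],
        columns=["tf_name", "promoter_id", "offset", "strand", "score", "dissimilarity_pct"],
    )
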