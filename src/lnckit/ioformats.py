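"""Readers and writers for the external formats the pipeline touches.

All genomic intervals are 0-based half-open internally; GTF input (1-based
inclusive) is converted at the boundary and converted back on export. RNA
sequences use U internally, DNA uses T; both letters are accepted on input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA_ALPHABET = set("ACGTN")
_RNA_ALPHABET = set("ACGUN")

#: gene_type attribute values mapped onto the internal biotype vocabulary
BIOTYPE_ALIASES: dict[str, str] = {
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "antisense_RNA": "lncRNA",
    "processed_transcript": "lncRNA",
    "protein_coding": "mRNA",
    "mRNA": "mRNA",
    "miRNA": "miRNA",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A validated nucleotide sequence (DNA over ACGTN, RNA over ACGUN)."""

    id: str
    seq: str
    moltype: str  # "DNA" | "RNA"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")
        if self.moltype not in ("DNA", "RNA"):
            raise FormatError(f"moltype must be DNA or RNA, got {self.moltype!r}")
        alphabet = _DNA_ALPHABET if self.moltype == "DNA" else _RNA_ALPHABET
        for pos, ch in enumerate(self.seq):
            if ch not in alphabet:
                raise FormatError(
                    f"illegal character {ch!r} at position {pos} in record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_seq(raw: str, moltype: str) -> str:
    """Upper-case and convert between T and U for the declared moltype."""
    s = raw.upper()
    return s.replace("U", "T") if moltype == "DNA" else s.replace("T", "U")


_COMPLEMENT_DNA = str.maketrans("ACGTN", "TGCAN")
_COMPLEMENT_RNA = str.maketrans("ACGUN", "UGCAN")


def reverse_complement(seq: str, moltype: str = "DNA") -> str:
    table = _COMPLEMENT_DNA if moltype == "DNA" else _COMPLEMENT_RNA
    return seq.translate(table)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """A gene on the genome with its strand-aware transcription start site."""

    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    start: int  # 0-based half-open
    end: int
    biotype: str  # lncRNA | mRNA | miRNA | other

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be + or -")

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class BlastTabRow:
    """One row of BLAST tabular output (outfmt 6, 12 columns)."""

    query_id: str
    subject_id: str
    identity_pct: float
    align_len: int
    mismatches: int
    gaps: int
    q_start: int  # 1-based inclusive, as in the format
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise FormatError(f"identity_pct {self.identity_pct} outside [0, 100]")
        if self.evalue < 0:
            raise FormatError(f"negative e-value {self.evalue}")
        for name in ("align_len", "mismatches", "gaps"):
            if getattr(self, name) < 0:
                raise FormatError(f"negative {name}")


@dataclass(frozen=True)
class InteractionRecord:
    """A molecular interaction from a database export or a prediction."""

    source_id: str
    target_id: str
    target_type: str  # mRNA | miRNA | protein
    evidence: str  # validated | predicted
    provenance: str = ""
    source_type: str = "lncRNA"

    def __post_init__(self) -> None:
        if self.source_id == self.target_id:
            raise FormatError(f"self-interaction on {self.source_id!r}")
        if self.target_type not in ("mRNA", "miRNA", "protein", "lncRNA", "TF"):
            raise FormatError(f"unknown target_type {self.target_type!r}")
        if self.evidence not in ("validated", "predicted"):
            raise FormatError(f"evidence must be validated or predicted")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, moltype: str) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    T/U are normalized to the declared moltype; duplicate ids and characters
    outside the alphabet are hard errors. An empty file yields an empty list
    with a logged warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, normalize_seq(str(rec.seq), moltype), moltype))
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF gene model

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def map_biotype(gene_type: str) -> str:
    return BIOTYPE_ALIASES.get(gene_type, "other")


def read_gene_model(path: str | Path) -> list[GeneRecord]:
    """Read gene-level lines from a GTF file.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Lines without a gene_id attribute are skipped with a warning; an interval
    with end < start is a hard error.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start1, end1, _score, strand, _frame, attrs = fields[:9]
            if feature != "gene":
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            if "gene_id" not in attr:
                logger.warning("%s:%d: gene line without gene_id skipped", path, lineno)
                continue
            start1i, end1i = int(start1), int(end1)
            if end1i < start1i:
                raise FormatError(f"{path}:{lineno}: end < start")
            genes.append(
                GeneRecord(
                    gene_id=attr["gene_id"],
                    chrom=chrom,
                    strand=strand,
                    start=start1i - 1,
                    end=end1i,
                    biotype=map_biotype(attr.get("gene_type", "other")),
                )
            )
    return genes


_BIOTYPE_EXPORT = {"lncRNA": "lncRNA", "mRNA": "protein_coding", "miRNA": "miRNA", "other": "other"}


def write_gene_model(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene-level GTF lines, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{_BIOTYPE_EXPORT[g.biotype]}";'
            fh.write(
                f"{g.chrom}\tlnckit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular


def read_blast_tab(path: str | Path) -> list[BlastTabRow]:
    """Parse 12-column BLAST tabular output (outfmt 6)."""
    rows: list[BlastTabRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                rows.append(
                    BlastTabRow(
                        query_id=parts[0],
                        subject_id=parts[1],
                        identity_pct=float(parts[2]),
                        align_len=int(parts[3]),
                        mismatches=int(parts[4]),
                        gaps=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return rows


# ---------------------------------------------------------------------------
# Interaction / term / catRAPID tables (simple TSVs with headers)


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read a TSV of interactions: source, target, target_type, evidence, provenance."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("source_id", "target_id", "target_type", "evidence"):
            if col not in idx:
                raise FormatError(f"{path}: missing column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            records.append(
                InteractionRecord(
                    source_id=p[idx["source_id"]],
                    target_id=p[idx["target_id"]],
                    target_type=p[idx["target_type"]],
                    evidence=p[idx["evidence"]],
                    provenance=p[idx["provenance"]] if "provenance" in idx else "",
                    source_type=p[idx["source_type"]] if "source_type" in idx else "lncRNA",
                )
            )
    return records


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source_id\ttarget_id\ttarget_type\tevidence\tprovenance\tsource_type\n")
        for r in records:
            fh.write(
                f"{r.source_id}\t{r.target_id}\t{r.target_type}\t{r.evidence}\t"
                f"{r.provenance}\t{r.source_type}\n"
            )


def read_mirna_targets(path: str | Path) -> dict[str, set[str]]:
    """Read a validated miRNA-target TSV (mirna_id, mrna_id) into a mapping."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["mirna_id", "mrna_id"]:
            raise FormatError(f"{path}: expected columns mirna_id, mrna_id")
        for line in fh:
            if not line.strip():
                continue
            mirna, mrna = line.rstrip("\n").split("\t")[:2]
            table.setdefault(mirna, set()).add(mrna)
    return table


# ---------------------------------------------------------------------------
# GML network export / import


def write_gml(network: "nx.Graph", path: str | Path) -> None:
    """Export a knowledge network as a Cytoscape-compatible GML file.

    Node attributes: label, moltype, de_flag (0/1), log2fc; edge attributes:
    evidence and provenance (semicolon-joined). Re-reading with
    :func:`read_gml` yields an isomorphic, attribute-equal graph.
    """
    out = nx.Graph()
    for node, data in network.nodes(data=True):
        out.add_node(
            node,
            label=str(data.get("label", node)),
            moltype=str(data.get("moltype", "other")),
            de_flag=int(bool(data.get("de_flag", False))),
            log2fc=float(data.get("log2fc", 0.0)),
        )
    for u, v, data in network.edges(data=True):
        ev = data.get("evidence", set())
        prov = data.get("provenance", set())
        out.add_edge(
            u,
            v,
            evidence=";".join(sorted(ev)) if isinstance(ev, (set, frozenset)) else str(ev),
            provenance=";".join(sorted(prov)) if isinstance(prov, (set, frozenset)) else str(prov),
        )
    nx.write_gml(out, str(path))


def read_gml(path: str | Path) -> "nx.Graph":
    """Read a GML network back, restoring set-valued edge attributes."""
    g = nx.read_gml(str(path), label="label")
    out = nx.Graph()
    for node, data in g.nodes(data=True):
        out.add_node(
            node,
            label=data.get("label", str(node)),
            moltype=data.get("moltype", "other"),
            de_flag=bool(data.get("de_flag", 0)),
            log2fc=float(data.get("log2fc", 0.0)),
        )
    for u, v, data in g.edges(data=True):
        out.add_edge(
            u,
            v,
            evidence=set(filter(None, str(data.get("evidence", "")).split(";"))),
            provenance=set(filter(None, str(data.get("provenance", "")).split(";"))),
        )
    return out
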