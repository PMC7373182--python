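"""Seeded synthetic-data generator with planted ground truth.

Every input the pipeline consumes can be generated here: a negative-
binomial count matrix with planted fold changes (7 vs 7 samples, 10% of
genes at |log2FC| = 2, dispersion 0.1 — a small two-group RNA-Seq design),
a random genome with a non-overlapping gene model, transcript and miRNA
sequences, interaction and miRNA-target tables, PWMs and term-gene tables.

A designated lncRNA carries planted signals that thread through the whole
protocol: a >=40-nt complementary site for one mRNA (with ~10% G:U wobble
substitutions), near-perfect complementary sites for two miRNAs, a
validated-target table in which those miRNAs target that same mRNA, a
planted up-regulation of that mRNA in the counts, and a TF consensus
planted in the lncRNA promoter. Running the pipeline on these fixtures
must recover the planted mRNA as the triple-evidence candidate.

Everything is a pure function of the seed; the same seed reproduces every
output byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .ioformats import (
    GeneRecord,
    InteractionRecord,
    SequenceRecord,
    reverse_complement,
    write_fasta,
    write_gene_model,
    write_interactions,
)
from .promoter import write_pwm_counts

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the generator; the seed determines every output byte."""

    seed: int = 0
    n_genes: int = 2000
    n_samples_per_group: int = 7
    de_fraction: float = 0.10
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    baseline_mean_range: tuple[float, float] = (20.0, 2000.0)
    n_chroms: int = 1
    chrom_len: int = 200_000
    n_mrna_genes: int = 20
    n_mirna_genes: int = 4
    lncrna_len: int = 1200
    mrna_len_range: tuple[int, int] = (600, 1500)
    mirna_len: int = 26
    duplex_site_len: int = 50
    wobble_fraction: float = 0.10
    n_planted_mirnas: int = 2
    tfbs_consensus_len: int = 10
    tfbs_promoter_offset: int = 300  # promoter-relative, 0 = -2000 bp

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.duplex_site_len < 40:
            raise ValueError("planted duplex site must be >= 40 nt")
        if self.n_planted_mirnas < 2:
            raise ValueError("need >= 2 planted miRNAs for the sponge triangle")


@dataclass
class FixtureBundle:
    """Everything one simulated study produces, plus the planted truth."""

    spec: FixtureSpec
    counts: CountMatrix
    genome: dict[str, SequenceRecord]
    genes: list[GeneRecord]
    lncrna: SequenceRecord  # RNA, with planted sites
    mirnas: list[SequenceRecord]
    transcripts: list[SequenceRecord]  # mRNA transcripts (RNA)
    validated_interactions: list[InteractionRecord]
    mirna_targets: dict[str, set[str]]
    protein_predictions: pd.DataFrame
    pwm_counts: dict[str, np.ndarray]
    terms: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_tsv(outdir / "counts.tsv", outdir / "conditions.tsv")
        write_fasta(self.genome.values(), outdir / "genome.fa")
        write_gene_model(self.genes, outdir / "genes.gtf")
        write_fasta([self.lncrna], outdir / "lncrna.fa")
        write_fasta(self.mirnas, outdir / "mirnas.fa")
        write_fasta(self.transcripts, outdir / "transcripts.fa")
        write_interactions(self.validated_interactions, outdir / "interactions.tsv")
        with open(outdir / "mirna_targets.tsv", "w") as fh:
            fh.write("mirna_id\tmrna_id\n")
            for mirna in sorted(self.mirna_targets):
                for mrna in sorted(self.mirna_targets[mirna]):
                    fh.write(f"{mirna}\t{mrna}\n")
        self.protein_predictions.to_csv(outdir / "protein_predictions.tsv", sep="\t", index=False)
        write_pwm_counts(self.pwm_counts, outdir / "pwms.txt")
        self.terms.to_csv(outdir / "terms.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])


def _rna_complement_site(segment: str) -> str:
    """Antiparallel complement: the subsequence a query needs to pair the
    segment 5'->3' against 3'->5'."""
    return "".join(_RNA_COMPLEMENT[c] for c in reversed(segment))


def _apply_wobble(site: str, rng: np.random.Generator, fraction: float, max_n: int | None = None) -> str:
    """Convert a fraction of positions to G:U wobble where chemistry allows
    (A->G pairs a U as G:U; C->U pairs a G as G:U)."""
    chars = list(site)
    candidates = [i for i, c in enumerate(chars) if c in "AC"]
    n = int(round(fraction * len(chars)))
    if max_n is not None:
        n = min(n, max_n)
    for i in rng.permutation(candidates)[:n]:
        chars[i] = "G" if chars[i] == "A" else "U"
    return "".join(chars)


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    spec: FixtureSpec,
    gene_ids: list[str] | None = None,
    forced_up: set[str] = frozenset(),
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts with planted fold changes.

    Variance follows mu + dispersion * mu^2. A ``de_fraction`` of genes gets
    the case-group mean multiplied by 2**(+-planted_log2fc); genes in
    ``forced_up`` are always planted with positive sign. Returns the matrix
    and a truth table (gene_id, direction, log2fc).
    """
    rng = _rng(spec, 1)
    n = spec.n_genes
    if gene_ids is None:
        gene_ids = [f"GENE{i + 1:05d}" for i in range(n)]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length must equal n_genes")
    id_index = {g: i for i, g in enumerate(gene_ids)}
    for g in forced_up:
        if g not in id_index:
            raise ValueError(f"forced_up gene {g!r} not among gene ids")

    lo, hi = spec.baseline_mean_range
    base_mu = np.exp(rng.uniform(np.log(lo), np.log(hi), n))

    n_de = int(round(spec.de_fraction * n))
    planted_idx: list[int] = sorted(id_index[g] for g in forced_up)
    pool = np.array([i for i in range(n) if i not in set(planted_idx)])
    extra = rng.choice(pool, size=max(0, n_de - len(planted_idx)), replace=False)
    planted = np.zeros(n, dtype=bool)
    planted[planted_idx] = True
    planted[extra] = True
    signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    signs[planted_idx] = 1.0

    n_per = spec.n_samples_per_group
    mu = np.tile(base_mu[:, None], (1, 2 * n_per))
    fc = 2.0 ** (spec.planted_log2fc * signs)
    mu[planted, n_per:] *= fc[planted, None]

    disp = spec.nb_dispersion
    if disp > 0:
        size = 1.0 / disp
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mu)

    sample_ids = [f"ctrl{i + 1}" for i in range(n_per)] + [f"case{i + 1}" for i in range(n_per)]
    condition = ["control"] * n_per + ["disease"] * n_per
    cm = CountMatrix(list(gene_ids), sample_ids, counts.astype(np.int64), condition)
    truth = pd.DataFrame(
        {
            "gene_id": [gene_ids[i] for i in np.flatnonzero(planted)],
            "log2fc": [spec.planted_log2fc * signs[i] for i in np.flatnonzero(planted)],
        }
    )
    return cm, truth


# ---------------------------------------------------------------------------
# genome and gene model


def simulate_genome_and_genes(
    spec: FixtureSpec,
) -> tuple[dict[str, SequenceRecord], list[GeneRecord]]:
    """Random genome with non-overlapping genes on both strands.

    One designated lncRNA (the first gene, plus strand, with 2600 bp of
    clear upstream promoter space), ``n_mrna_genes`` mRNA genes and
    ``n_mirna_genes`` miRNA genes are placed sequentially with random gaps;
    raises when the requested genes cannot fit.
    """
    rng = _rng(spec, 2)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    genome = {
        name: _random_seq(rng, spec.chrom_len) for name in chrom_names
    }

    lengths = [spec.lncrna_len]
    ids = ["LNC0001"]
    biotypes = ["lncRNA"]
    for i in range(spec.n_mrna_genes):
        lengths.append(int(rng.integers(*spec.mrna_len_range)))
        ids.append(f"MRNA{i + 1:04d}")
        biotypes.append("mRNA")
    for i in range(spec.n_mirna_genes):
        lengths.append(spec.mirna_len)
        ids.append(f"MIR{i + 1:04d}")
        biotypes.append("miRNA")

    promoter_reserve = 2600  # clear upstream space for the designated lncRNA
    min_gap, max_gap = 200, 800
    per_chrom: dict[str, list[tuple[str, int, str]]] = {c: [] for c in chrom_names}
    chrom_iter = 0
    for gid, length, biotype in zip(ids, lengths, biotypes):
        per_chrom[chrom_names[chrom_iter % spec.n_chroms]].append((gid, length, biotype))
        chrom_iter += 1

    genes: list[GeneRecord] = []
    for chrom in chrom_names:
        cursor = promoter_reserve
        for gid, length, biotype in per_chrom[chrom]:
            gap = int(rng.integers(min_gap, max_gap))
            start = cursor + (0 if gid == "LNC0001" else gap)
            end = start + length
            if end + promoter_reserve > spec.chrom_len:
                raise ValueError(
                    f"gene placement failed on {chrom}: increase chrom_len "
                    f"(need > {end + promoter_reserve})"
                )
            strand = "+" if gid == "LNC0001" else ("+" if rng.random() < 0.5 else "-")
            genes.append(GeneRecord(gid, chrom, strand, start, end, biotype))
            # only the designated lncRNA needs guaranteed clear promoter space;
            # other genes pack with small gaps (gene bodies never overlap)
            cursor = end + (promoter_reserve if gid == "LNC0001" else 0)
    # guarantee both strands appear
    if all(g.strand == "+" for g in genes) and len(genes) > 1:
        g = genes[-1]
        genes[-1] = GeneRecord(g.gene_id, g.chrom, "-", g.start, g.end, g.biotype)
    for name in chrom_names:
        genome[name] = SequenceRecord(name, genome[name], "DNA")
    return genome, genes


def _stamp(genome: dict[str, SequenceRecord], gene: GeneRecord, rna_seq: str) -> None:
    """Write a transcript sequence into the genome at its locus, strand-aware."""
    dna = rna_seq.replace("U", "T")
    if gene.strand == "-":
        dna = reverse_complement(dna, "DNA")
    chrom = genome[gene.chrom]
    new = chrom.seq[: gene.start] + dna + chrom.seq[gene.end :]
    genome[gene.chrom] = SequenceRecord(chrom.id, new, "DNA")


def transcript_of(gene: GeneRecord, genome: dict[str, SequenceRecord]) -> SequenceRecord:
    """Transcript sequence (RNA, 5'->3') of a gene from the genome."""
    dna = genome[gene.chrom].seq[gene.start : gene.end]
    if gene.strand == "-":
        dna = reverse_complement(dna, "DNA")
    return SequenceRecord(gene.gene_id, dna.replace("T", "U"), "RNA")


# ---------------------------------------------------------------------------
# planted interactions


def plant_interactions(
    spec: FixtureSpec,
    genome: dict[str, SequenceRecord],
    genes: list[GeneRecord],
) -> dict:
    """Plant the full evidence cascade into genome and tables (in place).

    Returns a dict with the designed sequences, tables and truth. The
    planted mRNA (MRNA0001) ends up as: predicted direct duplex partner of
    the lncRNA, validated target of both planted miRNAs, and (once counts
    are simulated with it forced up) significantly deregulated — the
    triple-evidence pattern.
    """
    rng = _rng(spec, 3)
    by_id = {g.gene_id: g for g in genes}
    lnc_gene = by_id["LNC0001"]
    target_gene = by_id["MRNA0001"]

    # design miRNAs (random RNA); first n_planted get complement sites
    mirna_ids = [g.gene_id for g in genes if g.biotype == "miRNA"]
    mirna_seqs = {
        mid: _random_seq(rng, spec.mirna_len, "ACGU") for mid in mirna_ids
    }
    for mid, seq in mirna_seqs.items():
        _stamp(genome, by_id[mid], seq)

    # design the lncRNA: random backbone + planted complement sites
    target_rna = transcript_of(target_gene, genome)
    site_pos_in_target = int(
        rng.integers(50, len(target_rna.seq) - spec.duplex_site_len - 50)
    )
    target_segment = target_rna.seq[
        site_pos_in_target : site_pos_in_target + spec.duplex_site_len
    ]
    mrna_site = _apply_wobble(
        _rna_complement_site(target_segment), rng, spec.wobble_fraction
    )
    planted_mirnas = mirna_ids[: spec.n_planted_mirnas]
    mirna_sites = {
        mid: _apply_wobble(_rna_complement_site(mirna_seqs[mid]), rng, spec.wobble_fraction, max_n=1)
        for mid in planted_mirnas
    }

    backbone = _random_seq(rng, spec.lncrna_len, "ACGU")
    lnc = list(backbone)
    mrna_site_offset = 200
    lnc[mrna_site_offset : mrna_site_offset + len(mrna_site)] = mrna_site
    mirna_offsets = {}
    cursor = mrna_site_offset + len(mrna_site) + 100
    for mid in planted_mirnas:
        site = mirna_sites[mid]
        lnc[cursor : cursor + len(site)] = site
        mirna_offsets[mid] = cursor
        cursor += len(site) + 60
    lnc_seq = "".join(lnc)
    _stamp(genome, lnc_gene, lnc_seq)

    # plant a TF consensus in the lncRNA promoter (plus strand gene:
    # promoter-relative offset o sits at genomic tss - 2000 + o)
    consensus = _random_seq(rng, spec.tfbs_consensus_len, "ACGT")
    tss = lnc_gene.tss
    genomic_pos = tss - 2000 + spec.tfbs_promoter_offset
    chrom = genome[lnc_gene.chrom]
    genome[lnc_gene.chrom] = SequenceRecord(
        chrom.id,
        chrom.seq[:genomic_pos] + consensus + chrom.seq[genomic_pos + len(consensus) :],
        "DNA",
    )

    # PWMs: the planted TF has a strictly dominant count matrix spelling the
    # consensus; two decoy motifs are random-dominant
    pwm_counts: dict[str, np.ndarray] = {}
    base_index = {b: i for i, b in enumerate("ACGT")}

    def dominant_matrix(motif: str) -> np.ndarray:
        counts = np.full((len(motif), 4), 1.0)
        for i, b in enumerate(motif):
            counts[i, base_index[b]] = 18.0
        return counts

    pwm_counts["TFA"] = dominant_matrix(consensus)
    for decoy in ("TFB", "TFC"):
        pwm_counts[decoy] = dominant_matrix(_random_seq(rng, spec.tfbs_consensus_len, "ACGT"))

    # validated interaction and miRNA-target tables
    mrna_ids = [g.gene_id for g in genes if g.biotype == "mRNA"]
    mirna_targets: dict[str, set[str]] = {mid: set() for mid in mirna_ids}
    for mid in planted_mirnas:
        mirna_targets[mid].add(target_gene.gene_id)
        mirna_targets[mid].add(str(rng.choice(mrna_ids[1:])))
    for mid in mirna_ids[spec.n_planted_mirnas :]:
        mirna_targets[mid] = set(rng.choice(mrna_ids[1:], size=2, replace=False))

    validated = [
        InteractionRecord("LNC0001", "TFA", "protein", "validated", "protein-db"),
        InteractionRecord("LNC0001", "PROT_X1", "protein", "validated", "protein-db"),
        InteractionRecord("LNC0001", str(rng.choice(mrna_ids[1:])), "mRNA", "validated", "rna-db"),
    ]

    protein_predictions = pd.DataFrame(
        {
            "protein_id": ["TFA", "PROT_X1", "PROT_X2", "PROT_X3"],
            "star_rating": [3.0, 2.8, 2.0, 2.6],
            "discriminative_power_pct": [85.0, 90.0, 95.0, 60.0],
        }
    )

    truth = {
        "lncrna_id": "LNC0001",
        "target_mrna_id": target_gene.gene_id,
        "mrna_site_lnc_interval": [mrna_site_offset, mrna_site_offset + len(mrna_site)],
        "mrna_site_target_interval": [
            site_pos_in_target,
            site_pos_in_target + spec.duplex_site_len,
        ],
        "planted_mirnas": planted_mirnas,
        "mirna_site_offsets": mirna_offsets,
        "tfbs_tf": "TFA",
        "tfbs_consensus": consensus,
        "tfbs_promoter_offset": spec.tfbs_promoter_offset,
    }
    return {
        "lncrna": SequenceRecord("LNC0001", lnc_seq, "RNA"),
        "mirnas": [SequenceRecord(mid, mirna_seqs[mid], "RNA") for mid in mirna_ids],
        "mirna_targets": mirna_targets,
        "validated_interactions": validated,
        "protein_predictions": protein_predictions,
        "pwm_counts": pwm_counts,
        "truth": truth,
    }


def _make_terms(
    spec: FixtureSpec, gene_ids: list[str], de_truth: pd.DataFrame, target_mrna: str
) -> pd.DataFrame:
    """Term-gene table with one cardiac-like term enriched in planted DE
    genes (always containing the planted target mRNA) plus random terms."""
    rng = _rng(spec, 4)
    rows = []
    de_genes = list(de_truth["gene_id"])
    enriched = set(rng.choice(de_genes, size=min(12, len(de_genes)), replace=False))
    enriched.add(target_mrna)
    for g in sorted(enriched):
        rows.append(("TERM_CARDIO", "cardiac remodeling (synthetic)", "pathway-db", g))
    for t in range(1, 9):
        members = rng.choice(gene_ids, size=15, replace=False)
        for g in sorted(members):
            rows.append((f"TERM_{t:03d}", f"synthetic term {t}", "pathway-db", g))
    return pd.DataFrame(rows, columns=["term_id", "term_name", "source", "gene_id"])


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate one complete, internally consistent simulated study."""
    genome, genes = simulate_genome_and_genes(spec)
    planted = plant_interactions(spec, genome, genes)
    target_mrna = planted["truth"]["target_mrna_id"]

    genome_gene_ids = [g.gene_id for g in genes]
    filler = [f"GENE{i + 1:05d}" for i in range(spec.n_genes - len(genome_gene_ids))]
    counts, de_truth = simulate_counts(
        spec, gene_ids=genome_gene_ids + filler, forced_up={target_mrna}
    )
    transcripts = [transcript_of(g, genome) for g in genes if g.biotype == "mRNA"]
    terms = _make_terms(spec, genome_gene_ids + filler, de_truth, target_mrna)
    truth = dict(planted["truth"])
    truth["planted_de"] = {
        row.gene_id: row.log2fc for row in de_truth.itertuples()
    }
    return FixtureBundle(
        spec=spec,
        counts=counts,
        genome=genome,
        genes=genes,
        lncrna=planted["lncrna"],
        mirnas=planted["mirnas"],
        transcripts=transcripts,
        validated_interactions=planted["validated_interactions"],
        mirna_targets=planted["mirna_targets"],
        protein_predictions=planted["protein_predictions"],
        pwm_counts=planted["pwm_counts"],
        terms=terms,
        truth=truth,
    )
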