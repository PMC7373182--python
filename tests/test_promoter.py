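import numpy as np
import pytest

from lnckit.ioformats import GeneRecord, InteractionRecord, SequenceRecord, reverse_complement
from lnckit.promoter import (
    PWM,
    PromoterParameters,
    TFBSHit,
    combine_tf_with_interactors,
    extract_promoter,
    read_pwms,
    scan_pwm,
    write_pwm_counts,
)


def _genome(seq, chrom="chr1"):
    return {chrom: SequenceRecord(chrom, seq, "DNA")}


def _random_genome(rng, n=12000):
    return _genome("".join(rng.choice(list("ACGT"), n)))


class TestExtractPromoter:
    def test_plus_strand_window(self, rng):
        genome = _random_genome(rng)
        gene = GeneRecord("g", "chr1", "+", 5000, 6000, "lncRNA")
        prom = extract_promoter(gene, genome)
        assert prom.genomic_interval == (3000, 5500)
        assert len(prom.record.seq) == 2500
        assert not prom.truncated
        assert prom.record.seq == genome["chr1"].seq[3000:5500]

    def test_minus_strand_window_reverse_complemented(self, rng):
        genome = _random_genome(rng)
        gene = GeneRecord("g", "chr1", "-", 4000, 5001, "lncRNA")  # tss = 5000
        prom = extract_promoter(gene, genome)
        assert prom.genomic_interval == (4501, 7001)
        assert len(prom.record.seq) == 2500
        assert prom.record.seq == reverse_complement(genome["chr1"].seq[4501:7001], "DNA")

    def test_truncation_at_chromosome_start(self, rng):
        genome = _random_genome(rng)
        gene = GeneRecord("g", "chr1", "+", 1000, 2000, "lncRNA")
        prom = extract_promoter(gene, genome)
        assert prom.genomic_interval == (0, 1500)
        assert len(prom.record.seq) == 1500
        assert prom.truncated

    def test_missing_chromosome_is_error(self, rng):
        gene = GeneRecord("g", "chrX", "+", 5000, 6000, "lncRNA")
        with pytest.raises(KeyError):
            extract_promoter(gene, _random_genome(rng))

    def test_promoter_outside_chromosome_is_error(self):
        genome = _genome("ACGT" * 100)
        gene = GeneRecord("g", "chr1", "-", 10, 20, "lncRNA")
        # minus-strand promoter upstream region lies beyond the chromosome end?
        # here instead: plus-strand gene with tss far beyond downstream reach
        bad = GeneRecord("g", "chr1", "+", 390, 400, "lncRNA")
        params = PromoterParameters(upstream_bp=0, downstream_bp=0)
        with pytest.raises(ValueError):
            extract_promoter(bad, genome, params)

    def test_untruncated_length_is_always_up_plus_down(self, rng):
        genome = _random_genome(rng, 20000)
        for _ in range(50):
            tss_zone = int(rng.integers(6000, 14000))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = GeneRecord("g", "chr1", strand, tss_zone, tss_zone + 500, "mRNA")
            prom = extract_promoter(gene, genome)
            assert not prom.truncated
            assert len(prom.record.seq) == 2500

    def test_strand_symmetry(self, rng):
        """Extracting a minus-strand promoter equals extracting the plus-strand
        promoter of the mirrored gene from the reverse-complemented genome."""
        n = 15000
        genome = _random_genome(rng, n)
        rc_genome = _genome(reverse_complement(genome["chr1"].seq, "DNA"))
        for _ in range(50):
            start = int(rng.integers(5000, 9000))
            end = start + int(rng.integers(100, 800))
            gene_minus = GeneRecord("g", "chr1", "-", start, end, "mRNA")
            gene_mirror = GeneRecord("g", "chr1", "+", n - end, n - start, "mRNA")
            p1 = extract_promoter(gene_minus, genome)
            p2 = extract_promoter(gene_mirror, rc_genome)
            assert p1.record.seq == p2.record.seq


def _consensus_pwm(motif="ACGT" * 2, dominant=10.0):
    counts = np.full((len(motif), 4), 1.0)
    idx = {b: i for i, b in enumerate("ACGT")}
    for i, b in enumerate(motif):
        counts[i, idx[b]] = dominant
    return PWM.from_counts("TF1", counts)


class TestScanPwm:
    def test_zero_dissimilarity_equals_consensus_match(self):
        pwm = PWM(
            "TF",
            np.array(
                [
                    [2.0, 0.0, 0.0, 0.0],
                    [0.0, 3.0, 0.0, 0.0],
                    [0.0, 0.0, 4.0, 0.0],
                    [0.0, 0.0, 0.0, 5.0],
                ]
            ),
        )
        prom = SequenceRecord("p", "TTACGTTT", "DNA")
        hits = scan_pwm(prom, [pwm], PromoterParameters(scan_both_strands=False))
        assert [(h.offset, h.strand) for h in hits] == [(2, "+")]
        assert hits[0].dissimilarity_pct == 0.0

    def test_single_non_consensus_column_rejected_at_zero(self):
        pwm = PWM("TF", np.diag([2.0, 3.0, 4.0, 5.0]))
        prom = SequenceRecord("p", "TTACCTTT", "DNA")
        assert scan_pwm(prom, [pwm], PromoterParameters(scan_both_strands=False)) == []

    def test_dissimilarity_formula_worked_example(self):
        # col1 (A:2,C:0,G:0,T:0), col2 (A:0,C:3,G:1,T:0); window "AG":
        # S = 2 + 1 = 3, S_max = 5, S_min = 0 -> dissimilarity 40%
        pwm = PWM("TF", np.array([[2.0, 0.0, 0.0, 0.0], [0.0, 3.0, 1.0, 0.0]]))
        hits = scan_pwm(
            SequenceRecord("p", "AG", "DNA"),
            [pwm],
            PromoterParameters(max_dissimilarity_pct=50.0, scan_both_strands=False),
        )
        assert hits[0].dissimilarity_pct == pytest.approx(40.0)

    def test_matches_bruteforce_consensus_search(self, rng):
        motif = "GATTACAT"
        pwm = _consensus_pwm(motif)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        hits = scan_pwm(SequenceRecord("p", seq, "DNA"), [pwm], PromoterParameters())
        expected_fwd = {i for i in range(len(seq) - 7) if seq[i : i + 8] == motif}
        rc = reverse_complement(motif, "DNA")
        expected_rev = {i for i in range(len(seq) - 7) if seq[i : i + 8] == rc}
        assert {h.offset for h in hits if h.strand == "+"} == expected_fwd
        assert {h.offset for h in hits if h.strand == "-"} == expected_rev

    def test_dissimilarity_invariant_to_affine_rescaling(self):
        log_odds = np.array([[2.0, 0.1, 0.0, -1.0], [0.0, 3.0, 1.0, 0.5]])
        pwm = PWM("TF", log_odds)
        rescaled = PWM("TF", 3.5 * log_odds + 1.25)
        params = PromoterParameters(max_dissimilarity_pct=100.0, scan_both_strands=False)
        seq = SequenceRecord("p", "AGCTTACG", "DNA")
        d1 = [h.dissimilarity_pct for h in scan_pwm(seq, [pwm], params)]
        d2 = [h.dissimilarity_pct for h in scan_pwm(seq, [rescaled], params)]
        assert d1 == pytest.approx(d2)

    def test_raising_max_dissimilarity_never_removes_hits(self, rng):
        pwm = _consensus_pwm("ACGTACGT", dominant=5.0)
        seq = SequenceRecord("p", "".join(rng.choice(list("ACGT"), 500)), "DNA")
        strict = scan_pwm(seq, [pwm], PromoterParameters(max_dissimilarity_pct=10.0))
        loose = scan_pwm(seq, [pwm], PromoterParameters(max_dissimilarity_pct=40.0))
        strict_keys = {(h.offset, h.strand) for h in strict}
        loose_keys = {(h.offset, h.strand) for h in loose}
        assert strict_keys <= loose_keys

    def test_n_bases_score_as_column_minimum(self):
        pwm = PWM("TF", np.diag([2.0, 3.0, 4.0, 5.0]))
        prom = SequenceRecord("p", "NCGT", "DNA")
        assert scan_pwm(prom, [pwm], PromoterParameters(scan_both_strands=False)) == []

    def test_pwm_wider_than_promoter_skipped(self):
        pwm = _consensus_pwm("ACGTACGT")
        assert scan_pwm(SequenceRecord("p", "ACG", "DNA"), [pwm], PromoterParameters()) == []

    def test_tied_column_maxima_accept_all_tied_bases(self):
        col_tied = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 2.0, 0.0]])
        pwm = PWM("TF", col_tied)
        params = PromoterParameters(scan_both_strands=False)
        assert scan_pwm(SequenceRecord("p", "AG", "DNA"), [pwm], params)
        assert scan_pwm(SequenceRecord("p", "CG", "DNA"), [pwm], params)


class TestCombineTfWithInteractors:
    def _hit(self, tf):
        return TFBSHit(tf, "p", 0, "+", 1.0, 0.0)

    def _interactor(self, name):
        return InteractionRecord("lnc", name, "protein", "validated", "db")

    def test_outer_join_flags(self):
        table = combine_tf_with_interactors(
            [self._hit("GATA1"), self._hit("STAT4")],
            [self._interactor("STAT4"), self._interactor("EP300")],
        )
        row = table.set_index("tf_name")
        assert row.loc["STAT4", "top_candidate"]
        assert row.loc["GATA1", "has_binding_site"] and not row.loc["GATA1", "is_interactor"]
        assert row.loc["EP300", "is_interactor"] and not row.loc["EP300", "has_binding_site"]

    def test_no_hits_all_interactor_only(self):
        table = combine_tf_with_interactors([], [self._interactor("EP300")])
        assert not table["has_binding_site"].any()

    def test_empty_inputs_empty_table(self):
        assert combine_tf_with_interactors([], []).empty


class TestPwmIO:
    def test_round_trip_counts(self, tmp_path):
        counts = {"TFX": np.array([[8, 1, 1, 1], [1, 8, 1, 1], [1, 1, 8, 1], [1, 1, 1, 8]])}
        path = tmp_path / "pwms.txt"
        write_pwm_counts(counts, path)
        (pwm,) = read_pwms(path)
        assert pwm.tf_name == "TFX"
        assert pwm.consensus() == "ACGT"
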