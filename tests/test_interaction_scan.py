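import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lnckit.fixtures import _apply_wobble, _rna_complement_site
from lnckit.interaction_scan import (
    CatRapidFilterParams,
    DuplexHit,
    ScanParameters,
    duplex_align,
    filter_protein_predictions,
    scan_lncrna_vs_transcripts,
    scan_mirnas_vs_lncrna,
    split_snippets,
)
from lnckit.ioformats import FormatError, SequenceRecord
from oracles import best_duplex_score


def _rna(seq, name="x"):
    return SequenceRecord(name, seq, "RNA")


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), n))


class TestSplitSnippets:
    def test_tiling_of_120nt_with_step_50(self):
        params = ScanParameters(snippet_len=50, snippet_step=50)
        intervals = [iv for iv, _ in split_snippets(_rna("A" * 120), params)]
        assert intervals == [(0, 50), (50, 100), (100, 120)]

    def test_exact_length_single_window(self):
        assert [iv for iv, _ in split_snippets(_rna("A" * 50))] == [(0, 50)]

    def test_short_sequence_single_window(self):
        assert [iv for iv, _ in split_snippets(_rna("A" * 49))] == [(0, 49)]

    def test_trailing_short_window_replaced_by_end_anchored_window(self):
        # 110 nt, step 50: the 10 nt tail is below min_snippet_len, so a
        # full-width window anchored at the end restores coverage
        params = ScanParameters(snippet_len=50, snippet_step=50)
        intervals = [iv for iv, _ in split_snippets(_rna("A" * 110), params)]
        assert intervals == [(0, 50), (50, 100), (60, 110)]

    @settings(derandomize=True, max_examples=60)
    @given(length=st.integers(20, 400), step=st.integers(1, 50))
    def test_coverage_union_equals_sequence(self, length, step):
        params = ScanParameters(snippet_len=50, snippet_step=step)
        covered = np.zeros(length, dtype=bool)
        for (a, b), sub in split_snippets(_rna("A" * length), params):
            assert len(sub) == b - a
            covered[a:b] = True
        assert covered.all()


class TestDuplexAlign:
    def test_perfect_seven_mer_duplex(self):
        (hit,) = duplex_align(_rna("UGAGGUA", "q"), _rna("UACCUCA", "t"))
        assert hit.score == 35.0
        assert hit.energy_kcal == -17.0
        assert hit.n_paired == 7
        assert hit.query_interval == (0, 7)
        assert hit.target_interval == (0, 7)

    def test_no_complementarity_yields_no_hits(self):
        assert duplex_align(_rna("AAAA"), _rna("AAAA")) == []

    def test_non_rna_rejected(self):
        with pytest.raises(FormatError):
            duplex_align(SequenceRecord("q", "ACGT", "DNA"), _rna("ACGU"))

    def test_matches_exhaustive_enumeration_on_short_pairs(self, rng):
        params = ScanParameters()
        for _ in range(200):
            n, m = rng.integers(1, 9, 2)
            q, t = _random_rna(rng, n), _random_rna(rng, m)
            expected = best_duplex_score(q, t)
            hits = duplex_align(_rna(q, "q"), _rna(t, "t"), params)
            got = hits[0].score if hits else 0.0
            assert got == pytest.approx(expected), (q, t)

    def test_energy_is_additive_over_pair_table(self, rng):
        params = ScanParameters()
        for _ in range(30):
            q = _random_rna(rng, 20)
            t = _rna_complement_site(q)
            hits = duplex_align(_rna(q, "q"), _rna(t, "t"), params)
            assert hits
            h = hits[0]
            gc = sum(1 for c in q if c in "GC")
            au = len(q) - gc
            assert h.energy_kcal == pytest.approx(-3.0 * gc - 2.0 * au)
            assert h.n_paired == len(q)

    def test_wobble_pairs_score_and_energy(self):
        # G:U wobble site: query G pairs target U
        (hit,) = duplex_align(_rna("GGGGGGG", "q"), _rna("UUUUUUU", "t"))
        assert hit.score == 7.0  # 7 wobbles at +1
        assert hit.energy_kcal == -7.0

    def test_suboptimal_hits_are_non_overlapping_on_target(self, rng):
        site = "UGAGGUAGUAGGUUGUAUAGUU"
        comp = _rna_complement_site(site)
        spacer = "AAAA"
        target = comp + spacer + comp
        hits = duplex_align(_rna(site, "q"), _rna(target, "t"), ScanParameters(), min_score=50)
        assert len(hits) >= 2
        (a, b), (c, d) = hits[0].target_interval, hits[1].target_interval
        assert b <= c or d <= a


class TestScans:
    def _planted_scan_case(self, rng, site_len=50):
        target_seq = _random_rna(rng, 400)
        pos = 150
        segment = target_seq[pos : pos + site_len]
        site = _rna_complement_site(segment)
        lnc_seq = _random_rna(rng, 300)
        lnc = lnc_seq[:100] + site + lnc_seq[100 + site_len :]
        return _rna(lnc, "lnc"), _rna(target_seq, "t"), (100, 100 + site_len), (pos, pos + site_len)

    def test_planted_site_found_and_merged_to_one_hit(self, rng):
        lnc, target, q_iv, t_iv = self._planted_scan_case(rng)
        hits = scan_lncrna_vs_transcripts(lnc, [target])
        assert len(hits) == 1
        assert hits[0].query_interval == q_iv
        assert hits[0].target_interval == t_iv
        assert hits[0].score >= 160 and hits[0].energy_kcal <= -72

    def test_short_site_below_threshold_not_reported(self, rng):
        lnc, target, *_ = self._planted_scan_case(rng, site_len=10)
        assert scan_lncrna_vs_transcripts(lnc, [target]) == []

    def test_empty_target_list(self):
        assert scan_lncrna_vs_transcripts(_rna("ACGU" * 30), []) == []

    def test_snippet_scan_equals_unsplit_scan(self, rng):
        # planted sites <= 25 nt with step 25 <= 50 - span: the snippet scan
        # must recover exactly the hits of scanning the whole sequence
        params = ScanParameters(
            snippet_len=50,
            snippet_step=25,
            score_threshold_mrna=90.0,
            energy_threshold_kcal=-30.0,
        )
        for _ in range(20):
            site_len = int(rng.integers(20, 26))
            target_seq = _random_rna(rng, 300)
            pos = int(rng.integers(20, 250 - site_len))
            site = _rna_complement_site(target_seq[pos : pos + site_len])
            lnc_seq = list(_random_rna(rng, 200))
            offset = int(rng.integers(0, 200 - site_len))
            lnc_seq[offset : offset + site_len] = site
            lnc = _rna("".join(lnc_seq), "lnc")
            target = _rna(target_seq, "t")
            unsplit_params = ScanParameters(
                snippet_len=len(lnc.seq),
                snippet_step=len(lnc.seq),
                score_threshold_mrna=90.0,
                energy_threshold_kcal=-30.0,
            )
            snippet_hits = scan_lncrna_vs_transcripts(lnc, [target], params)
            unsplit_hits = scan_lncrna_vs_transcripts(lnc, [target], unsplit_params)
            for u in unsplit_hits:
                if u.query_interval[1] - u.query_interval[0] <= 25:
                    match = [
                        s
                        for s in snippet_hits
                        if s.target_interval == u.target_interval and s.score == u.score
                    ]
                    assert match, (u, snippet_hits)

    def test_mirna_planted_site_reaches_threshold(self, rng):
        mirna = _rna(_random_rna(rng, 26), "mir")
        site = _rna_complement_site(mirna.seq)
        lnc_seq = _random_rna(rng, 300)
        lnc = _rna(lnc_seq[:120] + site + lnc_seq[120 + 26 :], "lnc")
        hits = scan_mirnas_vs_lncrna([mirna], lnc)
        assert hits and hits[0].score >= 120
        assert hits[0].target_interval == (120, 146)

    def test_shuffled_mirnas_rarely_hit(self, rng):
        lnc = _rna(_random_rna(rng, 500), "lnc")
        n_hits = 0
        for _ in range(100):
            mirna = _rna(_random_rna(rng, 22), "mir")
            n_hits += bool(scan_mirnas_vs_lncrna([mirna], lnc))
        assert n_hits <= 5  # zero-hit rate >= 0.95 under the null

    def test_mirna_longer_than_30nt_rejected(self):
        with pytest.raises(ValueError):
            scan_mirnas_vs_lncrna([_rna("A" * 31, "m")], _rna("ACGU" * 20))

    def test_raising_threshold_never_adds_hits(self, rng):
        lnc, target, *_ = self._planted_scan_case(rng)
        loose = ScanParameters(score_threshold_mrna=150.0, energy_threshold_kcal=-60.0)
        strict = ScanParameters(score_threshold_mrna=200.0, energy_threshold_kcal=-100.0)
        loose_hits = {(h.target_id, h.query_interval) for h in scan_lncrna_vs_transcripts(lnc, [target], loose)}
        strict_hits = {(h.target_id, h.query_interval) for h in scan_lncrna_vs_transcripts(lnc, [target], strict)}
        assert strict_hits <= loose_hits


class TestProteinPredictionFilter:
    TABLE = pd.DataFrame(
        {
            "protein_id": ["p1", "p2", "p3"],
            "star_rating": [2.5, 2.0, 3.0],
            "discriminative_power_pct": [80.0, 90.0, 75.0],
        }
    )

    def test_star_boundary_inclusive_power_boundary_strict(self):
        kept = filter_protein_predictions(self.TABLE)
        assert [r.target_id for r in kept] == ["p1"]  # p2: low star; p3: power not > 75

    def test_records_are_predicted_protein_interactions(self):
        (rec,) = filter_protein_predictions(self.TABLE, lncrna_id="lncX")
        assert rec.evidence == "predicted"
        assert rec.target_type == "protein"
        assert rec.source_id == "lncX"

    def test_missing_column_is_hard_error(self):
        with pytest.raises(FormatError, match="star_rating"):
            filter_protein_predictions(self.TABLE.drop(columns=["star_rating"]))
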