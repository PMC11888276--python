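"""Additive scoring, deltaSVM identities, saturation mutagenesis, tracks,
motif profiles and variant-table scoring."""

import numpy as np
import pandas as pd
import pytest

from crevip.gkm import (KmerWeightTable, reverse_complement, revcomp_codes,
                        sliding_codes)
from crevip.io import GenomicRegion, VariantRecord
from crevip.variants import (MotifOccurrence, VipTable, delta_svm_indel,
                             delta_svm_snv, motif_vip_profile,
                             saturation_mutagenesis, scan_motif_occurrences,
                             score_sequence_additive, score_variant_table,
                             summed_vip_track)


def random_table(rng, l, rc_symmetric=True):
    w = rng.normal(size=4 ** l)
    if rc_symmetric:
        rc = revcomp_codes(np.arange(4 ** l, dtype=np.uint32), l)
        w = (w + w[rc]) / 2
    return KmerWeightTable(word_length=l, weights=w)


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestAdditiveScore:
    def test_zero_table_scores_zero(self, rng):
        table = KmerWeightTable(word_length=4, weights=np.zeros(256))
        assert score_sequence_additive(table, rand_seq(rng, 50)) == 0.0

    def test_window_count(self, rng):
        table = KmerWeightTable(word_length=11, weights=np.ones(4 ** 11))
        assert score_sequence_additive(table, rand_seq(rng, 301)) == 291.0

    def test_toy_two_window_example(self):
        arr = np.zeros(16)
        arr[sliding_codes("AA", 2)[0]] = 1.0
        table = KmerWeightTable(word_length=2, weights=arr)
        assert score_sequence_additive(table, "AAA") == 2.0

    def test_too_short_is_error(self):
        table = KmerWeightTable(word_length=4, weights=np.zeros(256))
        with pytest.raises(ValueError):
            score_sequence_additive(table, "ACG")


class TestDeltaSvm:
    def test_windowed_equals_full_rescore_on_random_snvs(self, rng):
        """The windowed SNV score and the full additive rescore difference
        are oracles for each other."""
        table = random_table(rng, 5)
        seq = rand_seq(rng, 120)
        for _ in range(300):
            pos = int(rng.integers(0, len(seq)))
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == seq[pos]:
                continue
            full = (score_sequence_additive(table, seq[:pos] + alt + seq[pos + 1:])
                    - score_sequence_additive(table, seq))
            assert delta_svm_snv(table, seq, pos, alt) == pytest.approx(full, abs=1e-9)

    def test_alt_equal_ref_is_zero_with_warning(self, rng):
        table = random_table(rng, 4)
        with pytest.warns(UserWarning):
            assert delta_svm_snv(table, "ACGTACGT", 2, "G") == 0.0

    def test_locality_of_context(self, rng):
        """VIP depends only on sequence within l-1 bp of the edit."""
        table = random_table(rng, 5)
        core = rand_seq(rng, 30)
        pos, alt = 15, "A" if core[15] != "A" else "C"
        base = delta_svm_snv(table, core, pos, alt)
        for _ in range(5):
            extended = rand_seq(rng, 10) + core + rand_seq(rng, 10)
            assert delta_svm_snv(table, extended, pos + 10, alt) == \
                pytest.approx(base, abs=1e-9)

    def test_strand_consistency(self, rng):
        """Scoring the reverse-complemented context with the complemented
        allele gives the same VIP under strand-symmetric weights."""
        table = random_table(rng, 5, rc_symmetric=True)
        seq = rand_seq(rng, 60)
        comp = dict(zip("ACGT", "TGCA"))
        for pos in (7, 25, 50):
            alt = "A" if seq[pos] != "A" else "G"
            fwd = delta_svm_snv(table, seq, pos, alt)
            rev = delta_svm_snv(table, reverse_complement(seq),
                                len(seq) - 1 - pos, comp[alt])
            assert fwd == pytest.approx(rev, abs=1e-9)

    def test_indel_identity_and_zero(self, rng):
        table = random_table(rng, 5)
        seq = rand_seq(rng, 60)
        assert delta_svm_indel(table, seq, seq) == 0.0
        deleted = seq[:20] + seq[28:]
        expected = (score_sequence_additive(table, deleted)
                    - score_sequence_additive(table, seq))
        assert delta_svm_indel(table, seq, deleted) == pytest.approx(expected)

    def test_double_deletion_scored_independently_of_singles(self, rng):
        """The combined deletion is a full rescore, not the sum of singles."""
        table = random_table(rng, 5)
        seq = rand_seq(rng, 80)
        del_a = seq[:10] + seq[18:]
        del_b = seq[:50] + seq[58:]
        del_ab = seq[:10] + seq[18:50] + seq[58:]
        combined = delta_svm_indel(table, seq, del_ab)
        expected = (score_sequence_additive(table, del_ab)
                    - score_sequence_additive(table, seq))
        assert combined == pytest.approx(expected, abs=1e-9)


class TestSaturation:
    def region(self, width=61):
        return GenomicRegion("chr1", 100, 100 + width, name="r")

    def test_entry_count_three_per_position(self, rng):
        table = random_table(rng, 5)
        seq = rand_seq(rng, 61)
        vip = saturation_mutagenesis(table, self.region(), sequence=seq)
        assert vip.n_entries == 3 * 61

    def test_window_length_region(self, rng):
        table = random_table(rng, 11)
        seq = rand_seq(rng, 11)
        vip = saturation_mutagenesis(table, GenomicRegion("chr1", 0, 11),
                                     sequence=seq)
        assert vip.n_entries == 33

    def test_matches_scalar_delta_svm(self, rng):
        table = random_table(rng, 5)
        seq = rand_seq(rng, 40)
        vip = saturation_mutagenesis(table, GenomicRegion("chr1", 0, 40),
                                     sequence=seq)
        for p in (0, 17, 39):
            for b, base in enumerate("ACGT"):
                if base == seq[p]:
                    assert np.isnan(vip.vip[p, b])
                else:
                    assert vip.vip[p, b] == pytest.approx(
                        delta_svm_snv(table, seq, p, base), abs=1e-9)

    def test_uniform_table_gives_zero_vips(self, rng):
        table = KmerWeightTable(word_length=4, weights=np.full(256, 2.5))
        seq = rand_seq(rng, 30)
        vip = saturation_mutagenesis(table, GenomicRegion("chr1", 0, 30),
                                     sequence=seq)
        np.testing.assert_allclose(np.nan_to_num(vip.vip), 0, atol=1e-9)

    def test_n_positions_are_skipped(self, rng):
        table = random_table(rng, 4)
        seq = "ACGTACGT" + "N" + "ACGTACGTACGT"
        vip = saturation_mutagenesis(table, GenomicRegion("chr1", 0, 21),
                                     sequence=seq)
        assert np.isnan(vip.vip[8]).all()
        assert vip.n_entries == 3 * 20


class TestSummedTrack:
    def test_sums_three_alternates(self, rng):
        table = random_table(rng, 4)
        seq = rand_seq(rng, 30)
        vip = saturation_mutagenesis(table, GenomicRegion("chr1", 50, 80),
                                     sequence=seq)
        track = summed_vip_track(vip)
        assert len(track) == 30
        p = 10
        assert track[("chr1", 60)] == pytest.approx(np.nansum(vip.vip[p]))

    def test_zero_table_gives_zero_track(self, rng):
        table = KmerWeightTable(word_length=4, weights=np.zeros(256))
        seq = rand_seq(rng, 20)
        vip = saturation_mutagenesis(table, GenomicRegion("chr1", 0, 20),
                                     sequence=seq)
        assert all(v == 0 for v in summed_vip_track(vip).values())


class TestMotifProfileAndScan:
    def test_embedded_consensus_is_found_once(self, sharp_pfm, rng):
        seq = rand_seq(rng, 40) + sharp_pfm.consensus + rand_seq(rng, 40)
        genome = {"chr1": seq}
        regions = [GenomicRegion("chr1", 0, len(seq))]
        occs = scan_motif_occurrences(regions, genome, sharp_pfm, 0.85)
        assert len(occs) == 1
        assert occs[0].start == 40 and occs[0].strand == "+"

    def test_palindrome_collapses_to_forward(self, rng):
        from crevip.io import MotifPFM
        pal = "GAATTC"  # EcoRI site, reverse-complement palindrome
        matrix = np.full((4, 6), 1.0)
        for j, b in enumerate(pal):
            matrix["ACGT".index(b), j] = 97.0
        pfm = MotifPFM("PAL", "PAL", matrix)
        seq = rand_seq(rng, 20) + pal + rand_seq(rng, 20)
        occs = scan_motif_occurrences([GenomicRegion("chr1", 0, len(seq))],
                                      {"chr1": seq}, pfm, 0.9)
        at_site = [o for o in occs if o.start == 20]
        assert len(at_site) == 1 and at_site[0].strand == "+"

    def test_uniform_vip_gives_flat_profile(self, sharp_pfm):
        region = GenomicRegion("chr1", 0, 100)
        vip = VipTable(region=region, ref_sequence="A" * 100,
                       vip=np.full((100, 4), -1.0))
        occ = MotifOccurrence("M_TEST", "chr1", 40, 48, "+", 10.0)
        profile = motif_vip_profile([vip], [occ], window=10)
        assert profile.n_occurrences == 1
        np.testing.assert_allclose(profile.mean_vip, -1.0)
        assert profile.offsets[0] == -10 and profile.offsets[-1] == 17

    def test_minus_strand_occurrence_is_flipped(self):
        region = GenomicRegion("chr1", 0, 50)
        vip_values = np.tile(np.arange(50, dtype=float)[:, None], (1, 4))
        vip = VipTable(region=region, ref_sequence="A" * 50, vip=vip_values)
        fwd = motif_vip_profile([vip], [MotifOccurrence("M", "chr1", 20, 28,
                                                        "+", 1.0)], window=0)
        rev = motif_vip_profile([vip], [MotifOccurrence("M", "chr1", 20, 28,
                                                        "-", 1.0)], window=0)
        np.testing.assert_allclose(rev.mean_vip, fwd.mean_vip[::-1])

    def test_no_occurrences_is_error(self):
        with pytest.raises(ValueError):
            motif_vip_profile([], [], window=5)


class TestVariantTable:
    def test_snv_and_indel_scoring_with_ref_check(self, rng):
        table = random_table(rng, 5)
        genome = {"chr1": rand_seq(rng, 500)}
        seq = genome["chr1"]
        variants = [
            VariantRecord("snv1", "chr1", 100, seq[100],
                          "A" if seq[100] != "A" else "C"),
            VariantRecord("del1", "chr1", 200, seq[200:203], seq[200]),
        ]
        df = score_variant_table({"m": table}, variants, genome,
                                 flank_context=30)
        expected_snv = delta_svm_snv(table, seq[70:131], 30,
                                     variants[0].alt_allele)
        assert df.loc[df.id == "snv1", "vip_m"].iloc[0] == \
            pytest.approx(expected_snv, abs=1e-9)
        ctx = seq[170:233]
        alt_ctx = ctx[:30] + variants[1].alt_allele + ctx[33:]
        assert df.loc[df.id == "del1", "vip_m"].iloc[0] == \
            pytest.approx(delta_svm_indel(table, ctx, alt_ctx), abs=1e-9)

    def test_context_enlargement_does_not_change_vip(self, rng):
        table = random_table(rng, 5)
        genome = {"chr1": rand_seq(rng, 600)}
        v = [VariantRecord("v", "chr1", 300, genome["chr1"][300],
                           "T" if genome["chr1"][300] != "T" else "G")]
        small = score_variant_table({"m": table}, v, genome, flank_context=10)
        large = score_variant_table({"m": table}, v, genome, flank_context=150)
        assert small["vip_m"].iloc[0] == pytest.approx(large["vip_m"].iloc[0],
                                                       abs=1e-9)

    def test_ref_mismatch_names_variant(self, rng):
        table = random_table(rng, 4)
        genome = {"chr1": "A" * 100}
        bad = [VariantRecord("oops", "chr1", 50, "C", "T")]
        with pytest.raises(ValueError, match="oops"):
            score_variant_table({"m": table}, bad, genome)
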