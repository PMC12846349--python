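"""Slippery-site detection, -1 read-through measurement and locus surveys."""

import numpy as np
import pytest

from charkit import synthetic_data as sd
from charkit.errors import EmptyInputError
from charkit.genome_io import FeatureCoord, GenomeRecord, reverse_complement
from charkit.prf_scanner import (dedupe_alleles, find_slippery,
                                 minus1_extension, scan_orf, survey_locus)
from oracles import minus1_readthrough


def _record_with_orf(orf_seq: str, downstream: str = "", upstream: str = "",
                     strand: str = "+") -> tuple[GenomeRecord, FeatureCoord]:
    seq = upstream + orf_seq + downstream
    start, end = len(upstream), len(upstream) + len(orf_seq)
    if strand == "-":
        seq = reverse_complement(seq)
        start, end = len(seq) - end, len(seq) - start
    feat = FeatureCoord("orf1", start, end, strand)
    return GenomeRecord(id="g", sequence=seq, features=[feat]), feat


class TestFindSlippery:
    def test_motif_before_stop_has_offset_3(self):
        # ...GTTTTT TAA: motif end abuts the stop codon
        orf = "ATG" + "GCA" * 10 + "GTTTTTTAA"
        rec, feat = _record_with_orf(orf)
        sites = find_slippery(rec, feat)
        assert len(sites) == 1
        assert sites[0].offset_from_stop == 3
        assert rec.sequence[sites[0].genome_pos:sites[0].genome_pos + 6] == "GTTTTT"

    def test_no_motif_returns_empty(self):
        orf = "ATG" + "GCA" * 10 + "TAA"
        rec, feat = _record_with_orf(orf)
        assert find_slippery(rec, feat) == []

    def test_motif_outside_window_is_excluded(self):
        orf = "ATG" + "GTTTTT" + "GCA" * 70 + "TAA"  # motif ~210 nt from stop
        rec, feat = _record_with_orf(orf)
        assert find_slippery(rec, feat, window_nt=60) == []
        assert len(find_slippery(rec, feat, window_nt=len(orf))) == 1

    def test_minus_strand_site_maps_to_same_offset(self):
        orf = "ATG" + "GCA" * 10 + "GTTTTTTAA"
        rec_p, feat_p = _record_with_orf(orf, upstream="ACGTAC")
        rec_m, feat_m = _record_with_orf(orf, upstream="ACGTAC", strand="-")
        sp = find_slippery(rec_p, feat_p)[0]
        sm = find_slippery(rec_m, feat_m)[0]
        assert sp.offset_from_stop == sm.offset_from_stop == 3


class TestMinus1Extension:
    def test_planted_extension_measured_exactly(self):
        """A -1 frame engineered to run stop-free for a known distance past
        the original stop, checked against the translation oracle."""
        spec = sd.PrfGenomeSpec(n_genomes=1, extension_len=300, seed=1)
        genomes, truth = sd.make_prf_genomes(spec)
        g = genomes[0]
        feat = g.feature_by_id(truth.orf_id[0])
        res = scan_orf(g, feat)
        assert not res.premature_stop
        assert res.extension_nt == truth.expect_extension_nt[0] >= 300
        ctx = g.feature_sequence(feat) + g.sequence[feat.end:feat.end + 3000]
        oracle = minus1_readthrough(ctx, len(feat), "GTTTTT")
        assert oracle["extension_nt"] == res.extension_nt

    def test_planted_premature_stop_fails(self):
        spec = sd.PrfGenomeSpec(n_genomes=1,
                                negatives={0: "plant_minus1_stop"}, seed=2)
        genomes, truth = sd.make_prf_genomes(spec)
        g = genomes[0]
        res = scan_orf(g, g.feature_by_id(truth.orf_id[0]))
        assert res.site is not None
        assert res.premature_stop and not res.passes
        assert res.extension_nt == 0

    def test_unterminated_scan_fails_gracefully(self):
        # -1 frame after the slip contains no stop within the scan limit
        orf = "ATG" + "GCA" * 5 + "GTTTTTTAA"
        rec, feat = _record_with_orf(orf, downstream="ACA" * 200)
        site = find_slippery(rec, feat)[0]
        res = minus1_extension(rec, feat, site, scan_limit_nt=100)
        assert res.unterminated and not res.passes

    def test_extension_invariant_under_minus_strand(self):
        spec_p = sd.PrfGenomeSpec(n_genomes=5, divergence=0.05, seed=9)
        spec_m = sd.PrfGenomeSpec(n_genomes=5, divergence=0.05, seed=9,
                                  minus_strand=True)
        gp, tp = sd.make_prf_genomes(spec_p)
        gm, tm = sd.make_prf_genomes(spec_m)
        for (g1, o1), (g2, o2) in zip(zip(gp, tp.orf_id), zip(gm, tm.orf_id)):
            r1 = scan_orf(g1, g1.feature_by_id(o1))
            r2 = scan_orf(g2, g2.feature_by_id(o2))
            assert r1.extension_nt == r2.extension_nt
            assert r1.passes == r2.passes


class TestDedupeAlleles:
    def test_case_insensitive_counting(self):
        assert dedupe_alleles(["ACGT", "acgt", "TTTT"]) == [("ACGT", 2),
                                                            ("TTTT", 1)]

    def test_single_input(self):
        assert dedupe_alleles(["ACGT"]) == [("ACGT", 1)]

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            dedupe_alleles([])

    def test_counts_are_conserved(self):
        rng = np.random.default_rng(0)
        loci = ["".join(rng.choice(list("ACGT"), size=6)) for _ in range(200)]
        assert sum(c for _, c in dedupe_alleles(loci)) == 200


class TestSurveyLocus:
    def test_positive_set_all_pass(self, prf_genome_set):
        genomes, truth = prf_genome_set
        mapping = dict(zip(truth.genome_id, truth.orf_id))
        survey = survey_locus(genomes, mapping, align=False)
        for res, row in zip(survey.per_genome, truth.itertuples()):
            assert res.passes == row.expect_pass
            assert (res.site is not None) == row.expect_site
        assert sum(r.premature_stop for r in survey.per_genome) == 0

    def test_scrambled_negatives_fail_with_site_absent(self, prf_genome_set):
        genomes, truth = prf_genome_set
        mapping = dict(zip(truth.genome_id, truth.orf_id))
        survey = survey_locus(genomes, mapping, align=False)
        scrambled = truth.index[truth["mode"] == "scramble_motif"].tolist()
        assert scrambled  # fixture plants three of them
        for i in scrambled:
            assert survey.per_genome[i].site is None
            assert not survey.per_genome[i].passes

    def test_motif_columns_invariant_in_positive_alignment(self):
        spec = sd.PrfGenomeSpec(n_genomes=8, divergence=0.08, seed=21)
        genomes, truth = sd.make_prf_genomes(spec)
        mapping = dict(zip(truth.genome_id, truth.orf_id))
        survey = survey_locus(genomes, mapping)
        assert survey.conservation is not None
        # the slippery hexamer survives in every aligned allele
        for row in survey.msa.rows:
            assert "GTTTTT" in row.replace("-", "")
        assert survey.conservation.invariant_fraction > 0

    def test_zero_divergence_collapses_to_one_allele(self):
        spec = sd.PrfGenomeSpec(n_genomes=6, divergence=0.0, seed=4)
        genomes, truth = sd.make_prf_genomes(spec)
        mapping = dict(zip(truth.genome_id, truth.orf_id))
        survey = survey_locus(genomes, mapping)
        assert survey.n_unique_alleles == 1

    def test_missing_orf_names_the_genome(self, prf_genome_set):
        genomes, truth = prf_genome_set
        mapping = dict(zip(truth.genome_id, truth.orf_id))
        mapping[genomes[0].id] = "nonexistent"
        with pytest.raises(KeyError, match=genomes[0].id):
            survey_locus(genomes[:2], mapping, align=False)


class TestOracleAgreement:
    def test_scanner_agrees_with_translation_oracle(self):
        """Across seeded positive/scrambled/premature genomes the scanner's
        decision must match an independent translation-based oracle."""
        for seed in range(40):
            mode = ["positive", "scramble_motif", "plant_minus1_stop"][seed % 3]
            negatives = {} if mode == "positive" else {0: mode}
            spec = sd.PrfGenomeSpec(n_genomes=1, negatives=negatives,
                                    divergence=0.05, seed=seed)
            genomes, truth = sd.make_prf_genomes(spec)
            g = genomes[0]
            feat = g.feature_by_id(truth.orf_id[0])
            res = scan_orf(g, feat)
            ctx = g.feature_sequence(feat) + (
                g.sequence[feat.end:feat.end + 3000] if feat.strand == "+"
                else reverse_complement(g.sequence[max(0, feat.start - 3000):feat.start]))
            oracle = minus1_readthrough(ctx, len(feat), "GTTTTT")
            assert (res.site is not None) == oracle["found"]
            assert res.premature_stop == oracle["premature"]
            assert res.extension_nt == oracle["extension_nt"]
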