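import numpy as np
import pytest
from hypothesis import given, strategies as st

import mitophylo as mp
from mitophylo.genes import (CANONICAL_PCGS, STOP_CODONS, ExtractionError,
                             TranslationError, effective_cds)

NON_STOP_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - STOP_CODONS)


class TestResolveGeneName:
    @pytest.mark.parametrize("raw,expected", [
        ("COI", "COX1"), ("cytb", "CYTB"), ("NADH1", "ND1"),
        ("nadh dehydrogenase subunit 4L", "ND4L"), ("ATPase6", "ATP6"),
        ("ATPase 8", "ATP8"), ("12S rRNA", "rrnS"), ("l-rRNA", "rrnL"),
        ("trnF", "tRNA-Phe"), ("COIII", "COX3"), ("hypothetical_orf", None),
    ])
    def test_synonyms(self, raw, expected):
        assert mp.resolve_gene_name(raw) == expected

    def test_idempotent_on_canonical_symbols(self):
        for symbol in CANONICAL_PCGS:
            assert mp.resolve_gene_name(symbol) == symbol


class TestTranslateMito:
    @pytest.mark.parametrize("cds,expected", [
        ("ATGTGACGATAA", "MWR"),   # TGA = Trp under table 2; TAA trimmed
        ("ATAAGA", "M"),           # ATA = Met; AGA is a stop, trimmed
        ("ATGNNNTAA", "MX"),
        ("ATGAAAT", "MK"),         # incomplete terminal stop (T) dropped
        ("ATGAAATA", "MK"),        # incomplete terminal stop (TA) dropped
    ])
    def test_examples(self, cds, expected):
        assert mp.translate_mito(cds) == expected

    def test_codon_start_offset(self):
        assert mp.translate_mito("GATGAAATAA", codon_start=2) == "MK"

    def test_internal_stop_reports_codon_index(self):
        with pytest.raises(TranslationError, match="codon 2"):
            mp.translate_mito("ATGAGATTTTAA")

    def test_empty_input_rejected(self):
        with pytest.raises(TranslationError):
            mp.translate_mito("")

    @given(st.lists(st.sampled_from(NON_STOP_CODONS), min_size=1, max_size=40),
           st.sampled_from(["", "TAA", "TAG", "AGA", "AGG", "T", "TA"]))
    def test_no_stop_in_protein_and_length_contract(self, codons, tail):
        cds = "".join(codons) + tail
        protein = mp.translate_mito(cds)
        assert "*" not in protein
        assert protein == "".join(mp.translate_mito(c) for c in codons)
        eff = effective_cds(cds)
        assert len(eff) == 3 * len(protein)


def _record_with(features, sequence, acc="TST1"):
    return mp.MitoRecord(acc, "test organism", sequence, features)


class TestExtractPcgs:
    def test_plus_strand_and_codon_start(self):
        #          1234567890123
        sequence = "GATGAAATAACCC"
        rec = _record_with(
            [mp.GeneFeature("ND1", "CDS", 1, 10, codon_start=2)], sequence)
        gs = mp.extract_pcgs(rec)
        assert gs.genes["ND1"] == ("ATGAAA", "MK")
        assert len(gs.missing) == 12

    def test_minus_strand(self):
        cds = "ATGAAATAA"  # revcomp placed on genome
        rc = cds[::-1].translate(str.maketrans("ACGT", "TGCA"))
        rec = _record_with(
            [mp.GeneFeature("ND6", "CDS", 3, 11, strand="-")], "GG" + rc + "AA")
        gs = mp.extract_pcgs(rec)
        assert gs.genes["ND6"] == ("ATGAAA", "MK")

    def test_duplicate_symbol_rejected(self):
        feats = [mp.GeneFeature("COX1", "CDS", 1, 9),
                 mp.GeneFeature("COI", "CDS", 10, 18)]
        rec = _record_with(feats, "ATGAAATAAATGAAATAA")
        with pytest.raises(ExtractionError, match="COX1"):
            mp.extract_pcgs(rec)

    def test_trna_only_record_all_missing(self):
        rec = _record_with([mp.GeneFeature("tRNA-Phe", "tRNA", 1, 9)],
                           "ACGTACGTA")
        gs = mp.extract_pcgs(rec)
        assert gs.genes == {}
        assert sorted(gs.missing) == sorted(CANONICAL_PCGS)

    def test_generator_truth_recovered(self, small_bundle):
        for rec in small_bundle.records:
            gs = mp.extract_pcgs(rec)
            assert gs.missing == []
            for gene in CANONICAL_PCGS:
                truth = small_bundle.genes[gene].cds_by_taxon[rec.organism]
                assert gs.genes[gene][0] == truth


class TestGeneOrder:
    def test_synthetic_record_is_canonical(self, small_bundle):
        report = mp.validate_gene_order(small_bundle.records[0])
        assert report.counts == (13, 22, 2, 1)
        assert report.deviations == []

    def test_nd6_strand_flip_single_deviation(self, small_bundle):
        rec = small_bundle.records[0]
        flipped = [mp.GeneFeature(f.gene_name, f.feature_kind, f.start, f.end,
                                  "+" if f.gene_name == "ND6" else f.strand,
                                  f.transl_table, f.codon_start, f.wraps_origin)
                   for f in rec.features]
        mutated = mp.MitoRecord(rec.accession, rec.organism, rec.sequence, flipped)
        report = mp.validate_gene_order(mutated)
        assert len(report.deviations) == 1
        assert "ND6" in report.deviations[0]
        assert "strand" in report.deviations[0]
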