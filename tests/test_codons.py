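"""Genetic-code tables, codon splitting, start/stop calls and RSCU."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.codons import (INVERTEBRATE_MITO, NO_STOP, GeneticCode, count_codons,
                             gene_start_stops, identify_start_stop, rscu,
                             split_codons)
from mitocomp.model import GeneFeature, MitoGenome

CDS = st.text(alphabet="ACGT", min_size=3, max_size=120)


class TestGeneticCode:
    def test_invertebrate_mito_reassignments(self):
        code = INVERTEBRATE_MITO
        assert code.translate("ATA") == "M"
        assert code.translate("TGA") == "W"
        assert code.translate("AGA") == code.translate("AGG") == "S"

    def test_families_partition_all_64_codons(self):
        for table_id in (2, 5):
            code = GeneticCode.from_ncbi_id(table_id)
            members = [c for fam in code.families.values() for c in fam]
            assert sorted(members) == sorted(set(members))
            assert len(members) == 64

    def test_expected_family_sizes_under_table5(self):
        code = INVERTEBRATE_MITO
        assert len(code.family_of("TTA")) == 6          # Leu
        assert len(code.family_of("TCT")) == 8          # Ser incl. AGA/AGG
        assert sorted(code.families["*"]) == ["TAA", "TAG"]


class TestSplitCodons:
    def test_cox2_style_length_664(self):
        codons, frag = split_codons("A" * 664)
        assert len(codons) == 221 and frag == "A"

    def test_exact_multiple_has_empty_fragment(self):
        codons, frag = split_codons("ATGAAA")
        assert codons == ["ATG", "AAA"] and frag == ""

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            split_codons("AT")

    @given(CDS)
    @settings(max_examples=80, deadline=None)
    def test_length_conservation(self, cds):
        codons, frag = split_codons(cds)
        assert 3 * len(codons) + len(frag) == len(cds)
        assert len(frag) < 3


class TestStartStop:
    @pytest.mark.parametrize("cds,start,stop", [
        ("ATA" + "AAA" * 4 + "TAA", "ATA", "TAA"),
        ("ATT" + "AAA" * 4 + "TAG", "ATT", "TAG"),
        ("ATA" + "AAA" * 4 + "T", "ATA", "T"),
        ("ATG" + "AAA" * 4 + "TA", "ATG", "TA"),
        ("ATG" + "AAA" * 4, "ATG", NO_STOP),
    ])
    def test_tokens(self, cds, start, stop):
        assert identify_start_stop(cds) == (start, stop)

    def test_agA_is_not_a_stop_under_table5(self):
        # AGA = Ser under the invertebrate code, a stop under the vertebrate one
        cds = "ATG" + "AAA" * 4 + "AGA"
        assert identify_start_stop(cds)[1] == NO_STOP
        assert identify_start_stop(cds, GeneticCode.from_ncbi_id(2))[1] == "AGA"

    def test_planted_tokens_recovered(self, synthetic_genome):
        genome, truth = synthetic_genome
        calls = gene_start_stops(genome)
        assert {g: s for g, (s, _) in calls.items()} == truth["start_codons"]
        assert {g: s for g, (_, s) in calls.items()} == truth["stop_codons"]


class TestRSCU:
    LEU = {"TTA": 247, "TTG": 47, "CTT": 49, "CTA": 48, "CTC": 7, "CTG": 3}

    def test_published_leucine_values(self):
        table = rscu(self.LEU)
        assert round(table.rscu["TTA"], 3) == 3.696
        assert round(table.rscu["CTG"], 3) == 0.045

    def test_published_two_fold_families(self):
        table = rscu({"ATA": 463, "ATG": 52, "AAA": 188, "AAG": 29})
        assert round(table.rscu["ATA"], 3) == 1.798
        assert round(table.rscu["AAG"], 3) == 0.267

    def test_stop_codons_form_their_own_two_member_family(self):
        table = rscu({"TAA": 11, "TAG": 1})
        assert round(table.rscu["TAA"], 3) == 1.833
        assert round(table.rscu["TAG"], 3) == 0.167

    def test_uniform_family_gives_all_ones(self):
        table = rscu({c: 5 for c in INVERTEBRATE_MITO.families["V"]})
        assert all(table.rscu[c] == pytest.approx(1.0)
                   for c in INVERTEBRATE_MITO.families["V"])

    def test_zero_family_is_nan_not_zero(self):
        assert math.isnan(rscu({}).rscu["GGG"])

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            rscu({"TTA": -1})

    def test_family_sums_and_scale_invariance(self):
        counts = {"TTA": 10, "CTT": 3, "CTG": 1, "ATA": 4, "ATG": 4}
        base = rscu(counts)
        scaled = rscu({c: 7.5 * v for c, v in counts.items()})
        for fam_aa in ("L", "M"):
            fam = INVERTEBRATE_MITO.families[fam_aa]
            assert sum(base.rscu[c] for c in fam) == pytest.approx(len(fam))
        assert all(base.rscu[c] == pytest.approx(scaled.rscu[c]) for c in counts)


class TestCountCodons:
    def _genome(self, seqs_and_strands):
        seq = "".join(s for s, _ in seqs_and_strands)
        feats, pos = [], 1
        from mitocomp.model import reverse_complement
        parts = []
        for i, (s, strand) in enumerate(seqs_and_strands):
            parts.append(reverse_complement(s) if strand == "-" else s)
            feats.append(GeneFeature(f"g{i}", "PCG", pos, pos + len(s) - 1, strand))
            pos += len(s)
        return MitoGenome("toy", "".join(parts), True, feats)

    def test_exact_hand_count_two_genes(self):
        g = self._genome([("ATAAAATAA", "+"), ("ATGTTTTAA", "-")])
        counts = count_codons(g)
        assert counts == {"ATA": 1.0, "AAA": 1.0, "TAA": 2.0, "ATG": 1.0, "TTT": 1.0}

    def test_incomplete_stop_fragment_not_counted(self):
        g = self._genome([("ATAAAAT", "+")])
        counts = count_codons(g)
        assert counts == {"ATA": 1.0, "AAA": 1.0}

    def test_ambiguity_split_halves_weight(self):
        g = self._genome([("ATACGYTAA", "+")])
        counts = count_codons(g, ambiguity_policy="split")
        assert counts["CGC"] == counts["CGT"] == pytest.approx(0.5)

    def test_drop_and_split_agree_without_ambiguity(self, synthetic_genome):
        genome, _ = synthetic_genome
        assert count_codons(genome, ambiguity_policy="drop") == \
            count_codons(genome, ambiguity_policy="split")

    def test_no_pcgs_warns_and_returns_empty(self):
        g = MitoGenome("toy", "ACGTACGT", True, [])
        with pytest.warns(UserWarning):
            assert count_codons(g) == {}

    def test_codon_count_reconciles_with_pcg_lengths(self, synthetic_genome):
        # 3 * total counted codons + incomplete-stop fragment lengths = sum PCG bp
        genome, truth = synthetic_genome
        counts = count_codons(genome)
        frag_nt = sum(len(t) for t in truth["stop_codons"].values() if t in ("T", "TA"))
        pcg_bp = sum(f.size_bp for f in genome.features_of_class("PCG"))
        assert 3 * sum(counts.values()) + frag_nt == pcg_bp
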