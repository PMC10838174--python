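"""Synthetic-data generators: determinism and planted-truth recovery."""

import numpy as np
import pytest

from mitocomp import codons
from mitocomp.architecture import adjacency_gaps, largest_unannotated_span
from mitocomp.kaks import pairwise_ng86
from mitocomp.model import PCG
from mitocomp.simulate import (DivergenceSpec, GenomeSpec, chesperidum_like_spec,
                               evolve_codon_pair, generate_mitogenome,
                               generate_trna, generate_trna_set)


def small_spec(seed=0, gaps=(2, -3, 0)):
    template = [("COX1", "PCG", 99, "+"), ("trnX", "tRNA", 60, "+"),
                ("ND1", "PCG", 150, "-"), ("rrnX", "rRNA", 200, "-")]
    return GenomeSpec(genome_length=600, gene_template=template,
                      planted_gaps=list(gaps), first_start=10,
                      start_codons={"COX1": "ATA", "ND1": "ATT"},
                      stop_codons={"COX1": "TAA", "ND1": "TAG"}, seed=seed)


class TestGenerateMitogenome:
    def test_determinism_same_seed_byte_identical(self):
        g1, _ = generate_mitogenome(small_spec(3))
        g2, _ = generate_mitogenome(small_spec(3))
        assert g1.sequence == g2.sequence
        assert g1.features == g2.features

    def test_different_seed_differs(self):
        g1, _ = generate_mitogenome(small_spec(3))
        g2, _ = generate_mitogenome(small_spec(4))
        assert g1.sequence != g2.sequence

    def test_planted_gaps_recovered(self):
        genome, truth = generate_mitogenome(small_spec())
        recs = adjacency_gaps(genome.features, genome.length_bp, True)
        got = [r.intergenic_length for r in recs if not r.is_wrap]
        assert got == [2, -3, 0]

    def test_all_zero_gaps_give_no_overlaps_or_spacers(self):
        genome, _ = generate_mitogenome(small_spec(gaps=(0, 0, 0)))
        recs = adjacency_gaps(genome.features, genome.length_bp, True)
        assert all(r.intergenic_length == 0 for r in recs if not r.is_wrap)

    def test_infeasible_spec_rejected(self):
        spec = small_spec()
        spec.genome_length = 300
        with pytest.raises(ValueError, match="infeasible"):
            generate_mitogenome(spec)

    def test_composition_targets_hit(self):
        genome, truth = generate_mitogenome(chesperidum_like_spec(seed=2))
        assert abs(truth["realised_at_content"] - 0.834) <= 0.01
        assert abs(truth["realised_at_skew"] - 0.22) <= 0.02

    def test_pcgs_are_orfs_with_planted_tokens(self):
        genome, truth = generate_mitogenome(small_spec())
        calls = codons.gene_start_stops(genome)
        assert calls["COX1"] == ("ATA", "TAA")
        assert calls["ND1"] == ("ATT", "TAG")

    def test_no_internal_stop_codons_in_clean_pcgs(self):
        # genes that overlap nothing must be open reading frames throughout
        genome, _ = generate_mitogenome(small_spec(gaps=(5, 5, 5)))
        from mitocomp.model import extract_gene_sequence
        for f in genome.features_of_class(PCG):
            body, _ = codons.split_codons(extract_gene_sequence(genome, f))
            assert not any(codons.INVERTEBRATE_MITO.is_stop(c) for c in body[:-1])

    def test_unannotated_span_matches_truth(self):
        genome, truth = generate_mitogenome(small_spec())
        assert largest_unannotated_span(genome)[2] == truth["unannotated_length"]


class TestEvolveCodonPair:
    def test_zero_divergence_identity(self):
        a, b = evolve_codon_pair(DivergenceSpec(
            n_codons=50, omega=1.0, expected_substitutions_per_codon=0.0, seed=1))
        assert a == b

    def test_omega_zero_gives_no_nonsynonymous_differences(self):
        a, b = evolve_codon_pair(DivergenceSpec(n_codons=300, omega=0.0, seed=1))
        r = pairwise_ng86(a, b)
        assert r.Nd == 0.0 and r.Sd > 0

    def test_deterministic_under_seed(self):
        spec = DivergenceSpec(n_codons=100, omega=0.7, seed=9)
        assert evolve_codon_pair(spec) == evolve_codon_pair(spec)

    def test_no_stop_codons_ever_created(self):
        a, b = evolve_codon_pair(DivergenceSpec(n_codons=400, omega=2.0, seed=5))
        for seq in (a, b):
            cods, _ = codons.split_codons(seq)
            assert not any(codons.INVERTEBRATE_MITO.is_stop(c) for c in cods)

    def test_neutral_calibration(self):
        ratios = []
        for rep in range(8):
            a, b = evolve_codon_pair(DivergenceSpec(n_codons=500, omega=1.0, seed=rep))
            ratios.append(pairwise_ng86(a, b).ratio)
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_monotone_in_omega(self):
        means = []
        for omega in (0.2, 1.0, 2.0):
            vals = [pairwise_ng86(*evolve_codon_pair(
                DivergenceSpec(n_codons=400, omega=omega, seed=50 + rep))).ratio
                for rep in range(6)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DivergenceSpec(n_codons=0, omega=1.0)
        with pytest.raises(ValueError):
            DivergenceSpec(n_codons=10, omega=-0.5)


class TestGenerateTrna:
    def test_round_trip_all_architectures(self):
        from mitocomp.trna import analyse_trna
        for arch in ("cloverleaf", "d_armless", "t_armless", "minimal"):
            seq, struct = generate_trna(arch, seed=6)
            assert analyse_trna(seq, struct).arch_class == arch

    def test_deterministic_under_seed(self):
        assert generate_trna("cloverleaf", seed=8) == generate_trna("cloverleaf", seed=8)

    def test_planted_gu_fraction_on_twenty_paired_bases(self):
        # 20 bp of stems at G-U fraction 0.2 -> exactly 4 wobble pairs
        from mitocomp.trna import analyse_trna
        seq, struct = generate_trna("cloverleaf", seed=10, acceptor_bp=6, d_bp=4,
                                    ac_bp=5, t_bp=5, gu_pairs=4)
        assert analyse_trna(seq, struct).gu_pairs == 4

    def test_set_respects_requested_classes(self):
        rows = generate_trna_set({"a": "minimal", "b": "cloverleaf"}, seed=1)
        assert {r[0]: r[1] for r in rows} == {"a": "minimal", "b": "cloverleaf"}

    def test_excess_gu_request_rejected(self):
        with pytest.raises(ValueError):
            generate_trna("minimal", seed=1, acceptor_bp=3, ac_bp=3, gu_pairs=50)
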