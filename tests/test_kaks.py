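"""NG86 site counting, pathway averaging and Ka/Ks estimation."""

import itertools
import math

import numpy as np
import pytest

from mitocomp.codons import INVERTEBRATE_MITO, GeneticCode
from mitocomp.kaks import (SkipCodon, codon_site_counts, is_defined, jukes_cantor,
                           mean_kaks, pairwise_ng86, per_gene_mean_kaks,
                           thread_codon_alignment)
from mitocomp.simulate import DivergenceSpec, evolve_codon_pair

CODE = INVERTEBRATE_MITO
SENSE = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
         if not CODE.is_stop(c)]


def oracle_site_counts(codon, code=CODE):
    """Independent enumeration of all nine single-base changes."""
    syn = 0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        mut = codon[:pos] + base + codon[pos + 1:]
        if code.translate(mut) == code.translate(codon):
            syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def oracle_pathway_counts(a, b, code=CODE):
    """Exhaustive enumeration of every ordering of the differing positions."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    syn = nonsyn = 0.0
    paths = list(itertools.permutations(diffs))
    for order in paths:
        cur = a
        for i in order:
            nxt = cur[:i] + b[i] + cur[i + 1:]
            if code.translate(nxt) == code.translate(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
    return syn / len(paths), nonsyn / len(paths)


class TestSiteCounts:
    def test_ttt_enumeration(self):
        s, n = codon_site_counts("TTT")
        assert s == pytest.approx(1 / 3) and n == pytest.approx(8 / 3)

    def test_fourfold_third_position(self):
        # GGA (Gly): third position fully degenerate, positions 1-2 not
        s, _ = codon_site_counts("GGA")
        assert s == pytest.approx(1.0)

    def test_every_sense_codon_sums_to_three(self):
        for codon in SENSE:
            s, n = codon_site_counts(codon)
            assert s + n == pytest.approx(3.0)
            assert (s, n) == pytest.approx(oracle_site_counts(codon))

    def test_stop_and_ambiguous_codons_are_skip_signals(self):
        with pytest.raises(SkipCodon):
            codon_site_counts("TAA")
        with pytest.raises(SkipCodon):
            codon_site_counts("ANA")


class TestPairwise:
    def test_identical_sequences(self):
        r = pairwise_ng86("ATAGGATTT", "ATAGGATTT")
        assert (r.Sd, r.Nd, r.Ka, r.Ks) == (0.0, 0.0, 0.0, 0.0)
        assert not is_defined(r.ratio)

    def test_sites_sum_to_three_per_codon(self):
        r = pairwise_ng86("ATAGGATTT", "ATAGGCTTC")
        assert r.S_sites + r.N_sites == pytest.approx(3 * r.n_codons_used)

    def test_one_of_each_difference_gives_positive_rates(self):
        # GGA->GGC synonymous (Gly), TTT->GTT nonsynonymous (Phe->Val)
        r = pairwise_ng86("GGATTTAAA" * 10, "GGCGTTAAA" * 10)
        assert r.Ka > 0 and r.Ks > 0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(SENSE, size=40))
        b = "".join(rng.choice(SENSE, size=40))
        ra, rb = pairwise_ng86(a, b), pairwise_ng86(b, a)
        assert ra.Sd == pytest.approx(rb.Sd) and ra.Nd == pytest.approx(rb.Nd)
        assert ra.S_sites == pytest.approx(rb.S_sites)

    def test_gapped_stop_or_ambiguous_codons_excluded(self):
        r = pairwise_ng86("ATA---TAAANAGGA", "ATAGGGTAAAAAGGC")
        assert r.n_codons_used == 2 and r.n_codons_skipped == 3

    def test_length_mismatch_and_frame_errors(self):
        with pytest.raises(ValueError):
            pairwise_ng86("ATAGGA", "ATA")
        with pytest.raises(ValueError):
            pairwise_ng86("ATAG", "ATAG")

    def test_pathway_averages_match_exhaustive_oracle(self):
        """100 random 200-codon pairs: Sd/Nd equal the brute-force pathway
        enumeration over all orderings, exactly."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            a = "".join(rng.choice(SENSE, size=200))
            b = "".join(rng.choice(SENSE, size=200))
            r = pairwise_ng86(a, b)
            sd = nd = 0.0
            for i in range(200):
                s, n = oracle_pathway_counts(a[3 * i:3 * i + 3], b[3 * i:3 * i + 3])
                sd += s
                nd += n
            assert r.Sd == pytest.approx(sd, abs=1e-9)
            assert r.Nd == pytest.approx(nd, abs=1e-9)


class TestJukesCantor:
    def test_domain_boundary_gives_nan_sentinel(self):
        assert not is_defined(jukes_cantor(0.75))
        assert not is_defined(jukes_cantor(0.9))

    def test_zero_distance(self):
        assert jukes_cantor(0.0) == 0.0

    def test_correction_exceeds_raw_proportion(self):
        assert jukes_cantor(0.3) > 0.3


class TestMeans:
    def test_single_pair_mean_is_that_ratio(self):
        a, b = evolve_codon_pair(DivergenceSpec(n_codons=200, omega=0.5, seed=3))
        r = pairwise_ng86(a, b)
        m = per_gene_mean_kaks({("s1", "s2"): (a, b)})
        assert m.mean == pytest.approx(r.ratio) and m.n_used == 1

    def test_undefined_ratios_excluded_and_counted(self):
        a, b = evolve_codon_pair(DivergenceSpec(n_codons=200, omega=0.5, seed=3))
        m = per_gene_mean_kaks({("s1", "s2"): (a, b), ("s1", "s1"): (a, a)})
        assert m.n_used == 1 and m.n_undefined == 1

    def test_all_undefined_gives_nan(self):
        m = per_gene_mean_kaks({("s1", "s1"): ("ATAGGA", "ATAGGA")})
        assert not is_defined(m.mean)

    def test_simple_average(self):
        class R:  # minimal stand-in with a ratio attribute
            def __init__(self, ratio):
                self.ratio = ratio
        assert mean_kaks([R(0.5), R(1.5)]).mean == pytest.approx(1.0)


class TestThreading:
    def test_threads_codons_through_protein_gaps(self):
        prot = {"s1": "MK-F", "s2": "MKQF"}
        cds = {"s1": "ATGAAATTT", "s2": "ATGAAACAATTT"}
        out = thread_codon_alignment(prot, cds)
        assert out["s1"] == "ATGAAA---TTT"
        assert out["s2"] == "ATGAAACAATTT"

    def test_terminal_stop_codon_tolerated(self):
        out = thread_codon_alignment({"s1": "MK"}, {"s1": "ATGAAATAA"})
        assert out["s1"] == "ATGAAA"

    def test_residue_codon_mismatch_rejected(self):
        with pytest.raises(ValueError):
            thread_codon_alignment({"s1": "MKF"}, {"s1": "ATGAAA"})
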