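"""Pairwise Ka/Ks by the Nei-Gojobori (1986) counting method.

Synonymous site counts: for each codon, s is the sum over its three positions
of the fraction of the three possible single-nucleotide changes that leave the
amino acid unchanged (changes creating a stop codon count as nonsynonymous);
n = 3 - s.  S and N for a sequence pair are the means of the per-sequence
totals.  Per-codon differences are resolved by enumerating every minimal
substitution pathway between the two codons with equal weights and averaging
the synonymous/nonsynonymous step counts.  Proportions ps = Sd/S and
pn = Nd/N are Jukes-Cantor corrected, d = -(3/4) ln(1 - (4/3) p); a
proportion >= 3/4 leaves the distance undefined (NaN sentinel), as does
Ka/Ks when Ks is zero or undefined.

Codons containing alignment gaps, ambiguity codes, or a stop codon in either
sequence are excluded from the pair entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

from .codons import INVERTEBRATE_MITO, GeneticCode, split_codons

UNDEFINED = math.nan
_ACGT = "ACGT"


def is_defined(x: float) -> bool:
    return x == x  # NaN is the only self-unequal float


class SkipCodon(ValueError):
    """Raised for codons NG86 cannot score (stops, ambiguity codes)."""


@lru_cache(maxsize=None)
def _site_counts_cached(codon: str, table_id: int) -> tuple[float, float]:
    code = GeneticCode.from_ncbi_id(table_id)
    aa = code.translate(codon)
    syn = 0.0
    for pos in range(3):
        for base in _ACGT:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if code.translate(mutant) == aa:  # change to a stop is nonsynonymous
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def codon_site_counts(codon: str, code: GeneticCode = INVERTEBRATE_MITO) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon; s + n = 3."""
    c = codon.upper().replace("U", "T")
    if set(c) - set(_ACGT) or len(c) != 3:
        raise SkipCodon(f"ambiguous or malformed codon {codon!r}")
    if code.is_stop(c):
        raise SkipCodon(f"stop codon {codon!r} has no NG86 site counts")
    return _site_counts_cached(c, code.table_id)


def _pathway_counts(a: str, b: str, code: GeneticCode) -> tuple[float, float]:
    """Equal-weight average of (syn, nonsyn) steps over all minimal pathways.

    Implemented by recursive branching over which differing position mutates
    next, averaging at each level (equivalent to enumerating the d! orderings
    with equal weights).
    """
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    syn_total = nonsyn_total = 0.0
    for i in diffs:
        step = a[:i] + b[i] + a[i + 1:]
        s_step = 1.0 if code.translate(step) == code.translate(a) else 0.0
        s_rest, n_rest = _pathway_counts(step, b, code)
        syn_total += s_step + s_rest
        nonsyn_total += (1.0 - s_step) + n_rest
    k = len(diffs)
    return syn_total / k, nonsyn_total / k


def jukes_cantor(p: float) -> float:
    """JC69 distance for a difference proportion; NaN outside the log domain."""
    if not is_defined(p) or p >= 0.75:
        return UNDEFINED
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    ratio: float
    n_codons_used: int
    n_codons_skipped: int = 0


def pairwise_ng86(seq_a: str, seq_b: str,
                  code: GeneticCode = INVERTEBRATE_MITO) -> KaKsResult:
    """NG86 Ka/Ks for one codon-aligned coding-strand sequence pair."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned sequences differ in length ({len(seq_a)} vs {len(seq_b)})")
    if len(seq_a) % 3:
        raise ValueError("aligned length is not a multiple of 3")
    codons_a, _ = split_codons(seq_a)
    codons_b, _ = split_codons(seq_b)
    S = N = Sd = Nd = 0.0
    used = skipped = 0
    for ca, cb in zip(codons_a, codons_b):
        try:
            sa, na = codon_site_counts(ca, code)
            sb, nb = codon_site_counts(cb, code)
        except SkipCodon:
            skipped += 1
            continue
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_counts(ca, cb, code)
        Sd += sd
        Nd += nd
        used += 1
    ps = Sd / S if S > 0 else UNDEFINED
    pn = Nd / N if N > 0 else UNDEFINED
    Ks, Ka = jukes_cantor(ps), jukes_cantor(pn)
    if is_defined(Ka) and is_defined(Ks) and Ks > 0:
        ratio = Ka / Ks
    else:
        ratio = UNDEFINED
    return KaKsResult(S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
                      Ks=Ks, Ka=Ka, ratio=ratio,
                      n_codons_used=used, n_codons_skipped=skipped)


@dataclass(frozen=True)
class MeanRatio:
    mean: float
    n_used: int
    n_undefined: int


def mean_kaks(results) -> MeanRatio:
    """Arithmetic mean of the defined Ka/Ks ratios in *results*."""
    ratios = [r.ratio for r in results]
    defined = [x for x in ratios if is_defined(x)]
    mean = sum(defined) / len(defined) if defined else UNDEFINED
    return MeanRatio(mean=mean, n_used=len(defined),
                     n_undefined=len(ratios) - len(defined))


def per_gene_mean_kaks(alignments: dict, code: GeneticCode = INVERTEBRATE_MITO) -> MeanRatio:
    """Mean pairwise Ka/Ks over {pair-label: (seqA, seqB)} codon alignments."""
    return mean_kaks(pairwise_ng86(a, b, code) for a, b in alignments.values())


def all_pairs_kaks(cds_by_species: dict[str, str],
                   code: GeneticCode = INVERTEBRATE_MITO) -> dict[tuple[str, str], KaKsResult]:
    """Every unordered species pair of one gene's aligned CDS set."""
    out = {}
    for sa, sb in combinations(sorted(cds_by_species), 2):
        out[(sa, sb)] = pairwise_ng86(cds_by_species[sa], cds_by_species[sb], code)
    return out


def thread_codon_alignment(protein_alignment: dict[str, str],
                           cds_by_species: dict[str, str]) -> dict[str, str]:
    """Back-translate an aligned protein set into a codon alignment.

    Each aligned amino acid (or gap) is replaced by the next codon of that
    species' in-frame CDS (or ``---``).  The alignment itself must be produced
    elsewhere; this helper only threads nucleotides through it.
    """
    out = {}
    for species, prot in protein_alignment.items():
        cds = cds_by_species[species]
        codons, _ = split_codons(cds)
        # a terminal stop codon in the CDS has no aligned residue
        n_residues = sum(1 for ch in prot if ch != "-")
        if len(codons) == n_residues + 1:
            codons = codons[:-1]
        if len(codons) != n_residues:
            raise ValueError(
                f"{species}: {len(codons)} codons cannot thread {n_residues} aligned residues")
        it = iter(codons)
        out[species] = "".join("---" if ch == "-" else next(it) for ch in prot)
    return out
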