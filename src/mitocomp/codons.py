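"""Codon extraction, start/stop identification and RSCU.

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial: ATA=Met, TGA=Trp, AGA/AGG=Ser, stops TAA/TAG); tables are data
taken from Biopython's codon-table registry, so the vertebrate mitochondrial
code etc. are selectable by id.

RSCU(c) = count(c) * family_size / family_total, where a family is the set of
synonymous codons for one amino acid (stop codons form their own family).
Mitochondrial CDSs may end in a 1-2 nt fragment ("T"/"TA"), an incomplete stop
completed to TAA by polyadenylation; fragments are recorded as stop tokens but
never counted as codons.  Fractional codon counts are supported throughout:
under the ``split`` ambiguity policy a codon containing IUPAC ambiguity codes
contributes weight 1/k to each of its k concrete expansions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.Data.IUPACData import ambiguous_dna_values

from .model import PCG, MitoGenome, extract_gene_sequence

UNDEFINED = math.nan
NO_STOP = "no-stop"

_BASES = "TCAG"
_ALL_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with its synonym-family partition."""

    table_id: int
    name: str
    codon_to_aa: dict[str, str]  # 64 codons; stops map to "*"
    families: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_ncbi_id(cls, table_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = {c: "*" for c in table.stop_codons}
        mapping.update(table.forward_table)
        assert len(mapping) == 64
        fams: dict[str, list[str]] = {}
        for codon in _ALL_CODONS:
            fams.setdefault(mapping[codon], []).append(codon)
        return cls(table_id=table_id, name=table.names[0], codon_to_aa=dict(mapping),
                   families={aa: tuple(cods) for aa, cods in fams.items()})

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon.upper().replace("U", "T")]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == "*"

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.translate(codon)]


INVERTEBRATE_MITO = GeneticCode.from_ncbi_id(5)


def split_codons(cds: str) -> tuple[list[str], str]:
    """Non-overlapping triplets from position 1 plus the 0-2 nt remainder."""
    if len(cds) < 3:
        raise ValueError(f"CDS of {len(cds)} nt is shorter than one codon")
    s = cds.upper().replace("U", "T")
    n_full = len(s) // 3
    return [s[3 * i:3 * i + 3] for i in range(n_full)], s[3 * n_full:]


def identify_start_stop(cds: str, code: GeneticCode = INVERTEBRATE_MITO) -> tuple[str, str]:
    """(start codon, stop token) of a coding-strand CDS.

    The stop token is the final complete triplet when it is a stop codon of
    *code*, the trailing fragment ("T"/"TA") when the length is not a multiple
    of three (an incomplete stop), and the ``NO_STOP`` flag otherwise.
    """
    if len(cds) < 6:
        raise ValueError("CDS shorter than 6 nt has no separable start and stop")
    codons, fragment = split_codons(cds)
    if fragment:
        stop = fragment
    elif code.is_stop(codons[-1]):
        stop = codons[-1]
    else:
        stop = NO_STOP
    return codons[0], stop


def _expand_ambiguous(codon: str) -> list[str]:
    options = [ambiguous_dna_values.get(b, b) for b in codon]
    return ["".join(c) for c in itertools.product(*options)]


def count_codons(genome: MitoGenome, code: GeneticCode = INVERTEBRATE_MITO,
                 ambiguity_policy: str = "drop") -> dict[str, float]:
    """Pool codon counts over all protein-coding genes of *genome*.

    Complete terminal stop codons are included; trailing incomplete-stop
    fragments are not.  ``ambiguity_policy="drop"`` discards codons containing
    ambiguity codes; ``"split"`` spreads weight 1/k over the k compatible
    concrete codons (the mechanism behind fractional counts such as 0.5).
    """
    if ambiguity_policy not in ("drop", "split"):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    pcgs = genome.features_of_class(PCG)
    if not pcgs:
        warnings.warn("genome has no protein-coding features; codon counts empty")
        return {}
    counts: dict[str, float] = {}
    for feat in pcgs:
        codons, _fragment = split_codons(extract_gene_sequence(genome, feat))
        for codon in codons:
            if set(codon) <= set("ACGT"):
                counts[codon] = counts.get(codon, 0.0) + 1.0
            elif ambiguity_policy == "split":
                expansions = _expand_ambiguous(codon)
                w = 1.0 / len(expansions)
                for e in expansions:
                    counts[e] = counts.get(e, 0.0) + w
    return counts


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon counts with their RSCU values under one genetic code."""

    code: GeneticCode
    counts: dict[str, float]
    rscu: dict[str, float]

    def rows(self) -> list[dict]:
        """Table rows (AA, codon, count, RSCU) sorted by RSCU descending."""
        out = [{"AA": self.code.translate(c), "codon": c,
                "count": self.counts.get(c, 0.0), "RSCU": self.rscu[c]}
               for c in _ALL_CODONS]
        return sorted(out, key=lambda r: (-(r["RSCU"] if r["RSCU"] == r["RSCU"] else -1),
                                          r["codon"]))


def rscu(counts: dict[str, float], code: GeneticCode = INVERTEBRATE_MITO) -> CodonUsageTable:
    """Relative synonymous codon usage for one count table.

    Families whose total count is zero get NaN for every member (RSCU is
    undefined there, not zero).
    """
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative codon count")
    clean = {c.upper().replace("U", "T"): float(v) for c, v in counts.items()}
    values: dict[str, float] = {}
    for family in code.families.values():
        total = sum(clean.get(c, 0.0) for c in family)
        size = len(family)
        for c in family:
            values[c] = UNDEFINED if total == 0 else clean.get(c, 0.0) * size / total
    return CodonUsageTable(code=code, counts=clean, rscu=values)


def gene_start_stops(genome: MitoGenome,
                     code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, tuple[str, str]]:
    """{gene name: (start codon, stop token)} over all PCGs of *genome*."""
    return {f.name: identify_start_stop(extract_gene_sequence(genome, f), code)
            for f in genome.features_of_class(PCG)}
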