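"""Base composition and AT/GC strand skews.

AT skew = (A - T) / (A + T); GC skew = (G - C) / (G + C).  Positive AT skew
means the examined strand is A-rich; in AT-rich insect mitogenomes the plus
strand typically shows positive AT skew and negative GC skew while
reverse-strand genes, read on their coding strand, show the mirror image.

Per-gene rows are computed on the gene's coding strand (reverse-strand genes
reverse-complemented); aggregate rows ("13 PCGs", "22 tRNAs") are computed on
the concatenation of member sequences, i.e. length-weighted, never by
averaging percentages; the whole-genome "Total" row uses the deposited plus
strand.  Ambiguity codes are excluded from both numerator and denominator and
tallied separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .model import (PCG, RRNA, TRNA, MitoGenome, extract_gene_sequence,
                    normalize_gene_name, reverse_complement)

UNDEFINED = math.nan


@dataclass(frozen=True)
class CompositionRow:
    """One row of a composition table (a region's base percentages + skews)."""

    region_label: str
    pct_a: float
    pct_t: float
    pct_g: float
    pct_c: float
    at_content: float
    at_skew: float
    gc_skew: float
    n_counted: int
    n_ambiguous: int = 0

    def as_dict(self) -> dict:
        return {
            "region": self.region_label, "A(%)": self.pct_a, "T(%)": self.pct_t,
            "G(%)": self.pct_g, "C(%)": self.pct_c, "A+T(%)": self.at_content,
            "AT-skew": self.at_skew, "GC-skew": self.gc_skew, "n": self.n_counted,
        }


def skew(x: float, y: float) -> float:
    """(x - y) / (x + y); NaN when the denominator is zero."""
    return UNDEFINED if x + y == 0 else (x - y) / (x + y)


def at_skew(row: CompositionRow) -> float:
    """AT skew recomputed from the row's stored A/T percentages."""
    return skew(row.pct_a, row.pct_t)


def gc_skew(row: CompositionRow) -> float:
    """GC skew recomputed from the row's stored G/C percentages."""
    return skew(row.pct_g, row.pct_c)


def base_composition(seq: str, label: str = "") -> CompositionRow:
    """Composition of one sequence, counting unambiguous A/C/G/T only."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    a, t, g, c = s.count("A"), s.count("T"), s.count("G"), s.count("C")
    n = a + t + g + c
    if n == 0:
        raise ValueError(f"sequence {label!r} contains no unambiguous bases")
    pa, pt, pg, pc = (100.0 * x / n for x in (a, t, g, c))
    return CompositionRow(
        region_label=label, pct_a=pa, pct_t=pt, pct_g=pg, pct_c=pc,
        at_content=pa + pt, at_skew=skew(a, t), gc_skew=skew(g, c),
        n_counted=n, n_ambiguous=len(s) - n)


_CLASS_LABELS = {PCG: "13 PCGs", TRNA: "22 tRNAs", RRNA: "2 rRNAs"}


def partition_composition(genome: MitoGenome, selector) -> list[CompositionRow]:
    """Composition rows for a selection of genes plus their aggregate.

    *selector* may be a gene class (``"PCG"``, ``"tRNA"``, ``"rRNA"``), the
    string ``"total"`` (whole plus strand, single row), or an iterable of gene
    names.  Per-gene rows are followed by one aggregate row computed on the
    concatenated coding-strand sequences.
    """
    if selector == "total":
        return [base_composition(genome.sequence, "Total")]
    if isinstance(selector, str):
        feats = genome.features_of_class(selector)
        label = f"{len(feats)} {selector}s"
    else:
        wanted = {normalize_gene_name(n) for n in selector}
        feats = [f for f in genome.features if normalize_gene_name(f.name) in wanted]
        label = "+".join(sorted(wanted))
    if not feats:
        warnings.warn(f"selector {selector!r} matched no features")
        return []
    rows = []
    concat = []
    for f in feats:
        s = extract_gene_sequence(genome, f)
        concat.append(s)
        rows.append(base_composition(s, f.name))
    rows.append(base_composition("".join(concat), label))
    return rows


def composition_table(genome: MitoGenome) -> list[CompositionRow]:
    """Full composition table: per-PCG rows, tRNA/rRNA aggregates, Total.

    Mirrors the layout of a published per-genome composition table: one row
    per protein-coding gene, one aggregate row for the tRNA set, per-rRNA rows,
    the rRNA aggregate, and the whole plus strand.
    """
    rows = list(partition_composition(genome, PCG))
    trna = partition_composition(genome, TRNA)
    if trna:
        rows.append(trna[-1])
    rrna = partition_composition(genome, RRNA)
    rows.extend(rrna)
    rows.extend(partition_composition(genome, "total"))
    return rows


def windowed_gc(seq: str, window: int = 50) -> list[tuple[int, int, float]]:
    """(start, end, GC fraction) per non-overlapping window, 1-based inclusive."""
    out = []
    for i in range(0, len(seq), window):
        chunk = seq[i:i + window].upper()
        gc = sum(chunk.count(b) for b in "GC")
        acgt = sum(chunk.count(b) for b in "ACGT")
        out.append((i + 1, i + len(chunk), UNDEFINED if acgt == 0 else gc / acgt))
    return out
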