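"""Circular mitogenome model and I/O.

The central containers are :class:`GeneFeature` (one annotated gene) and
:class:`MitoGenome` (sequence + ordered features + topology).  Coordinates are
1-based inclusive throughout, the GenBank convention; conversion to 0-based
happens only at the Biopython boundary.  A feature that spans the origin of a
circular genome is stored with ``wraps=True`` and ``start > end``.

Readers accept GenBank flat files (via Biopython), plain FASTA, and a
tab-separated feature table with columns ``gene  start  end  strand
[anticodon]``; writers emit the same three formats so that every reader has a
round-trip partner.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
GENE_CLASSES = (PCG, TRNA, RRNA)

FORWARD = "+"
REVERSE = "-"

# strand spellings tolerated on input (Table-style minus signs included)
_STRAND_ALIASES = {
    "+": FORWARD, "f": FORWARD, "forward": FORWARD, "1": FORWARD,
    "-": REVERSE, "−": REVERSE, "–": REVERSE, "—": REVERSE,
    "r": REVERSE, "reverse": REVERSE, "-1": REVERSE,
}

# Canonical names for the 37 animal mitochondrial genes plus common aliases
# seen in GenBank records and published tables (cob/CYTB, nad1/ND1, rrnL/16S).
_SYNONYMS = {
    "cob": "CYTB", "cytb": "CYTB", "cytochromeb": "CYTB",
    "cox1": "COX1", "co1": "COX1", "coi": "COX1",
    "cox2": "COX2", "co2": "COX2", "coii": "COX2",
    "cox3": "COX3", "co3": "COX3", "coiii": "COX3",
    "atp6": "ATP6", "atpase6": "ATP6",
    "atp8": "ATP8", "atpase8": "ATP8",
    "nad1": "ND1", "nd1": "ND1", "nad2": "ND2", "nd2": "ND2",
    "nad3": "ND3", "nd3": "ND3", "nad4": "ND4", "nd4": "ND4",
    "nad4l": "ND4L", "nd4l": "ND4L", "nad5": "ND5", "nd5": "ND5",
    "nad6": "ND6", "nd6": "ND6",
    "rrnl": "rrnL", "16s": "rrnL", "16srrna": "rrnL", "lrrna": "rrnL",
    "largesubunitribosomalrna": "rrnL",
    "rrns": "rrnS", "12s": "rrnS", "12srrna": "rrnS", "srrna": "rrnS",
    "smallsubunitribosomalrna": "rrnS",
}

_VALID_BASES = set("ACGTUNRYSWKMBDHV")


def normalize_gene_name(name: str) -> str:
    """Map a gene label to its canonical spelling.

    Case-insensitive; strips decoration (``*``, underscores, spaces, hyphens)
    so that e.g. ``trnL_1_``, ``trnl1`` and ``trnL1`` collapse to ``trnL1``,
    and ``16S rRNA``/``l-rRNA``/``rrnL`` collapse to ``rrnL``.  Unrecognised
    names are returned with decoration stripped but spelling otherwise intact.
    """
    key = re.sub(r"[\s_\*\-\(\)]", "", name).lower()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    m = re.match(r"^trn([a-z])(\d?)$", key)
    if m:
        return "trn" + m.group(1).upper() + m.group(2)
    return re.sub(r"[\s_\*]", "", name)


def infer_gene_class(name: str) -> str:
    """tRNA for ``trn*`` names, rRNA for ``rrn*``/``*rRNA`` names, else PCG."""
    canon = normalize_gene_name(name).lower()
    if canon.startswith("trn"):
        return TRNA
    if canon.startswith("rrn") or "rrna" in canon:
        return RRNA
    return PCG


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class ValidationError(ValueError):
    """A feature or genome violates a structural invariant."""


class ParseError(ValueError):
    """Malformed input text."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a mitogenome.

    ``start``/``end`` are 1-based inclusive.  ``wraps=True`` marks a feature
    crossing the origin of a circular genome, in which case ``start > end``
    and ``size_bp`` must be supplied explicitly (it depends on genome length).
    """

    name: str
    gene_class: str
    start: int
    end: int
    strand: str = FORWARD
    anticodon: str | None = None
    wraps: bool = False
    size_bp: int = field(default=0)

    def __post_init__(self):
        if self.gene_class not in GENE_CLASSES:
            raise ValidationError(f"{self.name}: unknown gene class {self.gene_class!r}")
        if self.strand not in (FORWARD, REVERSE):
            raise ValidationError(f"{self.name}: strand must be '+' or '-'")
        if self.start < 1 or self.end < 1:
            raise ValidationError(f"{self.name}: coordinates are 1-based, got {self.start}..{self.end}")
        if not self.wraps and self.end < self.start:
            raise ValidationError(f"{self.name}: end < start for a non-wrapping feature")
        if self.anticodon is not None and self.gene_class != TRNA:
            raise ValidationError(f"{self.name}: anticodon on a non-tRNA feature")
        if not self.wraps:
            expect = self.end - self.start + 1
            if self.size_bp == 0:
                object.__setattr__(self, "size_bp", expect)
            elif self.size_bp != expect:
                raise ValidationError(
                    f"{self.name}: size_bp {self.size_bp} != end-start+1 = {expect}")
        elif self.size_bp <= 0:
            raise ValidationError(f"{self.name}: wrapping feature needs explicit size_bp")
        if self.gene_class == PCG and self.size_bp < 3:
            raise ValidationError(f"{self.name}: protein-coding feature shorter than one codon")


@dataclass
class MitoGenome:
    """A (usually circular) mitochondrial genome with ordered annotations."""

    identifier: str
    sequence: str
    is_circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValidationError(f"invalid sequence characters: {sorted(bad)}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        self.validate()

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = self.length_bp
        for f in self.features:
            if f.start > n or f.end > n:
                raise ValidationError(
                    f"feature {f.name} ({f.start}..{f.end}) outside sequence of {n} bp")
            if f.wraps:
                if not self.is_circular:
                    raise ValidationError(
                        f"feature {f.name} wraps the origin of a linear genome")
                expect = (n - f.start + 1) + f.end
                if f.size_bp != expect:
                    raise ValidationError(
                        f"feature {f.name}: wrapping size_bp {f.size_bp} != {expect}")

    def features_of_class(self, gene_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.gene_class == gene_class]

    def get_feature(self, name: str) -> GeneFeature:
        canon = normalize_gene_name(name)
        for f in self.features:
            if normalize_gene_name(f.name) == canon:
                return f
        raise KeyError(name)


def extract_gene_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """Coding-strand sequence of *feature*.

    Forward features give the plus-strand slice; reverse features its reverse
    complement; wrapping features concatenate the origin-spanning arcs before
    orientation.
    """
    n = genome.length_bp
    if feature.start > n or feature.end > n:
        raise ValidationError(f"feature {feature.name} outside genome bounds")
    if feature.wraps:
        plus = genome.sequence[feature.start - 1:] + genome.sequence[:feature.end]
    else:
        plus = genome.sequence[feature.start - 1:feature.end]
    return reverse_complement(plus) if feature.strand == REVERSE else plus


# ---------------------------------------------------------------------------
# Feature-table TSV
# ---------------------------------------------------------------------------

def read_feature_table(tsv_text: str) -> list[GeneFeature]:
    """Parse a Table-1-style feature TSV.

    Required columns ``gene``, ``start``, ``end``, ``strand``; optional
    ``anticodon`` and ``size`` (the latter is recomputed from coordinates,
    with a warning when the stated value disagrees).
    """
    lines = [ln for ln in tsv_text.splitlines()]
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")]
    if not rows:
        return []
    header = [h.strip().lower() for h in rows[0][1].split("\t")]
    required = {"gene", "start", "end", "strand"}
    if not required <= set(header):
        raise ParseError(f"feature table header must contain {sorted(required)}, got {header}")
    idx = {name: header.index(name) for name in header}
    features: list[GeneFeature] = []
    for lineno, ln in rows[1:]:
        parts = [p.strip() for p in ln.split("\t")]
        if len(parts) < len(required):
            raise ParseError(f"line {lineno}: expected at least {len(required)} columns")

        def col(name):
            i = idx.get(name)
            return parts[i] if i is not None and i < len(parts) else ""

        name = col("gene")
        try:
            start, end = int(col("start")), int(col("end"))
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric coordinates") from None
        strand_raw = col("strand").lower()
        if strand_raw not in _STRAND_ALIASES:
            raise ParseError(f"line {lineno}: unknown strand symbol {col('strand')!r}")
        strand = _STRAND_ALIASES[strand_raw]
        gene_class = infer_gene_class(name)
        anticodon = col("anticodon") or None
        if anticodon and gene_class != TRNA:
            anticodon = None
        wraps = end < start
        size_txt = col("size")
        feat = GeneFeature(name=name, gene_class=gene_class, start=start, end=end,
                           strand=strand, anticodon=anticodon, wraps=wraps,
                           size_bp=int(size_txt) if wraps and size_txt else 0)
        if size_txt and not wraps and int(size_txt) != feat.size_bp:
            warnings.warn(
                f"line {lineno}: stated size {size_txt} for {name} disagrees with "
                f"coordinates ({feat.size_bp}); using coordinates")
        features.append(feat)
    return features


def write_feature_table(features: list[GeneFeature]) -> str:
    out = ["gene\tstart\tend\tstrand\tanticodon\tsize"]
    for f in features:
        out.append(f"{f.name}\t{f.start}\t{f.end}\t{f.strand}\t{f.anticodon or ''}\t{f.size_bp}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# GenBank / FASTA
# ---------------------------------------------------------------------------

_FEATURE_TYPES = {"CDS": PCG, "tRNA": TRNA, "rRNA": RRNA}
_CLASS_TO_TYPE = {v: k for k, v in _FEATURE_TYPES.items()}


def _feature_name(sf: SeqFeature) -> str:
    for key in ("gene", "product", "locus_tag"):
        if key in sf.qualifiers:
            return str(sf.qualifiers[key][0])
    return sf.type


def _feature_anticodon(sf: SeqFeature) -> str | None:
    for key in ("anticodon", "note"):
        for val in sf.qualifiers.get(key, []):
            m = re.search(r"\b([ACGUacgu]{3})\b", str(val).replace("T", "U").replace("t", "u"))
            if m:
                return m.group(1).upper()
    return None


def read_genbank(record_text: str) -> MitoGenome:
    """Build a :class:`MitoGenome` from GenBank flat-file content.

    ``complement`` locations become reverse-strand features; ``join``
    locations whose parts bracket the origin become wrapping features;
    topology is taken from the LOCUS line.
    """
    try:
        record = SeqIO.read(io.StringIO(record_text), "genbank")
    except ValueError as exc:
        raise ParseError(f"not a readable GenBank record: {exc}") from None
    seq = str(record.seq)
    if not seq or set(seq) == {"N"} and len(record.features) == 0:
        raise ParseError("GenBank record has no sequence (missing ORIGIN block)")
    n = len(seq)
    circular = record.annotations.get("topology", "").lower() == "circular"
    features: list[GeneFeature] = []
    for sf in record.features:
        if sf.type not in _FEATURE_TYPES:
            continue
        gene_class = _FEATURE_TYPES[sf.type]
        strand = REVERSE if sf.location.strand == -1 else FORWARD
        parts = sorted(sf.location.parts, key=lambda p: int(p.start))
        wraps = False
        if len(parts) == 2 and int(parts[1].end) == n and int(parts[0].start) == 0:
            # join(x..n, 1..y): feature crosses the origin
            wraps = True
            start, end = int(parts[1].start) + 1, int(parts[0].end)
        else:
            start, end = int(sf.location.start) + 1, int(sf.location.end)
        if end > n or start > n:
            raise ValidationError(
                f"feature {_feature_name(sf)} extends past sequence end ({n} bp)")
        name = _feature_name(sf)
        features.append(GeneFeature(
            name=name, gene_class=gene_class, start=start, end=end, strand=strand,
            anticodon=_feature_anticodon(sf) if gene_class == TRNA else None,
            wraps=wraps, size_bp=((n - start + 1) + end) if wraps else 0))
    return MitoGenome(identifier=record.id or record.name, sequence=seq,
                      is_circular=circular, features=features)


def write_genbank(genome: MitoGenome) -> str:
    record = SeqRecord(Seq(genome.sequence), id=genome.identifier,
                       name=re.sub(r"\W", "_", genome.identifier)[:16] or "genome",
                       description="mitochondrial genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.is_circular else "linear"
    n = genome.length_bp
    for f in genome.features:
        strand = -1 if f.strand == REVERSE else 1
        if f.wraps:
            loc = CompoundLocation([SimpleLocation(f.start - 1, n, strand),
                                    SimpleLocation(0, f.end, strand)])
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        record.features.append(SeqFeature(loc, type=_CLASS_TO_TYPE[f.gene_class],
                                          qualifiers=quals))
    buf = io.StringIO()
    SeqIO.write(record, buf, "genbank")
    return buf.getvalue()


def read_fasta(text: str) -> dict[str, str]:
    """FASTA text -> ordered {id: sequence}."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(io.StringIO(text), "fasta")}


def write_fasta(seqs: dict[str, str]) -> str:
    buf = io.StringIO()
    SeqIO.write([SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()],
                buf, "fasta")
    return buf.getvalue()


def genome_from_parts(identifier: str, sequence: str, features: list[GeneFeature],
                      is_circular: bool = True) -> MitoGenome:
    """Assemble a genome from a FASTA sequence and a parsed feature table."""
    return MitoGenome(identifier=identifier, sequence=sequence,
                      is_circular=is_circular, features=features)


def with_feature(genome: MitoGenome, feature: GeneFeature) -> MitoGenome:
    return replace(genome, features=genome.features + [feature])
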