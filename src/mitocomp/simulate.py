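"""Synthetic mitogenomes, diverged codon pairs and tRNA structures.

Everything the analysis side consumes can be generated here with known ground
truth: an annotated circular genome whose gene order, overlaps/spacers, start
and stop codons (including incomplete "T"/"TA" stops) and base composition are
planted; codon-aligned sequence pairs diverged at a chosen dN/dS; and tRNA
dot-bracket structures with requested arm architectures and wobble-pair
counts.

Randomness: one integer seed is threaded through *named* substreams (one per
generator), so adding a generator never perturbs the output of another.
Every generator is deterministic given (spec, seed).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .codons import INVERTEBRATE_MITO, GeneticCode
from .model import (FORWARD, PCG, REVERSE, RRNA, TRNA, GeneFeature, MitoGenome,
                    infer_gene_class, reverse_complement)
from .trna import CLOVERLEAF, D_ARMLESS, MINIMAL, T_ARMLESS

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# substream tags: generator identity -> fixed offset mixed into the seed
_STREAMS = {"genome": 11, "codon_pair": 23, "trna": 37, "retry": 53}


def _rng(seed: int, stream: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream], salt])


# ---------------------------------------------------------------------------
# Annotated genome generation
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Blueprint for one synthetic circular mitogenome.

    ``gene_template`` rows are ``(name, gene_class, length, strand)``;
    ``planted_gaps`` has one signed entry per consecutive adjacency (negative
    = overlap).  Composition targets apply to the plus strand.  Start/stop
    policies map PCG name -> codon / stop token ("TAA", "TAG", or the
    incomplete tokens "T"/"TA").
    """

    genome_length: int
    gene_template: list[tuple[str, str, int, str]]
    planted_gaps: list[int]
    first_start: int = 1
    at_content_target: float = 0.834
    at_skew_target: float = 0.22
    gc_skew_target: float = -0.31
    start_codons: dict[str, str] = field(default_factory=dict)
    stop_codons: dict[str, str] = field(default_factory=dict)
    anticodons: dict[str, str] = field(default_factory=dict)
    table_id: int = 5
    seed: int = 0

    def coordinates(self) -> list[tuple[int, int]]:
        """Planted (start, end) per gene, in template order."""
        if len(self.planted_gaps) != len(self.gene_template) - 1:
            raise ValueError("need one planted gap per adjacency "
                             f"({len(self.gene_template) - 1}), got {len(self.planted_gaps)}")
        coords = []
        start = self.first_start
        for i, (_name, _cls, length, _strand) in enumerate(self.gene_template):
            end = start + length - 1
            coords.append((start, end))
            if i < len(self.planted_gaps):
                start = end + self.planted_gaps[i] + 1
        return coords


def _base_probs(at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    gc = 1.0 - at
    p = np.array([at * (1 + at_skew) / 2, gc * (1 - gc_skew) / 2,
                  gc * (1 + gc_skew) / 2, at * (1 - at_skew) / 2])  # A C G T
    if (p < 0).any():
        raise ValueError("infeasible composition/skew targets")
    return p / p.sum()


def _sense_codon_sampler(code: GeneticCode, coding_probs: np.ndarray):
    codons = np.array(["".join(c) for c in itertools.product("ACGT", repeat=3)])
    idx = {b: i for i, b in enumerate("ACGT")}
    w = np.array([np.prod([coding_probs[idx[b]] for b in c]) for c in codons])
    w[[code.is_stop(c) for c in codons]] = 0.0
    w /= w.sum()
    return codons, w


def _build_cds(name: str, length: int, spec: GenomeSpec, code: GeneticCode,
               rng: np.random.Generator, codons: np.ndarray, weights: np.ndarray) -> str:
    start = spec.start_codons.get(name, "ATA").upper()
    stop = spec.stop_codons.get(name, "TAA").upper()
    if len(start) != 3:
        raise ValueError(f"{name}: start codon must be a triplet")
    frag_len = len(stop) if stop in ("T", "TA") else 0
    tail = frag_len or 3
    if (length - 3 - tail) % 3 or length < 3 + tail:
        raise ValueError(
            f"{name}: length {length} incompatible with stop token {stop!r}")
    n_body = (length - 3 - tail) // 3
    body = rng.choice(codons, size=n_body, p=weights) if n_body else []
    return start + "".join(body) + stop


def _expected_plus_freqs(codons: np.ndarray, weights: np.ndarray,
                         strand: str) -> np.ndarray:
    """Expected plus-strand base frequencies of one sense-codon distribution."""
    freqs = np.zeros(4)
    for codon, w in zip(codons, weights):
        for b in codon:
            freqs["ACGT".index(b)] += w / 3.0
    if strand == REVERSE:
        freqs = freqs[::-1]  # complementing swaps A<->T and C<->G
    return freqs


def _render_attempt(spec: GenomeSpec, coords, code, rng) -> tuple[np.ndarray, dict]:
    plus_probs = _base_probs(spec.at_content_target, spec.at_skew_target,
                             spec.gc_skew_target)
    minus_probs = plus_probs[::-1]  # complement swaps A<->T and C<->G
    samplers = {FORWARD: _sense_codon_sampler(code, plus_probs),
                REVERSE: _sense_codon_sampler(code, minus_probs)}
    # ORFs exclude stop codons, which depresses A+T inside coding spans;
    # tilt the background so the whole plus strand still hits the targets.
    n = spec.genome_length
    expected = np.zeros(4)
    pcg_len = 0
    for (name, cls, length, strand), _ in zip(spec.gene_template, coords):
        if cls == PCG:
            expected += length * _expected_plus_freqs(*samplers[strand], strand)
            pcg_len += length
    bg_len = max(n - pcg_len, 1)
    bg = (plus_probs * n - expected) / bg_len
    bg = np.clip(bg, 1e-6, None)
    bg /= bg.sum()
    seq = rng.choice(_BASES, size=n, p=bg)
    locked: dict[int, str] = {}  # 0-based plus position -> required base
    truth_start, truth_stop = {}, {}
    for (name, cls, length, strand), (start, end) in zip(spec.gene_template, coords):
        if cls != PCG:
            continue
        codons, weights = samplers[strand]
        cds = _build_cds(name, length, spec, code, rng, codons, weights)
        truth_start[name] = cds[:3]
        stop = spec.stop_codons.get(name, "TAA").upper()
        truth_stop[name] = stop
        plus = reverse_complement(cds) if strand == REVERSE else cds
        for offset, base in enumerate(plus):
            pos = start - 1 + offset
            if pos not in locked:
                seq[pos] = base
        # lock this gene's start codon and stop token on the plus strand
        guard = list(range(3)) + list(range(length - len(stop), length))
        for cidx in guard:
            pos = (end - 1 - cidx) if strand == REVERSE else (start - 1 + cidx)
            base = _COMPLEMENT[cds[cidx]] if strand == REVERSE else cds[cidx]
            if locked.get(pos, base) != base:
                raise ValueError(
                    f"planted start/stop of {name} collides with an earlier gene "
                    f"at position {pos + 1}")
            locked[pos] = base
            seq[pos] = base
    return seq, {"start_codons": truth_start, "stop_codons": truth_stop}


def generate_mitogenome(spec: GenomeSpec,
                        max_attempts: int = 100) -> tuple[MitoGenome, dict]:
    """Sample a genome realising *spec*; returns (genome, truth record).

    The plus strand is resampled (up to *max_attempts* times) until realised
    A+T content is within +-1 percentage point of the target and AT skew
    within +-0.02; if no attempt qualifies the closest one is kept with a
    warning.  Protein-coding genes are open reading frames under the chosen
    code with the planted start/stop tokens; planted overlaps are realised by
    coordinate arithmetic, with earlier genes' start/stop positions locked so
    overlaps cannot destroy them.
    """
    coords = spec.coordinates()
    for (name, _c, _l, _s), (start, end) in zip(spec.gene_template, coords):
        if start < 1 or end > spec.genome_length:
            raise ValueError(f"gene {name} ({start}..{end}) outside genome of "
                             f"{spec.genome_length} bp: infeasible spec")
    if any(coords[i][0] > coords[i + 1][0] for i in range(len(coords) - 1)):
        raise ValueError("planted gaps produce features out of start order")
    code = GeneticCode.from_ncbi_id(spec.table_id)
    best = None
    for attempt in range(max_attempts):
        rng = _rng(spec.seed, "genome", attempt)
        seq, planted = _render_attempt(spec, coords, code, rng)
        counts = {b: int((seq == b).sum()) for b in "ACGT"}
        n = spec.genome_length
        at = (counts["A"] + counts["T"]) / n
        sk = ((counts["A"] - counts["T"]) / (counts["A"] + counts["T"])
              if counts["A"] + counts["T"] else 0.0)
        err = (abs(at - spec.at_content_target), abs(sk - spec.at_skew_target))
        if best is None or err < best[0]:
            best = (err, seq, planted, at, sk)
        if err[0] <= 0.01 and err[1] <= 0.02:
            break
    else:
        warnings.warn(
            f"composition targets not met after {max_attempts} attempts; keeping "
            f"closest (A+T {best[3]:.3f}, AT-skew {best[4]:.3f})")
    _err, seq, planted, at, sk = best
    features = []
    for (name, cls, length, strand), (start, end) in zip(spec.gene_template, coords):
        features.append(GeneFeature(
            name=name, gene_class=cls, start=start, end=end, strand=strand,
            anticodon=spec.anticodons.get(name) if cls == TRNA else None))
    genome = MitoGenome(identifier=f"synthetic-{spec.seed}", sequence="".join(seq),
                        is_circular=True, features=features)
    last_end = coords[-1][1]
    truth = {
        "gaps": {f"{a[0]}~{b[0]}": g for a, b, g in
                 zip(spec.gene_template, spec.gene_template[1:], spec.planted_gaps)},
        "sizes": {name: length for name, _c, length, _s in spec.gene_template},
        "coordinates": {name: c for (name, *_), c in zip(spec.gene_template, coords)},
        "unannotated_length": (spec.first_start - 1) + (spec.genome_length - last_end),
        "realised_at_content": at,
        "realised_at_skew": sk,
        **planted,
    }
    return genome, truth


# ---------------------------------------------------------------------------
# Diverged codon pairs at a known dN/dS
# ---------------------------------------------------------------------------

@dataclass
class DivergenceSpec:
    """A codon-alignment pair diverged at target dN/dS ``omega``.

    Substitution events are proposed uniformly over positions and accepted
    with probability min(1, omega) when nonsynonymous and min(1, 1/omega)
    when synonymous, so the realised dN/dS (relative to site opportunity) has
    expectation omega.  Proposals creating stop codons are rejected outright.
    """

    n_codons: int
    omega: float
    expected_substitutions_per_codon: float = 0.3
    table_id: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


def evolve_codon_pair(spec: DivergenceSpec) -> tuple[str, str]:
    """(ancestral, derived) coding sequences per *spec*; deterministic in seed."""
    code = GeneticCode.from_ncbi_id(spec.table_id)
    rng = _rng(spec.seed, "codon_pair")
    sense = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
             if not code.is_stop(c)]
    seq_a = "".join(rng.choice(sense, size=spec.n_codons))
    seq_b = list(seq_a)
    p_syn = 1.0 if spec.omega <= 1 else 1.0 / spec.omega
    p_non = min(1.0, spec.omega)
    target = int(round(spec.n_codons * spec.expected_substitutions_per_codon))
    accepted = 0
    budget = 1000 + 500 * target
    while accepted < target and budget > 0:
        budget -= 1
        pos = int(rng.integers(0, 3 * spec.n_codons))
        old = seq_b[pos]
        new = "ACGT".replace(old, "")[int(rng.integers(0, 3))]
        ci = pos - pos % 3
        codon_old = "".join(seq_b[ci:ci + 3])
        codon_new = codon_old[:pos - ci] + new + codon_old[pos - ci + 1:]
        if code.is_stop(codon_new):
            continue
        synonymous = code.translate(codon_new) == code.translate(codon_old)
        p = p_syn if synonymous else p_non
        if p >= 1.0 or rng.random() < p:
            seq_b[pos] = new
            accepted += 1
    if accepted < target:
        warnings.warn(f"only {accepted}/{target} substitutions placed "
                      "(acceptance budget exhausted)")
    return seq_a, "".join(seq_b)


# ---------------------------------------------------------------------------
# tRNA structures with planted architecture
# ---------------------------------------------------------------------------

def _stem(rng: np.random.Generator, n_bp: int, n_gu: int) -> tuple[str, str]:
    """A 5' stem and its 3' partner with exactly *n_gu* planted G-U pairs."""
    five = [str(rng.choice(_BASES)) for _ in range(n_bp)]
    three = [_COMPLEMENT[b] for b in five][::-1]
    gu_at = rng.choice(n_bp, size=min(n_gu, n_bp), replace=False)
    for i in gu_at:
        if rng.random() < 0.5:
            five[i], three[n_bp - 1 - i] = "G", "T"
        else:
            five[i], three[n_bp - 1 - i] = "T", "G"
    return "".join(five), "".join(three)


def _loop(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def generate_trna(arch: str, seed: int = 0, *, acceptor_bp: int = 7,
                  d_bp: int = 4, d_loop: int = 5, ac_bp: int = 5,
                  ac_loop: int = 7, t_bp: int = 5, t_loop: int = 7,
                  variable_nt: int = 4, anticodon: str | None = None,
                  gu_pairs: int = 0, salt: int = 0) -> tuple[str, str]:
    """(sequence, dot-bracket) realising exactly the requested architecture.

    Missing arms (per *arch*) are replaced by unpaired stretches the size of
    the arm's loop.  ``gu_pairs`` wobble pairs are planted exactly, spread
    over the stems.  Sequence is RNA (ACGU after output conversion).
    """
    if arch not in (CLOVERLEAF, D_ARMLESS, T_ARMLESS, MINIMAL):
        raise ValueError(f"unknown architecture {arch!r}")
    rng = _rng(seed, "trna", salt)
    with_d = arch in (CLOVERLEAF, T_ARMLESS)
    with_t = arch in (CLOVERLEAF, D_ARMLESS)
    stems = [acceptor_bp, d_bp if with_d else 0, ac_bp, t_bp if with_t else 0]
    total_bp = sum(stems)
    if gu_pairs > total_bp:
        raise ValueError("more G-U pairs requested than stem base pairs")
    # spread the planted wobble pairs over the stems, largest first
    alloc = [0, 0, 0, 0]
    remaining = gu_pairs
    for i in sorted(range(4), key=lambda i: -stems[i]):
        take = min(stems[i], remaining)
        alloc[i], remaining = take, remaining - take

    seq_parts: list[str] = []
    dot_parts: list[str] = []

    def emit(s: str, d: str):
        seq_parts.append(s)
        dot_parts.append(d)

    acc5, acc3 = _stem(rng, acceptor_bp, alloc[0])
    emit(acc5, "(" * acceptor_bp)
    emit(_loop(rng, 2), "..")  # acceptor->D connector
    if with_d:
        d5, d3 = _stem(rng, d_bp, alloc[1])
        emit(d5, "(" * d_bp)
        emit(_loop(rng, d_loop), "." * d_loop)
        emit(d3, ")" * d_bp)
        emit(_loop(rng, 1), ".")
    else:
        emit(_loop(rng, d_loop), "." * d_loop)
    ac5, ac3 = _stem(rng, ac_bp, alloc[2])
    emit(ac5, "(" * ac_bp)
    loop = _loop(rng, ac_loop)
    if anticodon is not None:
        if len(anticodon) != 3 or ac_loop < 3:
            raise ValueError("anticodon must be a triplet fitting in the loop")
        mid = (ac_loop - 1) // 2  # 0-based centre of the loop
        ac_dna = anticodon.upper().replace("U", "T")
        loop = loop[:mid - 1] + ac_dna + loop[mid + 2:]
    emit(loop, "." * ac_loop)
    emit(ac3, ")" * ac_bp)
    emit(_loop(rng, variable_nt), "." * variable_nt)
    if with_t:
        t5, t3 = _stem(rng, t_bp, alloc[3])
        emit(t5, "(" * t_bp)
        emit(_loop(rng, t_loop), "." * t_loop)
        emit(t3, ")" * t_bp)
    else:
        emit(_loop(rng, t_loop), "." * t_loop)
    emit(acc3, ")" * acceptor_bp)
    emit(_loop(rng, 1), ".")  # discriminator
    seq = "".join(seq_parts).replace("T", "U")
    struct = "".join(dot_parts)
    assert len(seq) == len(struct)
    return seq, struct


# gene -> architecture assignment reported for the C. hesperidum tRNA set
CHESPERIDUM_TRNA_CLASSES: dict[str, str] = {
    **{g: CLOVERLEAF for g in ("trnD", "trnL1", "trnL2", "trnM", "trnW", "trnF", "trnK")},
    **{g: D_ARMLESS for g in ("trnA", "trnR", "trnN", "trnQ", "trnS2", "trnY", "trnV")},
    **{g: T_ARMLESS for g in ("trnC", "trnE", "trnG", "trnH", "trnI", "trnP", "trnT")},
    "trnS1": MINIMAL,
}


def generate_trna_set(classes: dict[str, str] | None = None,
                      seed: int = 7) -> list[tuple[str, str, str, str]]:
    """A full tRNA fixture set: [(gene, arch, sequence, dot-bracket), ...].

    Defaults to the 22-gene class assignment above (7 cloverleaf, 7 D-armless,
    7 T-armless, 1 minimal).  Arm lengths vary within the ranges typical of
    insect mitochondrial tRNAs.
    """
    classes = classes or CHESPERIDUM_TRNA_CLASSES
    rng = _rng(seed, "trna", 999)
    out = []
    for i, (gene, arch) in enumerate(sorted(classes.items())):
        seq, struct = generate_trna(
            arch, seed=seed, salt=i,
            acceptor_bp=int(rng.integers(6, 8)),
            d_bp=int(rng.integers(3, 5)), ac_bp=int(rng.integers(4, 6)),
            t_bp=int(rng.integers(2, 6)), ac_loop=7,
            gu_pairs=int(rng.integers(0, 3)))
        out.append((gene, arch, seq, struct))
    return out


# ---------------------------------------------------------------------------
# A genome spec mirroring the C. hesperidum gene table
# ---------------------------------------------------------------------------

# (name, start, end, strand, anticodon, start codon, stop token) as published
CHESPERIDUM_GENE_TABLE: list[tuple] = [
    ("trnM", 753, 818, "+", "CAU", None, None),
    ("trnW", 810, 870, "+", "UCA", None, None),
    ("COX1", 861, 2387, "+", None, "ATA", "TAA"),
    ("trnL2", 2388, 2449, "+", "UAA", None, None),
    ("COX2", 2450, 3113, "+", None, "ATA", "T"),
    ("trnK", 3114, 3183, "+", "UUU", None, None),
    ("trnD", 3180, 3244, "+", "GUC", None, None),
    ("ATP8", 3238, 3378, "+", None, "ATT", "TAA"),
    ("ATP6", 3372, 3989, "+", None, "ATG", "TAA"),
    ("COX3", 3991, 4752, "+", None, "ATG", "TAA"),
    ("trnG", 4752, 4809, "+", "UCC", None, None),
    ("ND3", 4807, 5145, "+", None, "ATA", "TAA"),
    ("trnA", 5146, 5203, "-", "UGC", None, None),
    ("trnR", 5202, 5249, "+", "UCG", None, None),
    ("trnN", 5241, 5294, "+", "GUU", None, None),
    ("trnS1", 5296, 5343, "+", "UCU", None, None),
    ("trnE", 5352, 5405, "+", "UUC", None, None),
    ("trnF", 5396, 5452, "-", "GAA", None, None),
    ("ND5", 5451, 7055, "-", None, "ATT", "TAA"),
    ("trnH", 7056, 7112, "-", "GUG", None, None),
    ("ND4", 7114, 8388, "-", None, "ATT", "TAA"),
    ("ND4L", 8401, 8655, "-", None, "ATT", "TAA"),
    ("ND6", 8696, 9172, "+", None, "ATT", "TAG"),
    ("trnP", 9179, 9241, "+", "UGG", None, None),
    ("trnQ", 9238, 9295, "-", "UUG", None, None),
    ("trnC", 9295, 9349, "-", "GCA", None, None),
    ("trnI", 9359, 9423, "+", "GAU", None, None),
    ("ND2", 9424, 10362, "+", None, "ATT", "TAA"),
    ("trnY", 10373, 10425, "+", "GUA", None, None),
    ("trnT", 10440, 10493, "+", "UGU", None, None),
    ("CYTB", 10501, 11568, "+", None, "ATA", "TAA"),
    ("trnS2", 11570, 11622, "+", "UGA", None, None),
    ("ND1", 11647, 12552, "-", None, "ATT", "TAA"),
    ("trnL1", 12553, 12615, "-", "UAG", None, None),
    ("rrnL", 12616, 13789, "-", None, None, None),
    ("trnV", 13790, 13835, "-", "UAC", None, None),
    ("rrnS", 13836, 14447, "-", None, None, None),
]

CHESPERIDUM_LENGTH = 15566

# Pooled PCG codon counts as published for C. hesperidum (fractional entries
# arise from ambiguity-code splitting); input data for RSCU worked examples.
CHESPERIDUM_CODON_COUNTS: dict[str, float] = {
    "TTA": 247, "TCA": 116, "ACA": 84, "GTT": 91, "CCA": 34, "GGA": 38,
    "TCT": 73, "CAA": 30, "CGA": 11, "TAA": 11, "GCA": 12, "ATA": 463,
    "AAA": 188, "TTT": 413, "CGT": 10, "GAT": 49, "ATT": 324, "TGA": 47,
    "GAA": 48, "GCT": 10, "GTA": 60, "TAT": 130, "TGT": 11, "AGA": 53,
    "AAT": 190, "CCT": 21, "GGT": 24, "CAT": 25, "ACT": 35, "AGT": 32,
    "CTT": 49, "CTA": 48, "CAC": 14, "TTG": 47, "AAC": 96, "GCC": 4,
    "GGG": 10, "TGC": 4, "TAC": 47, "GAG": 14, "ACC": 13, "CCC": 6,
    "TGG": 10, "TCC": 13, "ATC": 68, "CGG": 2, "GAC": 9, "TTC": 67,
    "AAG": 29, "ATG": 52, "CCG": 3, "TAG": 1, "AGG": 6, "GTC": 6,
    "GTG": 6, "GGC": 2, "CTC": 7, "ACG": 3, "CGC": 0.5, "TCG": 3,
    "GCG": 0.5, "CAG": 1, "AGC": 2, "CTG": 3,
}


def chesperidum_features() -> list[GeneFeature]:
    """The published gene table as model features (real coordinates)."""
    return [GeneFeature(name=n, gene_class=infer_gene_class(n), start=s, end=e,
                        strand=FORWARD if strand == "+" else REVERSE,
                        anticodon=ac)
            for n, s, e, strand, ac, _start, _stop in CHESPERIDUM_GENE_TABLE]


def chesperidum_like_spec(seed: int = 0) -> GenomeSpec:
    """A GenomeSpec replicating the published gene order, sizes and gaps."""
    template, gaps, starts, stops, anticodons = [], [], {}, {}, {}
    prev_end = None
    for name, s, e, strand, ac, start_codon, stop_token in CHESPERIDUM_GENE_TABLE:
        cls = infer_gene_class(name)
        template.append((name, cls, e - s + 1, FORWARD if strand == "+" else REVERSE))
        if prev_end is not None:
            gaps.append(s - prev_end - 1)
        prev_end = e
        if start_codon:
            starts[name] = start_codon
            stops[name] = stop_token
        if ac:
            anticodons[name] = ac
    return GenomeSpec(genome_length=CHESPERIDUM_LENGTH, gene_template=template,
                      planted_gaps=gaps, first_start=753,
                      at_content_target=0.834, at_skew_target=0.22,
                      gc_skew_target=-0.31, start_codons=starts,
                      stop_codons=stops, anticodons=anticodons, seed=seed)
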