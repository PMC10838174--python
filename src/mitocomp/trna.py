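"""tRNA secondary-structure decomposition and architecture classification.

Structures are *input* as Vienna dot-bracket strings (the folding itself is
done by external predictors); this module parses the pairing, splits it into
the acceptor stem and up to three interior stem-loops, assigns those to the
D, anticodon and T arms, and classifies the molecule:

* ``cloverleaf``  - D arm and T arm both present
* ``d_armless``   - D arm absent (replaced by a loop), T arm present
* ``t_armless``   - T arm absent, D arm present
* ``minimal``     - both absent, anticodon stem-loop only

An interior helix counts as an arm only when its stem has at least 2 base
pairs (mitochondrial T arms as short as 2 bp are real).  Helix-to-arm
assignment follows the canonical 5'->3' topology (D before anticodon before
T); when only two interior helices exist the anticodon arm is the one whose
loop midpoint lies nearest the middle of the molecule, and the other helix is
D or T according to whether it precedes or follows it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

CLOVERLEAF = "cloverleaf"
D_ARMLESS = "d_armless"
T_ARMLESS = "t_armless"
MINIMAL = "minimal"

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


class StructureError(ValueError):
    pass


def parse_dot_bracket(structure: str) -> dict[int, int]:
    """Dot-bracket string -> 1-based pairing map (an involution).

    Only ``(``, ``)`` and ``.`` are accepted, so crossing pairs (pseudoknots)
    cannot be expressed; unbalanced brackets raise :class:`StructureError`.
    """
    pairing: dict[int, int] = {}
    stack: list[int] = []
    for i, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairing[j] = i
            pairing[i] = j
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {i}")
    if stack:
        raise StructureError(f"unclosed '(' at position {stack[-1]}")
    return pairing


def _helices(pairing: dict[int, int]) -> list[list[tuple[int, int]]]:
    """Maximal stacked runs of pairs: (i,j),(i+1,j-1),... with no gaps."""
    pairs = sorted((i, j) for i, j in pairing.items() if i < j)
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:
        if helices and helices[-1][-1] == (p[0] - 1, p[1] + 1):
            helices[-1].append(p)
        else:
            helices.append([p])
    return helices


@dataclass(frozen=True)
class TRNAStructure:
    gene_name: str
    sequence: str
    pairing: dict[int, int]
    acceptor_stem_bp: int
    d_arm_bp: int          # 0 = arm absent
    anticodon_arm_bp: int
    anticodon_loop_nt: int
    t_arm_bp: int          # 0 = arm absent
    variable_region_nt: int
    discriminator: str | None
    anticodon: str
    gu_pairs: int
    mismatch_pairs: int
    arch_class: str


def count_gu_pairs(seq: str, pairing: dict[int, int]) -> int:
    """Number of base pairs that are G-U (wobble) in either orientation."""
    s = seq.upper().replace("T", "U")
    return sum(1 for i, j in pairing.items()
               if i < j and (s[i - 1], s[j - 1]) in _GU)


def _count_mismatches(seq: str, pairing: dict[int, int]) -> int:
    s = seq.upper().replace("T", "U")
    return sum(1 for i, j in pairing.items()
               if i < j and (s[i - 1], s[j - 1]) not in _WC | _GU)


def decompose_arms(seq: str, pairing: dict[int, int], gene_name: str = "",
                   min_stem_bp: int = 2) -> TRNAStructure:
    """Assign helices to tRNA arms and classify the architecture."""
    if len(seq) < 10:
        raise StructureError("sequence too short to be tRNA-like")
    helices = _helices(pairing)
    if not helices:
        raise StructureError("not tRNA-like: no base pairs at all")
    # acceptor stem = exterior helix enclosing every other pair
    exterior = helices[0]
    lo, hi = exterior[-1]  # innermost pair of the exterior helix
    inner = helices[1:]
    if any(h[0][0] < lo or h[0][1] > hi for h in inner):
        raise StructureError("not tRNA-like: no single exterior (acceptor) stem")
    arms = [h for h in inner if len(h) >= min_stem_bp]
    if len(arms) > 3 or len(arms) == 0:
        raise StructureError(f"not tRNA-like: {len(arms)} interior stem-loops")

    def loop_span(helix):
        (a, b) = helix[-1]  # innermost pair
        return a + 1, b - 1  # unpaired loop positions

    if len(arms) == 3:
        d_helix, ac_helix, t_helix = arms
    elif len(arms) == 1:
        d_helix, ac_helix, t_helix = None, arms[0], None
    else:  # two interior helices: anticodon arm sits nearest the middle
        centre = (len(seq) + 1) / 2.0
        def loop_centre(h):
            a, b = loop_span(h)
            return (a + b) / 2.0
        ac_helix = min(arms, key=lambda h: abs(loop_centre(h) - centre))
        other = arms[0] if arms[1] is ac_helix else arms[1]
        if other[0][0] < ac_helix[0][0]:
            d_helix, t_helix = other, None
        else:
            d_helix, t_helix = None, other

    ac_lo, ac_hi = loop_span(ac_helix)
    ac_loop = ac_hi - ac_lo + 1
    mid = (ac_lo + ac_hi) // 2
    anticodon = seq[mid - 2:mid + 1].upper().replace("T", "U")

    # variable region: unpaired stretch between anticodon arm and T arm
    ac_end = ac_helix[0][1]  # outermost 3' position of AC stem
    var_end = t_helix[0][0] if t_helix is not None else hi
    variable = max(0, var_end - ac_end - 1)

    # discriminator: last nucleotide of the unpaired 3' tail after the stem
    tail_start = exterior[0][1] + 1
    discriminator = seq[len(seq) - 1].upper().replace("T", "U") if tail_start <= len(seq) else None

    d_bp = len(d_helix) if d_helix else 0
    t_bp = len(t_helix) if t_helix else 0
    if d_bp and t_bp:
        arch = CLOVERLEAF
    elif t_bp:
        arch = D_ARMLESS
    elif d_bp:
        arch = T_ARMLESS
    else:
        arch = MINIMAL
    return TRNAStructure(
        gene_name=gene_name, sequence=seq, pairing=dict(pairing),
        acceptor_stem_bp=len(exterior), d_arm_bp=d_bp,
        anticodon_arm_bp=len(ac_helix), anticodon_loop_nt=ac_loop,
        t_arm_bp=t_bp, variable_region_nt=variable,
        discriminator=discriminator, anticodon=anticodon,
        gu_pairs=count_gu_pairs(seq, pairing),
        mismatch_pairs=_count_mismatches(seq, pairing),
        arch_class=arch)


def analyse_trna(seq: str, structure: str, gene_name: str = "") -> TRNAStructure:
    """Convenience: dot-bracket text straight to a decomposed structure."""
    if len(seq) != len(structure):
        raise StructureError(
            f"{gene_name or 'tRNA'}: sequence ({len(seq)}) and structure "
            f"({len(structure)}) lengths differ")
    return decompose_arms(seq, parse_dot_bracket(structure), gene_name)


def classify_set(structures: list[TRNAStructure]) -> tuple[Counter, list[tuple[str, str]]]:
    """(per-class counts, per-gene class table) for a set of tRNAs."""
    if not structures:
        raise ValueError("empty structure set")
    table = [(s.gene_name, s.arch_class) for s in structures]
    return Counter(s.arch_class for s in structures), table


def load_bundled_trna_set() -> list[tuple[str, str, str, str]]:
    """The packaged 22-gene tRNA structure set.

    Synthetic stand-ins generated by :func:`mitocomp.simulate.generate_trna`
    to match the architecture classes reported for the C. hesperidum tRNA set
    (7 cloverleaf, 7 D-armless, 7 T-armless, 1 minimal); these are not the
    experimentally predicted folds.  Returns
    ``[(gene, planted_class, sequence, dot_bracket), ...]``.
    """
    from importlib.resources import files

    text = files("mitocomp.data").joinpath("trna_structures_synthetic.tsv").read_text()
    rows = [ln.split("\t") for ln in text.splitlines()[1:] if ln.strip()]
    return [(g, a, s, d) for g, a, s, d in rows]


def read_structure_file(fasta_text: str, structure_text: str) -> list[tuple[str, str, str]]:
    """Pair a FASTA with a Vienna-style structure file.

    The structure file holds one dot-bracket line per FASTA record, in order
    (blank lines and ``>`` headers in it are ignored).  Returns
    ``[(name, sequence, structure), ...]``.
    """
    from .model import read_fasta
    seqs = read_fasta(fasta_text)
    lines = [ln.strip() for ln in structure_text.splitlines()
             if ln.strip() and not ln.startswith(">")]
    if len(lines) != len(seqs):
        raise StructureError(
            f"{len(seqs)} sequences but {len(lines)} structure lines")
    return [(name, seq, struct) for (name, seq), struct in zip(seqs.items(), lines)]
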