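# Methods

## Genome model and coordinates

The genome is a circular nucleotide string with an ordered list of gene
features. Coordinates are 1-based inclusive (the GenBank convention) end to
end; conversion to 0-based half-open intervals happens only at the Biopython
boundary. A feature crossing the origin is stored with `start > end` and an
explicit `wraps` flag; its size must be supplied because it depends on genome
length. The unannotated remainder (the putative control region — the largest
span in *C. hesperidum* runs 14,448–752, 1,871 bp) is never represented as a
feature: it is reported as the "largest unannotated span" without biological
labelling, because the source annotation does not name a control region.

Gene names are normalised case-insensitively through a synonym map
(CYTB/cob, rrnL/16S rRNA/l-rRNA, trnL1/trnL_1_, …) so GenBank records and
published tables interoperate. Ambiguity codes are preserved verbatim in
sequences; each downstream module decides how to treat them.

GenBank and FASTA reading/writing is delegated to Biopython (`SeqIO`);
genetic-code tables come from `Bio.Data.CodonTable`. `complement` locations
become reverse-strand features and two-part `join` locations bracketing the
origin become wrapping features. Real tRNA features sometimes lack an
anticodon qualifier, so the model allows a missing anticodon on tRNAs but
rejects anticodons on non-tRNA features.

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C). Per-gene rows are computed on
the gene's **coding strand** (reverse-strand genes reverse-complemented).
This is the accounting under which, in an A-rich genome, the reverse-strand
NADH genes show negative AT skew on their own rows — the pattern the
published per-gene table shows — and it makes reverse-complementation negate
both skews exactly, a property test. Aggregate rows ("13 PCGs", "22 tRNAs")
are computed on the concatenation of member sequences (length-weighted);
averaging percentages would weight a 48-bp tRNA like a 1,527-bp gene. The
"Total" row uses the deposited plus strand. Ambiguity codes are excluded
from numerator and denominator and tallied separately — the simplest
defensible choice where the convention is unstated. A zero denominator
yields NaN (an undefined-value sentinel), never an exception.

Printed-table comparisons round half away from zero at the printed
precision; internal values stay unrounded. When checking agreement with a
published table we accept half a unit in the last printed place, because a
value sitting exactly on a rounding tie (e.g. an RSCU of 1.3125) can be
printed either way depending on the tie-breaking convention of the original
software.

## Codon usage and RSCU

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial: ATA→Met, TGA→Trp, AGA/AGG→Ser, stops {TAA, TAG}); the table
is data, not logic, so the vertebrate code etc. are selectable by id.
Synonym families partition all 64 codons by translated symbol, with the stop
codons forming their own family — required to reproduce published RSCU rows
for TAA/TAG. RSCU(c) = count(c) × family size / family total; a family with
zero total gets NaN for all members (undefined, not zero).

Codons are consecutive non-overlapping triplets from position 1. A CDS whose
length is not a multiple of three ends in a 1–2 nt fragment, the incomplete
stop ("T"/"TA") completed to TAA by mRNA polyadenylation; fragments are
recorded as stop tokens but never counted as codons. The stop token of a CDS
is the trailing fragment when one exists, otherwise the final triplet when it
is a stop codon, otherwise a no-stop flag. Pooled codon counts include
complete terminal stop codons and support fractional values: under the
`split` ambiguity policy a codon containing IUPAC codes contributes 1/k to
each of its k concrete expansions (the plausible mechanism behind published
0.5 counts); the default policy `drop` discards such codons. Conservation
holds on unambiguous data: 3 × total counted codons + fragment lengths =
total PCG length.

## Gene architecture

Adjacency is defined on start-coordinate order of the mixed-strand gene list
(strand ignored), matching how published gene tables interleave strands.
Intergenic length = start(downstream) − end(upstream) − 1: negative =
overlap, 0 = abutting, positive = spacer. Pile-ups (a gene overlapping its
neighbour's neighbour) are reported only pairwise for consecutive features.
On a circular genome a final adjacency links last→first with gap =
(L − end(last)) + (start(first) − 1); it is computed but flagged separately,
since published tables omit it. On a fully annotated circle, Σ sizes +
Σ signed gaps (including the wrap) = L — a test invariant, together with
invariance of the results under rotation of the coordinate origin.

Recomputing the *C. hesperidum* adjacencies from the published coordinates
gives 13 overlaps and 13 spacers. The published intergenic column prints 14
negative and 12 positive entries, but its trnC→trnI entry (−10) contradicts
the coordinates printed beside it (9,295–9,349 → 9,359–9,423 is a +9
spacer). The package always reports coordinate-derived values; the
13-overlap count in fact agrees with the accompanying prose.

## Ka/Ks (Nei–Gojobori 1986)

The method is fixed to NG86 with equal pathway weighting and Jukes–Cantor
correction — the classic counting estimator used by descriptive mitogenome
studies (it is also what DnaSP computes as its standard Ka/Ks). Per codon,
the synonymous site count s is the sum over the three positions of the
fraction of the three possible single-nucleotide changes that preserve the
amino acid; changes creating a stop codon count as nonsynonymous; n = 3 − s.
S and N for a pair are means of the two per-sequence totals. Differences per
codon pair are resolved by enumerating all d! orderings of the d differing
positions with equal weights and averaging synonymous/nonsynonymous step
counts (implemented by recursive averaging; an independent test oracle
enumerates the permutations explicitly). Codons containing gaps, ambiguity
codes or stops in either sequence are excluded. ps = Sd/S and pn = Nd/N are
JC-corrected, d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 leaves the distance
undefined (NaN sentinel, never a silent log-domain error), as is Ka/Ks when
Ks = 0. Per-gene means average the defined pairwise ratios; undefined ratios
are excluded and counted rather than treated as 0 or ∞.

Codon alignments are an input. A helper threads nucleotides through a
user-supplied protein alignment (tolerating a terminal stop codon in the
CDS); the alignment itself is out of scope.

## tRNA structures

Structures are input as Vienna dot-bracket strings — the folds come from
external predictors, and re-predicting them would make the classification
untestable against a fixed truth. Parsing is stack-based; only `(`, `)` and
`.` are accepted, so pseudoknots cannot be expressed. The acceptor stem is
the exterior helix enclosing all other pairs; interior helices with ≥ 2 bp
count as arms (published mitochondrial T arms go down to 2 bp). Three
interior helices are assigned D, anticodon, T in 5′→3′ order — the canonical
topology. With two, the anticodon arm is the helix whose loop midpoint lies
nearest the middle of the molecule (the anticodon loop sits centrally in all
natural architectures) and the other helix is D or T by position; with one,
it is the anticodon arm and the class is "minimal". The discriminator is the
last nucleotide of the unpaired 3′ tail; the anticodon is the middle three
nucleotides of the anticodon loop; G-U pairs are counted over all paired
positions, and non-Watson-Crick, non-wobble pairs are counted as mismatches
rather than rejected (non-standard pairing does occur).

The packaged 22-structure set (`data/trna_structures_synthetic.tsv`) is
generated by the package's own tRNA generator to match the per-gene
architecture classes reported for *C. hesperidum* (7 cloverleaf, 7 D-armless,
7 T-armless, trnS1 minimal). It is a synthetic stand-in: the experimentally
predicted folds live in supplementary material not redistributed here, so
per-gene arm lengths and the genome-wide G-U totals are not treated as
reproducible targets.

## Synthetic data

One integer seed is threaded through named substreams (one per generator),
so adding a generator never perturbs another's output; every generator is
deterministic given (spec, seed).

**Genomes.** The default `GenomeSpec` mirrors the published *C. hesperidum*
organisation: 15,566 bp, the 37-gene order/strand pattern with its published
sizes and signed gaps, A+T target 0.834, plus-strand AT-skew target 0.22,
GC-skew −0.31, the published per-gene start codons and stop tokens
(including COX2's incomplete "T"). Background bases are sampled per position
from strand-aware probabilities; protein-coding genes are written as open
reading frames whose body codons are drawn from the base distribution
restricted to sense codons. Because ORFs exclude stop codons (which are
A+T-rich here), the background distribution is tilted analytically so the
whole plus strand still hits the targets; a rejection loop (≤ 100 attempts,
tolerance ±1 percentage point A+T, ±0.02 skew) then keeps the closest
attempt, warning if none qualifies. Planted overlaps are realised by
coordinate arithmetic; each gene's start/stop positions are locked as
written so a later overlapping gene cannot destroy them (a genuinely
conflicting plant raises an error instead of silently corrupting). A body
codon forced by an earlier lock can in principle be a stop; this does not
occur under the default template and would not affect start/stop calls,
which read only the CDS ends.

**Divergence.** `evolve_codon_pair` draws an ancestor of uniform sense
codons and applies sequential single-nucleotide events: proposals are
uniform over positions, changes creating stops are rejected, nonsynonymous
changes are accepted with probability min(1, ω) and synonymous ones with
min(1, 1/ω). Because proposals hit synonymous sites in proportion to their
NG86 opportunity, the realised dN/dS has expectation ω for any ω ≥ 0 (ω = 0
yields purely synonymous divergence). The event count is
round(n_codons × expected substitutions per codon), 0.3 by default — enough
divergence to estimate from, low enough that multiple hits stay modest.
This acceptance model was chosen over a full continuous-time codon model
for transparency; its realised dN/dS is verified by the NG86 estimator
itself (neutral calibration within ±0.15 of 1.0 over 10 × 500-codon
replicates, strict monotonicity over ω ∈ {0.2, 1, 2} — the problem sizes
used throughout the validation suite).

**What the generator does not emulate:** indels, heteroplasmy, realistic
evolution along a phylogeny, codon-position-specific rate structure, or the
within-genome heterogeneity of real composition. Passing tests therefore
demonstrate correctness of the arithmetic and the estimators under the
stated model, not robustness to every feature of real data.

## Numerical conventions

NaN is the uniform undefined-value sentinel (zero-denominator skews,
zero-total RSCU families, JC out-of-domain distances, Ka/Ks with Ks = 0);
all means and summaries exclude it explicitly. Rounding for printed-table
output is half away from zero. Feature lists sort by (start, end);
overlap/spacer lists sort by length descending with coordinate ties. The
`printed` rounding mode uses percentages to 1 d.p., per-gene skews to
2 d.p., whole-genome skews and RSCU to 3 d.p.; `raw` mode emits full
precision, and identical inputs produce byte-identical outputs (timestamps
appear only in logs, which go to standard error).

## Known limitations

* The GenBank reader handles the single-record flat files typical of
  mitogenome submissions; multi-record files are rejected.
* Wrap-around support assumes a two-part join whose parts touch the sequence
  ends; more exotic compound locations are read as simple spans.
* Arm assignment assumes at most three interior stem-loops; heavily bulged
  folds that fragment a stem into >3 helix runs are reported as
  "not tRNA-like" rather than guessed at.
* NG86 is a counting method: at high divergence (p → 3/4) distances become
  undefined, and no correction for transition/transversion bias or codon
  frequencies is applied (by design — it reproduces the classic estimator).
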