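"""Table-style reports over one or many genomes.

Three per-genome tables mirror the layout of a published mitogenome paper:
a gene table (coordinates, sizes, start/stop codons, intergenic lengths), a
composition table (per gene / per class / total, with AT and GC skews) and an
RSCU codon-usage table.  The comparative report adds one row per genome
(length, A+T%, skews for the whole genome and for the PCG set) and, when
aligned CDS sets are supplied, a per-gene Ka/Ks table.

Rounding: ``printed`` mode rounds half away from zero at the precision the
field's tables conventionally use (percentages 1 d.p., per-gene skews 2 d.p.,
whole-genome skews 3 d.p., RSCU 3 d.p.); ``raw`` mode leaves full precision.
All numbers are recomputed from sequence, never copied from the input
annotation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import architecture, codons, composition, kaks
from .model import PCG, MitoGenome, extract_gene_sequence


def round_half_away(x: float, digits: int) -> float:
    """Round half away from zero (printed-table convention), NaN-safe."""
    if x != x:
        return x
    scale = 10 ** digits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass
class RunConfig:
    genbank: str | None = None
    fasta: str | None = None
    feature_table: str | None = None
    genetic_code_id: int = 5
    ambiguity_policy: str = "drop"
    output_format: str = "tsv"   # tsv | json
    rounding: str = "printed"    # printed | raw
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        has_gb = self.genbank is not None
        has_ft = self.fasta is not None or self.feature_table is not None
        if has_gb and has_ft:
            raise ValueError("give either a GenBank file or fasta+feature table, not both")
        if (self.fasta is None) != (self.feature_table is None):
            raise ValueError("fasta and feature table must be given together")
        if self.ambiguity_policy not in ("drop", "split"):
            raise ValueError(f"unknown ambiguity policy {self.ambiguity_policy!r}")
        if self.rounding not in ("printed", "raw"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")


def gene_table(genome: MitoGenome, code: codons.GeneticCode) -> pd.DataFrame:
    """Gene table with recomputed sizes, start/stop codons and gap column."""
    gaps = architecture.adjacency_gaps(genome.features, genome.length_bp,
                                       genome.is_circular)
    gap_by_down = {r.downstream_gene: r.intergenic_length
                   for r in gaps if not r.is_wrap}
    startstop = codons.gene_start_stops(genome, code)
    rows = []
    for f in genome.features:
        start_c, stop_c = startstop.get(f.name, ("", ""))
        rows.append({
            "gene": f.name, "class": f.gene_class, "start": f.start, "end": f.end,
            "size_bp": f.size_bp, "strand": f.strand,
            "start_codon": start_c, "stop_codon": stop_c,
            "anticodon": f.anticodon or "",
            "intergenic_length": gap_by_down.get(f.name, pd.NA),
        })
    return pd.DataFrame(rows)


def composition_table(genome: MitoGenome, rounding: str = "raw") -> pd.DataFrame:
    rows = [r.as_dict() for r in composition.composition_table(genome)]
    df = pd.DataFrame(rows)
    if rounding == "printed":
        for col in ("A(%)", "T(%)", "G(%)", "C(%)", "A+T(%)"):
            df[col] = df[col].map(lambda x: round_half_away(x, 1))
        for col in ("AT-skew", "GC-skew"):
            df[col] = df[col].map(lambda x: round_half_away(x, 2))
    return df


def rscu_table(genome: MitoGenome, code: codons.GeneticCode,
               ambiguity_policy: str = "drop", rounding: str = "raw") -> pd.DataFrame:
    counts = codons.count_codons(genome, code, ambiguity_policy)
    table = codons.rscu(counts, code)
    df = pd.DataFrame(table.rows())
    if rounding == "printed":
        df["RSCU"] = df["RSCU"].map(lambda x: round_half_away(x, 3))
    return df


def run_genome_report(genome: MitoGenome, config: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """All three per-genome tables plus an architecture summary."""
    config = config or RunConfig(genbank="-")
    code = codons.GeneticCode.from_ncbi_id(config.genetic_code_id)
    out = {"genes": gene_table(genome, code),
           "composition": composition_table(genome, config.rounding)}
    if genome.features_of_class(PCG):
        out["rscu"] = rscu_table(genome, code, config.ambiguity_policy, config.rounding)
    else:
        warnings.warn("no protein-coding features: RSCU table skipped")
    records = architecture.adjacency_gaps(genome.features, genome.length_bp,
                                          genome.is_circular)
    summary = architecture.architecture_summary(records)
    span = architecture.largest_unannotated_span(genome)
    summary["largest_unannotated_span"] = {"start": span[0], "end": span[1],
                                           "length": span[2]}
    out["architecture"] = pd.DataFrame([summary])
    return out


def comparative_table(genomes: list[MitoGenome], rounding: str = "raw") -> pd.DataFrame:
    """One row per genome: whole-genome and PCG-set length, A+T% and skews."""
    rows = []
    for g in genomes:
        total = composition.base_composition(g.sequence, g.identifier)
        pcg_feats = g.features_of_class(PCG)
        row = {"genome": g.identifier, "length_bp": g.length_bp,
               "A+T(%)": total.at_content, "AT-skew": total.at_skew,
               "GC-skew": total.gc_skew}
        if pcg_feats:
            pcg_seq = "".join(extract_gene_sequence(g, f) for f in pcg_feats)
            pcg = composition.base_composition(pcg_seq, "PCGs")
            row.update({"PCG_length_bp": len(pcg_seq), "PCG_A+T(%)": pcg.at_content,
                        "PCG_AT-skew": pcg.at_skew, "PCG_GC-skew": pcg.gc_skew})
        rows.append(row)
    df = pd.DataFrame(rows)
    if rounding == "printed":
        for col in df.columns:
            if col.endswith("(%)"):
                df[col] = df[col].map(lambda x: round_half_away(x, 1))
            elif col.endswith("skew"):
                df[col] = df[col].map(lambda x: round_half_away(x, 3))
    return df


def kaks_table(cds_sets: dict[str, dict[str, str]],
               code: codons.GeneticCode) -> pd.DataFrame:
    """Per-gene NG86 summary over {gene: {species: aligned CDS}} inputs."""
    rows = []
    for gene, by_species in sorted(cds_sets.items()):
        if len(by_species) < 2:
            warnings.warn(f"{gene}: fewer than two sequences, Ka/Ks skipped")
            rows.append({"gene": gene, "n_pairs": 0})
            continue
        pairs = kaks.all_pairs_kaks(by_species, code)
        mean = kaks.mean_kaks(pairs.values())
        agg = {k: sum(getattr(r, k) for r in pairs.values()) / len(pairs)
               for k in ("S_sites", "N_sites", "Sd", "Nd")}
        def_ka = [r.Ka for r in pairs.values() if kaks.is_defined(r.Ka)]
        def_ks = [r.Ks for r in pairs.values() if kaks.is_defined(r.Ks)]
        rows.append({
            "gene": gene, "S": agg["S_sites"], "N": agg["N_sites"],
            "Sd": agg["Sd"], "Nd": agg["Nd"],
            "Ka": sum(def_ka) / len(def_ka) if def_ka else math.nan,
            "Ks": sum(def_ks) / len(def_ks) if def_ks else math.nan,
            "mean_ratio": mean.mean, "n_pairs": mean.n_used,
            "n_undefined": mean.n_undefined,
        })
    return pd.DataFrame(rows)


def run_comparative_report(genomes: list[MitoGenome],
                           cds_sets: dict[str, dict[str, str]] | None = None,
                           config: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    config = config or RunConfig(genbank="-")
    out = {"genomes": comparative_table(genomes, config.rounding)}
    if cds_sets:
        if len(genomes) < 2 and all(len(v) < 2 for v in cds_sets.values()):
            warnings.warn("Ka/Ks needs at least two sequences per gene")
        code = codons.GeneticCode.from_ncbi_id(config.genetic_code_id)
        out["kaks"] = kaks_table(cds_sets, code)
    elif len(genomes) < 2:
        warnings.warn("single genome: comparative table emitted, Ka/Ks skipped")
    return out


def write_tables(tables: dict[str, pd.DataFrame], out_dir, fmt: str = "tsv") -> list[str]:
    """Write each table as <name>.tsv or <name>.json under *out_dir*."""
    import pathlib

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out_dir / f"{name}.{fmt}"
        if fmt == "tsv":
            df.to_csv(path, sep="\t", index=False)
        elif fmt == "json":
            path.write_text(json.dumps(df.to_dict(orient="records"), indent=1,
                                       default=str) + "\n")
        else:
            raise ValueError(f"unknown output format {fmt!r}")
        written.append(str(path))
    return written
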