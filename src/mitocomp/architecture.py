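"""Adjacent-gene spacing on a circular genome.

For consecutive features (start-coordinate order, strands interleaved) the
intergenic length is ``start(downstream) - end(upstream) - 1``: negative for
an overlap, zero for abutting genes, positive for a spacer.  On a circular
genome a final adjacency links the last feature back to the first across the
origin; it is computed but flagged, since published gene tables usually omit
it.  Multi-gene pile-ups are reported only pairwise for consecutive features.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass

from .model import GeneFeature, MitoGenome, ValidationError


@dataclass(frozen=True)
class AdjacencyRecord:
    upstream_gene: str
    downstream_gene: str
    intergenic_length: int  # negative = overlap, 0 = abutting, positive = spacer
    region: tuple[int, int] | None  # 1-based inclusive span of the gap/overlap
    is_wrap: bool = False

    @property
    def overlap_length(self) -> int:
        return -self.intergenic_length if self.intergenic_length < 0 else 0


def adjacency_gaps(features: list[GeneFeature], genome_length: int,
                   circular: bool = True) -> list[AdjacencyRecord]:
    """One record per consecutive feature pair, plus the wrap adjacency."""
    if any(features[i].start > features[i + 1].start for i in range(len(features) - 1)):
        raise ValidationError("features must be sorted by start coordinate")
    records = []
    for up, down in zip(features, features[1:]):
        gap = down.start - up.end - 1
        if gap > 0:
            region = (up.end + 1, down.start - 1)
        elif gap < 0:
            region = (down.start, min(up.end, down.end))
        else:
            region = None
        records.append(AdjacencyRecord(up.name, down.name, gap, region))
    if circular and len(features) >= 2:
        first, last = features[0], features[-1]
        gap = (genome_length - last.end) + (first.start - 1)
        region = None
        if gap > 0:
            region = (last.end + 1 if last.end < genome_length else 1,
                      first.start - 1 if first.start > 1 else genome_length)
        records.append(AdjacencyRecord(last.name, first.name, gap, region, is_wrap=True))
    return records


def _nonwrap(records):
    return [r for r in records if not r.is_wrap]


def overlap_regions(records: list[AdjacencyRecord],
                    include_wrap: bool = False) -> list[AdjacencyRecord]:
    """Overlapping adjacencies, longest first (ties by coordinate)."""
    pool = records if include_wrap else _nonwrap(records)
    hits = [r for r in pool if r.intergenic_length < 0]
    return sorted(hits, key=lambda r: (r.intergenic_length, r.region or (0, 0)))


def spacer_regions(records: list[AdjacencyRecord],
                   include_wrap: bool = False) -> list[AdjacencyRecord]:
    """Spacer adjacencies, longest first (ties by coordinate)."""
    pool = records if include_wrap else _nonwrap(records)
    hits = [r for r in pool if r.intergenic_length > 0]
    return sorted(hits, key=lambda r: (-r.intergenic_length, r.region or (0, 0)))


def largest_unannotated_span(genome: MitoGenome) -> tuple[int, int, int]:
    """(start, end, length) of the longest feature-free run of positions.

    Honours circular wrap: uncovered arcs touching the origin from both sides
    merge into one span (returned with start > end in that case).  A fully
    covered genome gives length 0.
    """
    n = genome.length_bp
    covered = np.zeros(n, dtype=bool)
    for f in genome.features:
        if f.wraps:
            covered[f.start - 1:] = True
            covered[:f.end] = True
        else:
            covered[f.start - 1:f.end] = True
    if covered.all():
        return (0, 0, 0)
    # maximal uncovered runs
    runs = []
    i = 0
    while i < n:
        if not covered[i]:
            j = i
            while j < n and not covered[j]:
                j += 1
            runs.append([i + 1, j, j - i])  # 1-based inclusive
            i = j
        else:
            i += 1
    if genome.is_circular and len(runs) >= 2 and runs[0][0] == 1 and runs[-1][1] == n:
        head = runs.pop(0)
        tail = runs.pop() if runs else None
        if tail is not None:
            runs.append([tail[0], head[1], head[2] + tail[2]])
        else:  # single run spanning everything
            runs.append(head)
    best = max(runs, key=lambda r: r[2])
    return (best[0], best[1], best[2])


def architecture_summary(records: list[AdjacencyRecord]) -> dict:
    """Counts and extremes over the non-wrap adjacencies."""
    overlaps = overlap_regions(records)
    spacers = spacer_regions(records)
    return {
        "n_overlaps": len(overlaps),
        "n_spacers": len(spacers),
        "longest_overlap": overlaps[0].overlap_length if overlaps else 0,
        "longest_spacer": spacers[0].intergenic_length if spacers else 0,
    }
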