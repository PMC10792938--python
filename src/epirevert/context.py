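"""Genomic-context annotation at base-pair resolution.

Partitions a genome into CpG-island-related categories (island, shore, shelf,
ocean: a shore is within 2 kb of an island, a shelf within 2 kb of a shore)
and into gene-related categories (exon, intron, intergenic), computes the
bp-level composition of region sets against either partition, compares a
composition to the genome background by Pearson chi-square, assigns the
nearest flanking genes of a region by TSS distance, and labels expression
change from log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as ivl

CPG_CATEGORIES = ("island", "shore", "shelf", "ocean")
GENE_CATEGORIES = ("exon", "intron", "intergenic")

SHORE_FLANK = 2000  # bp from island to the outer edge of the shore
SHELF_FLANK = 2000  # bp from shore to the outer edge of the shelf


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, CpG coordinates, islands, gene models and feature tracks.

    All coordinates are 0-based half-open.  ``cpg_positions`` maps chromosome
    to a sorted array of CpG start positions; ``islands`` and every entry of
    ``feature_tracks`` map chromosome to a merged (N, 2) interval array.
    ``genes`` is a DataFrame with columns gene_id, chrom, strand, tss, start,
    end, exons (list of (start, end) pairs inside the gene span).
    """

    chromosomes: dict[str, int]
    cpg_positions: dict[str, np.ndarray]
    islands: dict[str, np.ndarray]
    genes: pd.DataFrame
    feature_tracks: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, pos in self.cpg_positions.items():
            if chrom not in self.chromosomes:
                raise ValueError(f"CpG positions on unknown chromosome {chrom!r}")
            pos = np.asarray(pos, dtype=np.int64)
            if len(pos) and (pos[0] < 0 or pos[-1] >= self.chromosomes[chrom]):
                raise ValueError(f"CpG position out of bounds on {chrom}")
            self.cpg_positions[chrom] = pos
        for chrom, iv in self.islands.items():
            iv = ivl.merge(iv)
            if len(iv) and (iv[0, 0] < 0 or iv[-1, 1] > self.chromosomes[chrom]):
                raise ValueError(f"island out of bounds on {chrom}")
            self.islands[chrom] = iv

    def cpg_count(self, chrom: str, start: int, end: int) -> int:
        pos = self.cpg_positions.get(chrom)
        if pos is None or len(pos) == 0:
            return 0
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())


@dataclass
class ContextComposition:
    """bp counts per category of one partition; fractions sum to 1."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / t for k, v in self.counts.items()}

    def __add__(self, other: "ContextComposition") -> "ContextComposition":
        keys = set(self.counts) | set(other.counts)
        return ContextComposition(
            {k: self.counts.get(k, 0) + other.counts.get(k, 0) for k in keys}
        )


Partition = dict[str, dict[str, np.ndarray]]  # category -> chrom -> intervals


def build_cpg_context(
    islands: Mapping[str, np.ndarray],
    chromosomes: Mapping[str, int],
    flank: int = SHORE_FLANK,
) -> Partition:
    """Partition every chromosome into island / shore / shelf / ocean.

    Shores extend ``flank`` bp out from islands, shelves a further ``flank``
    bp out from shores; precedence island > shore > shelf resolves overlaps,
    and ocean is everything else.  The four interval sets tile each
    chromosome exactly.
    """
    part: Partition = {c: {} for c in CPG_CATEGORIES}
    for chrom, length in chromosomes.items():
        isl = ivl.merge(islands.get(chrom, np.empty((0, 2), dtype=np.int64)))
        if len(isl) and (isl[0, 0] < 0 or isl[-1, 1] > length):
            raise ValueError(f"island out of bounds on {chrom}")
        shore_u = ivl.expand(isl, flank, length)
        shelf_u = ivl.expand(shore_u, flank, length)
        part["island"][chrom] = isl
        part["shore"][chrom] = ivl.subtract(shore_u, isl)
        part["shelf"][chrom] = ivl.subtract(shelf_u, shore_u)
        part["ocean"][chrom] = ivl.complement(shelf_u, length)
    return part


def build_gene_context(
    genes: pd.DataFrame, chromosomes: Mapping[str, int]
) -> Partition:
    """Partition every chromosome into exon / intron / intergenic.

    Exons take precedence over introns where transcripts overlap; introns are
    gene-span bp not covered by any exon; intergenic is the rest.
    """
    part: Partition = {c: {} for c in GENE_CATEGORIES}
    for chrom, length in chromosomes.items():
        sub = genes[genes["chrom"] == chrom] if len(genes) else genes
        spans = []
        exons = []
        for _, g in sub.iterrows():
            spans.append((g["start"], g["end"]))
            exons.extend(g["exons"])
        span_iv = ivl.merge(spans) if spans else np.empty((0, 2), dtype=np.int64)
        exon_iv = ivl.merge(exons) if exons else np.empty((0, 2), dtype=np.int64)
        part["exon"][chrom] = exon_iv
        part["intron"][chrom] = ivl.subtract(span_iv, exon_iv)
        part["intergenic"][chrom] = ivl.complement(span_iv, length)
    return part


def _region_composition(
    chrom: str, start: int, end: int, partition: Partition
) -> ContextComposition:
    counts = {}
    for cat, per_chrom in partition.items():
        iv = per_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))
        counts[cat] = ivl.overlap_bp(start, end, iv)
    return ContextComposition(counts)


def annotate_region_context(
    region: tuple[str, int, int], cpg_partition: Partition
) -> ContextComposition:
    """bp overlap of one region with the island/shore/shelf/ocean partition."""
    return _region_composition(*region, cpg_partition)


def annotate_gene_context(
    region: tuple[str, int, int], gene_partition: Partition
) -> ContextComposition:
    """bp overlap of one region with the exon/intron/intergenic partition."""
    return _region_composition(*region, gene_partition)


def regions_composition(regions, partition: Partition) -> ContextComposition:
    """Summed composition of a region list (disjoint-union additivity)."""
    total = ContextComposition({cat: 0 for cat in partition})
    for chrom, start, end in regions:
        total = total + _region_composition(chrom, start, end, partition)
    return total


def genome_composition(partition: Partition) -> ContextComposition:
    """Composition of the whole genome under a partition (the background)."""
    return ContextComposition(
        {
            cat: sum(ivl.total_length(iv) for iv in per_chrom.values())
            for cat, per_chrom in partition.items()
        }
    )


def composition_chisq(
    observed: ContextComposition, background: ContextComposition
) -> tuple[float, float]:
    """Pearson chi-square of observed bp counts against background fractions.

    Expected counts are background fractions scaled to the observed total;
    dof = categories - 1.  Categories absent from both are dropped; a
    category observed but absent from the background is an error.
    """
    cats = [c for c in observed.counts if c in background.counts]
    obs = np.array([observed.counts[c] for c in cats], dtype=float)
    bg = np.array([background.fractions[c] for c in cats], dtype=float)
    if obs.sum() == 0:
        raise ValueError("observed composition is all zero")
    keep = ~((obs == 0) & (bg == 0))
    obs, bg = obs[keep], bg[keep]
    if np.any((bg == 0) & (obs > 0)):
        bad = [c for c, o, b in zip(cats, obs, bg) if b == 0 and o > 0]
        raise ValueError(f"observed counts in categories with zero background: {bad}")
    expected = bg / bg.sum() * obs.sum()
    stat, p = stats.chisquare(obs, expected)
    return float(stat), float(p)


@dataclass
class NearestGene:
    gene_id: str
    distance: int  # signed: negative = gene TSS left of the region, 0 = inside
    side: str  # "left", "right" or "inside"


def nearest_flanking_genes(
    region: tuple[str, int, int], genes: pd.DataFrame
) -> list[NearestGene]:
    """The nearest TSS on each side of a region (distance 0 if inside).

    Ties are broken by lower TSS coordinate, then lexicographic gene id.
    A chromosome without genes yields an empty list; a side without a gene is
    simply absent from the result.
    """
    chrom, start, end = region
    sub = genes[genes["chrom"] == chrom]
    if len(sub) == 0:
        return []
    sub = sub.sort_values(["tss", "gene_id"], kind="stable")
    tss = sub["tss"].to_numpy()
    ids = sub["gene_id"].to_numpy()

    inside = (tss >= start) & (tss < end)
    if inside.any():
        i = int(np.flatnonzero(inside)[0])
        return [NearestGene(str(ids[i]), 0, "inside")]

    out: list[NearestGene] = []
    left = np.flatnonzero(tss < start)
    if len(left):
        # nearest on the left = greatest TSS < start; ties at equal distance
        # resolve to the lower coordinate, i.e. the first of the tied block
        d = start - tss[left]
        best = d.min()
        cands = left[d == best]
        i = int(cands[0])
        out.append(NearestGene(str(ids[i]), -int(best), "left"))
    right = np.flatnonzero(tss >= end)
    if len(right):
        d = tss[right] - (end - 1)  # distance from the last covered bp
        best = d.min()
        cands = right[d == best]
        i = int(cands[0])
        out.append(NearestGene(str(ids[i]), int(best), "right"))
    return out


def label_expression_change(log2fc: float, threshold: float = 1.0) -> str:
    """up / down / neutral from a log2 fold change at a strict threshold."""
    if not np.isfinite(log2fc):
        raise ValueError("log2 fold change must be finite")
    if log2fc > threshold:
        return "up"
    if log2fc < -threshold:
        return "down"
    return "neutral"


def overlap_fraction(regions, track: Mapping[str, np.ndarray]) -> float:
    """Fraction of regions overlapping >= 1 feature interval (half-open)."""
    regions = list(regions)
    if not regions:
        return 0.0
    hits = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, pairs in by_chrom.items():
        iv = track.get(chrom, np.empty((0, 2), dtype=np.int64))
        arr = np.asarray(pairs, dtype=np.int64)
        hits += int(ivl.overlaps_any(arr[:, 0], arr[:, 1], ivl.merge(iv)).sum())
    return hits / len(regions)
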