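"""Overlap candidate regions with gene models and QTL intervals.

"Within or overlapping" is implemented as a >= 1 bp overlap on half-open
coordinates (containment is subsumed). Trait classes for the QTL tally are
taken verbatim from the BED payload; no ontology mapping is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .core import GenomicInterval
from .sweep_scan import SweepRegion


@dataclass
class RegionAnnotation:
    region: GenomicInterval
    genes: list[tuple[str, int]] = field(default_factory=list)  # (payload, bp)
    qtls: list[tuple[str, int]] = field(default_factory=list)


def _build_trees(features: list[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    return trees


def _check_chroms(regions, features, what: str) -> None:
    rc = {r.chrom for r in regions}
    fc = {f.chrom for f in features}
    unmatched = sorted(rc - fc)
    if unmatched and fc:
        warnings.warn(
            f"region chromosomes with no {what} feature: {unmatched}"
        )


def genes_in_regions(
    regions: list[GenomicInterval],
    gene_intervals: list[GenomicInterval],
) -> tuple[list[RegionAnnotation], list[str]]:
    """Interval-tree join of regions against gene models (>= 1 bp rule).

    Returns one annotation per region (each gene once per region, with the
    overlap in bp) and a deduplicated, order-stable global gene list.
    """
    _check_chroms(regions, gene_intervals, "gene")
    trees = _build_trees(gene_intervals)
    annotations: list[RegionAnnotation] = []
    global_genes: dict[str, None] = {}
    for region in regions:
        ann = RegionAnnotation(region=region)
        tree = trees.get(region.chrom)
        if tree is not None:
            hits = sorted(tree.overlap(region.start, region.end),
                          key=lambda h: (h.begin, h.end, str(h.data.payload)))
            seen: set[str] = set()
            for hit in hits:
                gene: GenomicInterval = hit.data
                label = gene.payload or f"{gene.chrom}:{gene.start}-{gene.end}"
                if label in seen:
                    continue
                seen.add(label)
                ann.genes.append((label, region.overlap_bp(gene)))
                global_genes.setdefault(label, None)
        annotations.append(ann)
    return annotations, list(global_genes)


def qtl_overlap(
    regions: list[GenomicInterval],
    qtl_intervals: list[GenomicInterval],
) -> tuple[list[RegionAnnotation], dict[str, int], dict[str, float]]:
    """Join regions against QTL intervals and tally overlapping QTLs by trait.

    A QTL is counted once even if it overlaps several regions. Returns the
    per-region annotations, the per-trait counts, and the per-trait fraction
    of all overlapping QTLs.
    """
    _check_chroms(regions, qtl_intervals, "QTL")
    trees = _build_trees(qtl_intervals)
    annotations: list[RegionAnnotation] = []
    hit_qtls: dict[int, GenomicInterval] = {}
    for region in regions:
        ann = RegionAnnotation(region=region)
        tree = trees.get(region.chrom)
        if tree is not None:
            hits = sorted(tree.overlap(region.start, region.end),
                          key=lambda h: (h.begin, h.end, str(h.data.payload)))
            for hit in hits:
                qtl: GenomicInterval = hit.data
                ann.qtls.append((qtl.payload or ".", region.overlap_bp(qtl)))
                hit_qtls[id(qtl)] = qtl
        annotations.append(ann)
    tally: dict[str, int] = {}
    for qtl in hit_qtls.values():
        trait = qtl.payload or "."
        tally[trait] = tally.get(trait, 0) + 1
    total = sum(tally.values())
    fractions = {t: c / total for t, c in tally.items()} if total else {}
    return annotations, tally, fractions


def regions_as_intervals(regions: list[SweepRegion]) -> list[GenomicInterval]:
    return [r.interval for r in regions]
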