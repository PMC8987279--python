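"""Readers and writers for the formats the pipeline touches.

VCF parsing goes through cyvcf2; multi-allelic and non-SNV records are dropped
(with a logged count) rather than split, because every downstream statistic is
defined on biallelic SNVs. The VCF writer emits a minimal GT-only VCF v4.2 so
that read -> write -> read is an identity on genotypes, positions and phase
flags.
"""

from __future__ import annotations

import logging
import math
import warnings
from pathlib import Path

import gffutils.feature
import numpy as np
from cyvcf2 import VCF

from .core import ChromData, GenomicInterval, HaplotypePanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- popmap ----

def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample population`` whitespace-separated map."""
    pop_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample pop'")
            pop_of[parts[0]] = parts[1]
    return pop_of


def write_popmap(pop_of: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in pop_of.items():
            fh.write(f"{sample}\t{pop}\n")


# ------------------------------------------------------------------- VCF ----

def read_vcf(path: str | Path, popmap_path: str | Path) -> HaplotypePanel:
    """Load a multi-sample VCF plus population map into a HaplotypePanel.

    Multi-allelic and non-SNV records are dropped (count logged). Sites are
    position-sorted per chromosome. Raises if the popmap is missing a sample.
    """
    pop_of = read_popmap(popmap_path)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_of]
    if absent:
        raise ValueError(f"popmap is missing samples: {absent}")

    chrom_lengths: dict[str, int] = {}
    try:
        seqlens = vcf.seqlens
    except AttributeError:  # header without contig lengths
        seqlens = []
    for name, length in zip(vcf.seqnames, seqlens):
        if length:
            chrom_lengths[name] = int(length)

    records: dict[str, list] = {}
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        gts = v.genotypes  # per sample: [a0, a1, phased]
        gt = np.empty((len(samples), 2), dtype=np.int8)
        phased = np.empty(len(samples), dtype=bool)
        for i, g in enumerate(gts):
            gt[i, 0] = g[0] if g[0] >= 0 else -1
            gt[i, 1] = g[1] if len(g) > 2 and g[1] >= 0 else -1
            phased[i] = bool(g[-1])
        qual = v.QUAL if v.QUAL is not None else math.nan
        records.setdefault(v.CHROM, []).append(
            (v.POS, v.REF, v.ALT[0], qual, gt, phased)
        )
    if n_dropped:
        logger.info("dropped %d multi-allelic/non-SNV records", n_dropped)

    chroms: dict[str, ChromData] = {}
    for chrom, recs in records.items():
        recs.sort(key=lambda r: r[0])
        pos = np.array([r[0] for r in recs], dtype=np.int64)
        chroms[chrom] = ChromData(
            pos=pos,
            ref=np.array([r[1] for r in recs]),
            alt=np.array([r[2] for r in recs]),
            qual=np.array([r[3] for r in recs], dtype=np.float64),
            gt=np.stack([r[4] for r in recs]),
            phased=np.stack([r[5] for r in recs]),
        )
        chrom_lengths.setdefault(chrom, int(pos.max()))

    panel = HaplotypePanel(
        samples=samples,
        pop_of={s: pop_of[s] for s in samples},
        chroms=chroms,
        chrom_lengths=chrom_lengths,
    )
    panel.n_dropped_records = n_dropped  # type: ignore[attr-defined]
    return panel


def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal GT-only VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for chrom in sorted(panel.chrom_lengths):
            fh.write(
                f"##contig=<ID={chrom},length={panel.chrom_lengths[chrom]}>\n"
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for chrom in sorted(panel.chroms):
            d = panel.chroms[chrom]
            for i in range(d.n_sites):
                qual = d.qual[i]
                qual_s = "." if math.isnan(qual) else f"{qual:g}"
                gts = []
                for j in range(panel.n_samples):
                    sep = "|" if d.phased[i, j] else "/"
                    a = [
                        "." if d.gt[i, j, k] < 0 else str(int(d.gt[i, j, k]))
                        for k in (0, 1)
                    ]
                    gts.append(sep.join(a))
                fh.write(
                    f"{chrom}\t{d.pos[i]}\t.\t{d.ref[i]}\t{d.alt[i]}\t"
                    f"{qual_s}\t.\t.\tGT\t" + "\t".join(gts) + "\n"
                )


# ------------------------------------------------------------- filtering ----

def filter_sites(
    panel: HaplotypePanel,
    maf_min: float = 0.01,
    min_call_rate: float = 0.3,
    qual_min: float = 30.0,
) -> HaplotypePanel:
    """Apply the site-level quality filters.

    Retains sites with pooled MAF > ``maf_min`` (over non-missing alleles),
    genotype call rate >= ``min_call_rate``, and QUAL > ``qual_min`` where a
    QUAL is present (sites without QUAL pass that test). Idempotent.
    """
    keep: dict[str, np.ndarray] = {}
    total = kept = 0
    for chrom, d in panel.chroms.items():
        if d.n_sites == 0:
            keep[chrom] = np.zeros(0, dtype=bool)
            continue
        called = (d.gt >= 0).all(axis=2)  # (m, n) fully-called genotypes
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called[:, :, None], d.gt, 0).sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
        maf = np.minimum(freq, 1.0 - freq)
        call_rate = called.mean(axis=1)
        qual_ok = np.isnan(d.qual) | (d.qual > qual_min)
        mask = (maf > maf_min) & (call_rate >= min_call_rate) & qual_ok
        keep[chrom] = mask
        total += d.n_sites
        kept += int(mask.sum())
    if total and kept == 0:
        warnings.warn("all sites removed by filters; returning empty panel")
    logger.info("filter_sites kept %d of %d sites", kept, total)
    return panel.subset_sites(keep)


# --------------------------------------------------------------- BED/GTF ----

def read_intervals(path: str | Path, fmt: str) -> list[GenomicInterval]:
    """Read genomic intervals from BED3+ or GTF.

    BED is 0-based half-open as-is; GTF records of type ``gene`` are 1-based
    inclusive and are converted. Payload carries the BED name column or the
    GTF gene_id/gene_name.
    """
    fmt = fmt.lower()
    if fmt == "bed":
        return _read_bed(path)
    if fmt == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown interval format: {fmt!r} (expected BED or GTF)")


def _read_bed(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            start, end = int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            payload = parts[3] if len(parts) > 3 else None
            out.append(GenomicInterval(parts[0], start, end, payload))
    return out


def _read_gtf(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            feat = gffutils.feature.feature_from_line(line, dialect=None)
            if feat.featuretype != "gene":
                continue
            start, end = feat.start - 1, feat.end  # to 0-based half-open
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start after conversion")
            gene_id = (feat.attributes.get("gene_id") or [""])[0]
            name = (feat.attributes.get("gene_name") or [gene_id])[0]
            payload = f"{gene_id}|{name}" if name != gene_id else gene_id
            out.append(GenomicInterval(feat.seqid, start, end, payload))
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            payload = iv.payload if iv.payload is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{payload}\n")
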