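"""Runs of homozygosity: detection, length classification, F_ROH.

Detection follows the sliding-window scheme popularized by PLINK's
``--homozyg``: every stretch of ``window_snps`` consecutive SNPs is tested for
homozygosity-compatibility (at most ``max_het_per_window`` heterozygous and
``max_miss_per_window`` missing calls); a SNP seeds a candidate run when at
least 5% of the windows containing it are compatible; maximal stretches of
seed SNPs are then split at inter-SNP gaps above ``max_gap_bp`` and kept only
when they satisfy the SNP-count, physical-length and SNP-density gates.

Segment length uses the SNP-span convention (last SNP position - first SNP
position + 1). The seven length bins are half-open ([100, 200) kb ... with an
open-ended >= 700 kb bin), so a 200 kb segment belongs to the 200-300 kb bin.
F_ROH divides the summed segment lengths by the autosome length (default
2.27 Gb, the pig autosome complement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, HaplotypePanel

PIG_AUTOSOME_BP = 2.27e9

ROH_BIN_EDGES_KB = (100, 200, 300, 400, 500, 600, 700)
ROH_BIN_LABELS = (
    "100-200kb", "200-300kb", "300-400kb", "400-500kb",
    "500-600kb", "600-700kb", ">700kb",
)


@dataclass
class ROHParams:
    window_snps: int = 50
    max_het_per_window: int = 1
    max_miss_per_window: int = 5
    min_snp_count: int = 50
    min_length_bp: int = 100_000
    min_density_bp_per_snp: int = 50_000
    max_gap_bp: int = 1_000_000
    hit_fraction: float = 0.05


@dataclass
class ROHSegment:
    sample: str
    interval: GenomicInterval
    n_snps: int
    n_hets: int
    n_missing: int

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class ROHSummary:
    sample: str
    bin_counts: dict[str, int]
    total_length_bp: int
    f_roh: float


def _moving_sum(x: np.ndarray, w: int) -> np.ndarray:
    cs = np.concatenate(([0], np.cumsum(x)))
    return cs[w:] - cs[:-w]


def detect_roh(
    panel: HaplotypePanel,
    sample: str,
    params: ROHParams | None = None,
) -> list[ROHSegment]:
    """Detect ROH segments for one sample across all chromosomes."""
    if params is None:
        params = ROHParams()
    if sample not in panel.samples:
        raise KeyError(f"unknown sample: {sample!r}")
    col = panel.samples.index(sample)
    w = params.window_snps
    segments: list[ROHSegment] = []
    for chrom in sorted(panel.chroms):
        d = panel.chroms[chrom]
        m = d.n_sites
        if m < w:
            continue
        gt = d.gt[:, col, :]
        missing = (gt < 0).any(axis=1)
        het = ~missing & (gt[:, 0] != gt[:, 1])

        # window k covers SNPs [k, k+w); compatibility per window
        win_het = _moving_sum(het.astype(np.int64), w)
        win_mis = _moving_sum(missing.astype(np.int64), w)
        compat = (win_het <= params.max_het_per_window) & (
            win_mis <= params.max_miss_per_window
        )
        # per SNP: fraction of overlapping windows that are compatible
        n_win = m - w + 1
        cs = np.concatenate(([0], np.cumsum(compat.astype(np.int64))))
        snp_idx = np.arange(m)
        first = np.maximum(0, snp_idx - w + 1)
        last = np.minimum(n_win - 1, snp_idx)  # inclusive
        n_cover = last - first + 1
        n_compat = cs[last + 1] - cs[first]
        seed = (n_compat / n_cover) >= params.hit_fraction

        # maximal seed runs, split at oversized gaps
        for run_lo, run_hi in _runs(seed):
            sub = np.arange(run_lo, run_hi)
            gaps = np.diff(d.pos[sub])
            breaks = np.flatnonzero(gaps > params.max_gap_bp)
            pieces = np.split(sub, breaks + 1)
            for piece in pieces:
                if piece.size < params.min_snp_count:
                    continue
                start_pos = int(d.pos[piece[0]])
                end_pos = int(d.pos[piece[-1]])
                span = end_pos - start_pos + 1
                if span < params.min_length_bp:
                    continue
                if span / piece.size > params.min_density_bp_per_snp:
                    continue
                segments.append(
                    ROHSegment(
                        sample=sample,
                        interval=GenomicInterval(
                            chrom, start_pos - 1, end_pos, payload=sample
                        ),
                        n_snps=int(piece.size),
                        n_hets=int(het[piece].sum()),
                        n_missing=int(missing[piece].sum()),
                    )
                )
    return segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [lo, hi) index ranges of True runs."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [mask.size]))
    return list(zip(starts.tolist(), ends.tolist()))


def classify_roh(segments: list[ROHSegment]) -> dict[str, int]:
    """Seven-bin length spectrum; every segment falls in exactly one bin."""
    counts = {label: 0 for label in ROH_BIN_LABELS}
    edges_bp = [e * 1000 for e in ROH_BIN_EDGES_KB]
    for seg in segments:
        length = seg.length
        if length < edges_bp[0]:
            raise ValueError(
                f"segment of {length} bp violates the {edges_bp[0]} bp floor"
            )
        k = int(np.searchsorted(edges_bp, length, side="right")) - 1
        k = min(k, len(ROH_BIN_LABELS) - 1)
        counts[ROH_BIN_LABELS[k]] += 1
    return counts


def f_roh(segments: list[ROHSegment], autosome_length: float = PIG_AUTOSOME_BP) -> float:
    """Genomic inbreeding coefficient: total ROH length / autosome length."""
    if autosome_length <= 0:
        raise ValueError("autosome_length must be > 0")
    return sum(seg.length for seg in segments) / autosome_length


def summarize_roh(
    panel: HaplotypePanel,
    params: ROHParams | None = None,
    autosome_length: float = PIG_AUTOSOME_BP,
) -> tuple[pd.DataFrame, list[ROHSegment]]:
    """Per-sample ROH summary table plus the flat segment list."""
    rows = []
    all_segments: list[ROHSegment] = []
    for sample in panel.samples:
        segs = detect_roh(panel, sample, params)
        all_segments.extend(segs)
        bins = classify_roh(segs)
        total = sum(s.length for s in segs)
        row = {
            "sample": sample,
            "pop": panel.pop_of[sample],
            "n_segments": len(segs),
            "total_length_bp": total,
            "f_roh": total / autosome_length,
        }
        row.update(bins)
        rows.append(row)
    return pd.DataFrame(rows), all_segments


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": s.sample,
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "length_bp": s.length,
                "n_snps": s.n_snps,
                "n_hets": s.n_hets,
                "n_missing": s.n_missing,
            }
            for s in segments
        ],
        columns=[
            "sample", "chrom", "start", "end",
            "length_bp", "n_snps", "n_hets", "n_missing",
        ],
    )
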