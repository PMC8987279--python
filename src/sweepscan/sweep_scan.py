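"""Sliding-window consensus engine for selective-sweep candidate regions.

The scan places overlapping windows (default 100 kb, 10 kb step) on every
chromosome, scores each window by several methods (F_ST, log2 pi-ratio,
windowed XP-EHH), flags the empirical right tail (default top 5%) of each
method's scored windows, selects windows flagged by at least ``min_methods``
methods, merges overlapping/abutting selected windows into maximal regions,
intersects regions across breed contrasts, and annotates regions with counts
of highly differentiated SNVs (dAF above a cutoff).

All method scores are oriented so that a sweep in the target population falls
in the right tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, SweepTruth


# ------------------------------------------------------------- window grid --

@dataclass
class WindowGrid:
    """Sliding windows per chromosome: (k, 2) arrays of [start, end)."""

    windows: dict[str, np.ndarray]
    size: int
    step: int

    def chroms(self) -> list[str]:
        return list(self.windows)

    @property
    def n_windows(self) -> int:
        return sum(len(w) for w in self.windows.values())

    def as_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame(
                {"chrom": c, "start": w[:, 0], "end": w[:, 1]}
            )
            for c, w in self.windows.items()
        ]
        return pd.concat(rows, ignore_index=True)


def make_windows(
    chrom_lengths: dict[str, int], size: int = 100_000, step: int = 10_000
) -> WindowGrid:
    """Windows starting at 0, step, 2*step, ... while start < chrom length;
    the trailing windows are right-clipped at the chromosome end."""
    if size <= 0 or step <= 0 or step > size:
        raise ValueError("require size > 0 and 0 < step <= size")
    windows: dict[str, np.ndarray] = {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + size, length)
        windows[chrom] = np.column_stack([starts, ends])
    return WindowGrid(windows=windows, size=size, step=step)


# ------------------------------------------------------- window aggregation --

def window_xpehh(
    scores: pd.DataFrame,
    grid: WindowGrid,
    min_snps: int = 10,
    summary: str = "mean",
) -> pd.DataFrame:
    """Aggregate normalized per-SNP XP-EHH scores to the window grid.

    ``scores`` needs columns chrom, pos (1-based), norm. Windows with fewer
    than ``min_snps`` scored SNPs are unscored. ``summary`` is "mean" or "max".
    """
    if summary not in ("mean", "max"):
        raise ValueError("summary must be 'mean' or 'max'")
    rows = []
    for chrom in grid.chroms():
        sub = scores[scores["chrom"] == chrom]
        norm = sub["norm"].to_numpy(dtype=np.float64)
        ok = np.isfinite(norm)
        pos0 = sub["pos"].to_numpy()[ok] - 1
        norm = norm[ok]
        order = np.argsort(pos0, kind="stable")
        pos0, norm = pos0[order], norm[order]
        w = grid.windows[chrom]
        lo = np.searchsorted(pos0, w[:, 0], side="left")
        hi = np.searchsorted(pos0, w[:, 1], side="left")
        counts = hi - lo
        val = np.full(len(w), np.nan)
        if summary == "mean":
            cs = np.concatenate(([0.0], np.cumsum(norm)))
            with np.errstate(invalid="ignore"):
                means = (cs[hi] - cs[lo]) / np.maximum(counts, 1)
            val = np.where(counts >= min_snps, means, np.nan)
        else:
            for i in range(len(w)):
                if counts[i] >= min_snps:
                    val[i] = norm[lo[i]:hi[i]].max()
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": w[:, 0],
                    "end": w[:, 1],
                    "n_snps": counts,
                    "xpehh": val,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ------------------------------------------------------ empirical threshold --

def empirical_threshold(values, tail: float = 0.05) -> float:
    """Right-tail cutoff: the (1 - tail) empirical quantile of scored values.

    Linear interpolation between order statistics; NaN (unscored) entries are
    excluded. Requires at least 20 scored values for the tail to be
    meaningful.
    """
    vals = np.asarray(values, dtype=np.float64)
    scored = vals[np.isfinite(vals)]
    if scored.size < 20:
        raise ValueError(
            f"only {scored.size} scored values; need >= 20 for a {tail:.0%} tail"
        )
    cutoff = float(np.quantile(scored, 1.0 - tail))
    if scored.min() == scored.max():
        warnings.warn("all scored values equal; every window will be flagged")
    return cutoff


def flag_tail(values, tail: float = 0.05) -> tuple[np.ndarray, float]:
    """Boolean flags (value >= cutoff; unscored never flagged) plus the cutoff."""
    vals = np.asarray(values, dtype=np.float64)
    cutoff = empirical_threshold(vals, tail)
    with np.errstate(invalid="ignore"):
        flags = np.isfinite(vals) & (vals >= cutoff)
    return flags, cutoff


# ------------------------------------------------------------ region calling --

@dataclass
class SweepRegion:
    """A merged candidate interval with its supporting evidence."""

    interval: GenomicInterval
    methods_by_contrast: dict[str, frozenset[str]]
    n_high_daf: int | None = None
    member_windows: list[tuple[int, int]] = field(default_factory=list)

    @property
    def methods(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.methods_by_contrast.values():
            out |= m
        return frozenset(out)

    @property
    def contrasts(self) -> frozenset[str]:
        return frozenset(self.methods_by_contrast)


def consensus_regions(
    flags_by_method: dict[str, np.ndarray],
    grid: WindowGrid,
    min_methods: int = 2,
    contrast: str = "contrast",
) -> list[SweepRegion]:
    """Select windows flagged by >= ``min_methods`` methods and merge them.

    ``flags_by_method`` maps a method name to a boolean array aligned with
    ``grid.as_frame()`` rows. Overlapping or abutting selected windows on a
    chromosome merge into maximal regions; each region records the union of
    supporting methods over its member windows.
    """
    frame = grid.as_frame()
    names = list(flags_by_method)
    flags = np.column_stack([np.asarray(flags_by_method[m], bool) for m in names])
    if flags.shape[0] != len(frame):
        raise ValueError("flag arrays must align with the window grid")
    selected = flags.sum(axis=1) >= min_methods

    regions: list[SweepRegion] = []
    for chrom in grid.chroms():
        in_chrom = (frame["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(in_chrom & selected)
        if idx.size == 0:
            continue
        starts = frame["start"].to_numpy()[idx]
        ends = frame["end"].to_numpy()[idx]
        cur_s, cur_e = int(starts[0]), int(ends[0])
        members = [idx[0]]
        for i, s, e in zip(idx[1:], starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or abut
                cur_e = max(cur_e, int(e))
                members.append(i)
            else:
                regions.append(_mk_region(chrom, cur_s, cur_e, members,
                                          flags, names, frame, contrast))
                cur_s, cur_e, members = int(s), int(e), [i]
        regions.append(_mk_region(chrom, cur_s, cur_e, members,
                                  flags, names, frame, contrast))
    return regions


def _mk_region(chrom, start, end, members, flags, names, frame, contrast):
    supported = frozenset(
        names[j] for j in range(len(names)) if flags[members, j].any()
    )
    mw = [
        (int(frame["start"].iloc[i]), int(frame["end"].iloc[i])) for i in members
    ]
    return SweepRegion(
        interval=GenomicInterval(chrom, start, end),
        methods_by_contrast={contrast: supported},
        member_windows=mw,
    )


def intersect_contrasts(
    regionsA: list[SweepRegion], regionsB: list[SweepRegion]
) -> list[SweepRegion]:
    """Intersect two merged region lists: one output region per pairwise
    overlap (>= 1 bp), spanning the intersection; per-contrast method sets are
    retained."""
    out: list[SweepRegion] = []
    for ra in regionsA:
        for rb in regionsB:
            bp = ra.interval.overlap_bp(rb.interval)
            if bp <= 0:
                continue
            iv = GenomicInterval(
                ra.interval.chrom,
                max(ra.interval.start, rb.interval.start),
                min(ra.interval.end, rb.interval.end),
            )
            methods = dict(ra.methods_by_contrast)
            methods.update(rb.methods_by_contrast)
            out.append(SweepRegion(interval=iv, methods_by_contrast=methods))
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


# -------------------------------------------------------------- dAF counts --

def count_high_daf(
    regions: list[SweepRegion],
    per_site_daf: pd.DataFrame,
    cutoff: float = 0.8,
) -> tuple[list[SweepRegion], dict]:
    """Count SNVs with dAF > cutoff inside each region (strict inequality).

    Also reports, over sites with a defined dAF, the fraction of high-dAF
    SNVs inside regions vs genome-wide, and their ratio as the enrichment
    summary.
    """
    daf = per_site_daf["daf"].to_numpy(dtype=np.float64)
    defined = np.isfinite(daf)
    high = defined & (daf > cutoff)
    chroms = per_site_daf["chrom"].to_numpy()
    pos0 = per_site_daf["pos"].to_numpy() - 1

    n_region_sites = 0
    n_region_high = 0
    for r in regions:
        in_r = (
            (chroms == r.interval.chrom)
            & (pos0 >= r.interval.start)
            & (pos0 < r.interval.end)
        )
        r.n_high_daf = int((in_r & high).sum())
        n_region_sites += int((in_r & defined).sum())
        n_region_high += r.n_high_daf

    n_genome_sites = int(defined.sum())
    n_genome_high = int(high.sum())
    genome_density = n_genome_high / n_genome_sites if n_genome_sites else np.nan
    region_density = n_region_high / n_region_sites if n_region_sites else np.nan
    ratio = (
        region_density / genome_density
        if n_genome_high and n_region_sites
        else np.nan
    )
    summary = {
        "n_region_high_daf": n_region_high,
        "n_region_sites": n_region_sites,
        "n_genome_high_daf": n_genome_high,
        "n_genome_sites": n_genome_sites,
        "region_density": region_density,
        "genome_density": genome_density,
        "enrichment_ratio": ratio,
    }
    return regions, summary


# ---------------------------------------------------------------- recovery --

def recovery_metrics(
    regions: list[SweepRegion],
    truth: list[SweepTruth],
    chrom_lengths: dict[str, int],
) -> dict:
    """Sweep-recovery scores against simulator ground truth.

    sensitivity = fraction of truth intervals overlapping >= 1 region (1 bp
    rule); genome_fraction = total region bp / total genome bp.
    """
    hits = sum(
        1
        for t in truth
        if any(t.interval.overlap_bp(r.interval) > 0 for r in regions)
    )
    region_bp = sum(r.interval.length for r in regions)
    genome_bp = sum(chrom_lengths.values())
    return {
        "sensitivity": hits / len(truth) if truth else np.nan,
        "n_truth": len(truth),
        "n_regions": len(regions),
        "region_bp": region_bp,
        "genome_fraction": region_bp / genome_bp if genome_bp else np.nan,
    }


def regions_to_bed(regions: list[SweepRegion], path) -> None:
    """Write regions as BED with methods, contrasts and high-dAF counts."""
    with open(path, "w") as fh:
        for r in regions:
            methods = ";".join(
                f"{c}:{','.join(sorted(ms))}"
                for c, ms in sorted(r.methods_by_contrast.items())
            )
            n = r.n_high_daf if r.n_high_daf is not None else "."
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{methods}\t{n}\n"
            )
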