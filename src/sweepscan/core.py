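"""Core in-memory containers shared by every analysis stage.

Coordinates are 0-based half-open everywhere inside the package; VCF and GTF
readers/writers convert at the boundary. Genotypes are stored as small integer
arrays: allele codes 0 (reference), 1 (alternate), -1 (missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

MISSING = -1


@dataclass
class GenomicInterval:
    """Half-open genomic interval [start, end) with an optional payload label."""

    chrom: str
    start: int
    end: int
    payload: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class VariantSite:
    """One biallelic SNV with per-sample genotypes.

    ``genotypes`` is an (n_samples, 2) array of allele codes in {0, 1, -1};
    ``phased`` is a boolean per sample taken from the VCF separator.
    """

    chrom: str
    pos: int  # 1-based physical position
    ref_allele: str
    alt_allele: str
    qual: float  # NaN when absent
    genotypes: np.ndarray
    phased: np.ndarray


@dataclass
class ChromData:
    """Column-oriented storage for all sites on one chromosome."""

    pos: np.ndarray        # (m,) int64, 1-based, strictly increasing
    ref: np.ndarray        # (m,) unicode
    alt: np.ndarray        # (m,) unicode
    qual: np.ndarray       # (m,) float64, NaN when absent
    gt: np.ndarray         # (m, n_samples, 2) int8, -1 missing
    phased: np.ndarray     # (m, n_samples) bool

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def take(self, idx: np.ndarray) -> "ChromData":
        return ChromData(
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            qual=self.qual[idx],
            gt=self.gt[idx],
            phased=self.phased[idx],
        )


@dataclass
class HaplotypePanel:
    """Phased (or unphased) multi-population biallelic genotype panel."""

    samples: list[str]
    pop_of: dict[str, str]
    chroms: dict[str, ChromData]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        missing = [s for s in self.samples if s not in self.pop_of]
        if missing:
            raise ValueError(f"samples without population label: {missing}")
        for c, data in self.chroms.items():
            if data.n_sites and data.pos.max() > self.chrom_lengths.get(c, np.inf):
                raise ValueError(f"site beyond declared length on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return sum(d.n_sites for d in self.chroms.values())

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.pop_of[s], None)
        return list(seen)

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if self.pop_of[s] == pop],
            dtype=np.int64,
        )
        if idx.size == 0:
            raise KeyError(f"unknown population label: {pop!r}")
        return idx

    def haplotypes(self, chrom: str, pop: str | None = None) -> np.ndarray:
        """Return the (2*n, m) haplotype matrix for ``chrom``.

        Requires fully phased, fully called genotypes for the selected
        samples; haplotype-based statistics are only defined on such data.
        """
        data = self.chroms[chrom]
        cols = (
            self.sample_indices(pop)
            if pop is not None
            else np.arange(self.n_samples)
        )
        gt = data.gt[:, cols, :]
        if (gt < 0).any():
            raise ValueError(
                f"missing genotypes on {chrom}: phased complete data required"
            )
        if data.n_sites and not data.phased[:, cols].all():
            raise ValueError(f"unphased genotypes on {chrom}")
        m, n, _ = gt.shape
        return gt.transpose(1, 2, 0).reshape(2 * n, m).astype(np.int8)

    def sites(self, chrom: str) -> Iterator[VariantSite]:
        d = self.chroms[chrom]
        for i in range(d.n_sites):
            yield VariantSite(
                chrom=chrom,
                pos=int(d.pos[i]),
                ref_allele=str(d.ref[i]),
                alt_allele=str(d.alt[i]),
                qual=float(d.qual[i]),
                genotypes=d.gt[i],
                phased=d.phased[i],
            )

    def subset_sites(self, keep: dict[str, np.ndarray]) -> "HaplotypePanel":
        """New panel retaining, per chromosome, the sites selected in ``keep``."""
        return HaplotypePanel(
            samples=list(self.samples),
            pop_of=dict(self.pop_of),
            chroms={c: d.take(keep[c]) for c, d in self.chroms.items()},
            chrom_lengths=dict(self.chrom_lengths),
        )


@dataclass
class SweepTruth:
    """Ground-truth record for one injected sweep."""

    pop: str
    interval: GenomicInterval
    sweep_freq: float

    def __post_init__(self) -> None:
        if not (0.0 < self.sweep_freq <= 1.0):
            raise ValueError("sweep_freq must be in (0, 1]")
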