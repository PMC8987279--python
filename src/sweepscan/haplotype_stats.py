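"""Extended haplotype homozygosity statistics on phased panels.

EHH at an extension j is the probability that two randomly drawn haplotypes
are identical over every site from the core SNP out to j inclusive, computed
as sum_g C(n_g, 2) / C(n, 2) over haplotype groups g; at the core alone the
groups are the two core alleles (the "whole-sample" variant used for
cross-population comparisons, not the allele-specific iHS variant). iHH is
the trapezoidal integral of the EHH decay curve over physical distance,
accumulated outward per arm and stopping after including the first point
below the EHH cutoff; arms cut off by a chromosome end, an oversized
inter-SNP gap, or missing data are integrated to the truncation point and
flagged. XP-EHH at a core SNP is ln(iHH_A / iHH_B), z-normalized genome-wide
over scored SNPs (population standard deviation).

Conventions: integration is over physical distance in bp (no genetic map);
a between-SNP gap above ``max_gap_bp`` (default 200 kb) truncates the arm;
cores with pooled minor-allele frequency below 0.05 are not scored. Scores
are oriented with the scan's target population as A, so sweeps in the target
fall in the right tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .core import HaplotypePanel

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP_BP = 200_000
DEFAULT_MAF_MIN = 0.05


# -------------------------------------------------------------- EHH curves --

@dataclass
class EHHArm:
    """One direction of an EHH decay curve, core point included."""

    positions: np.ndarray   # bp, starting at the core position
    ehh: np.ndarray         # EHH at each extension, ehh[0] = core EHH
    truncated: bool         # stopped by chromosome end, gap, or missing data


@dataclass
class EHHCurve:
    core_index: int
    core_pos: int
    n_haplotypes: int
    left: EHHArm
    right: EHHArm


def _pair_fraction(labels: np.ndarray) -> float:
    n = labels.size
    _, counts = np.unique(labels, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    direction: int,
    max_gap_bp: int | None = DEFAULT_MAX_GAP_BP,
) -> EHHArm:
    """EHH decay along one arm (direction -1 left, +1 right).

    ``haplotypes`` is an (n, m) allele matrix (codes 0/1, -1 missing); a
    missing allele stops the extension at the previous site with the
    truncation flag set, as does an inter-SNP gap above ``max_gap_bp``.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be -1 or +1")
    haps = np.asarray(haplotypes)
    n, m = haps.shape
    if n < 4:
        raise ValueError("EHH requires >= 4 haplotypes")
    labels = haps[:, core_index].astype(np.int64)
    if (labels < 0).any():
        raise ValueError("missing allele at the core SNP")
    pos_out = [int(positions[core_index])]
    ehh_out = [_pair_fraction(labels)]
    truncated = False
    j = core_index + direction
    prev_pos = positions[core_index]
    while 0 <= j < m:
        if max_gap_bp is not None and abs(int(positions[j]) - int(prev_pos)) > max_gap_bp:
            truncated = True
            break
        alleles = haps[:, j]
        if (alleles < 0).any():
            truncated = True
            break
        _, labels = np.unique(labels * 2 + alleles, return_inverse=True)
        pos_out.append(int(positions[j]))
        ehh_out.append(_pair_fraction(labels))
        prev_pos = positions[j]
        j += direction
    if not (0 <= j < m) and not truncated:
        truncated = True  # ran into the chromosome end
    return EHHArm(
        positions=np.array(pos_out, dtype=np.int64),
        ehh=np.array(ehh_out, dtype=np.float64),
        truncated=truncated,
    )


def ehh_curve(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    max_gap_bp: int | None = DEFAULT_MAX_GAP_BP,
) -> EHHCurve:
    """Both arms of the EHH decay curve around a core SNP."""
    return EHHCurve(
        core_index=core_index,
        core_pos=int(positions[core_index]),
        n_haplotypes=np.asarray(haplotypes).shape[0],
        left=ehh(haplotypes, positions, core_index, -1, max_gap_bp),
        right=ehh(haplotypes, positions, core_index, +1, max_gap_bp),
    )


# --------------------------------------------------------------------- iHH --

def ihh_arm(arm: EHHArm, cutoff: float = DEFAULT_CUTOFF) -> tuple[float, bool]:
    """Trapezoidal integral of one arm, stopping after the first sub-cutoff
    point; returns (integral in bp*EHH, truncated-before-decay flag)."""
    if arm.ehh[0] < cutoff:
        return 0.0, True
    total = 0.0
    core = arm.positions[0]
    for k in range(1, len(arm.ehh)):
        x0 = abs(int(arm.positions[k - 1]) - int(core))
        x1 = abs(int(arm.positions[k]) - int(core))
        total += (arm.ehh[k - 1] + arm.ehh[k]) / 2.0 * (x1 - x0)
        if arm.ehh[k] < cutoff:
            return total, False
    return total, arm.truncated


def ihh(curve: EHHCurve, cutoff: float = DEFAULT_CUTOFF) -> tuple[float, bool]:
    """Integrated EHH: sum of both arm integrals; flag set if either arm was
    truncated before decaying below the cutoff (or the core is already below)."""
    left, tl = ihh_arm(curve.left, cutoff)
    right, tr = ihh_arm(curve.right, cutoff)
    return left + right, tl or tr


def xpehh_raw(
    hapsA: np.ndarray,
    hapsB: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap_bp: int | None = DEFAULT_MAX_GAP_BP,
) -> float:
    """Unstandardized XP-EHH = ln(iHH_A / iHH_B); NaN when either iHH is 0.

    Population A is the scan's target population. Both panels must be phased
    over the same site list.
    """
    if np.asarray(hapsA).shape[1] != np.asarray(hapsB).shape[1]:
        raise ValueError("panels A and B must share the same site list")
    iA, _ = ihh(ehh_curve(hapsA, positions, core_index, max_gap_bp), cutoff)
    iB, _ = ihh(ehh_curve(hapsB, positions, core_index, max_gap_bp), cutoff)
    if iA == 0.0 or iB == 0.0:
        return float("nan")
    return float(np.log(iA / iB))


def normalize_xpehh(raws) -> np.ndarray:
    """Genome-wide z-scores of raw XP-EHH values (population sd, denominator n).

    Unscored (NaN) entries stay unscored; if the sd of scored values is 0 all
    norms are unscored with a warning.
    """
    raws = np.asarray(raws, dtype=np.float64)
    scored = np.isfinite(raws)
    if scored.sum() < 2:
        raise ValueError("need >= 2 scored sites to normalize")
    mean = raws[scored].mean()
    sd = raws[scored].std()  # ddof=0
    out = np.full(raws.shape, np.nan)
    if sd == 0.0:
        warnings.warn("sd of raw XP-EHH is 0; normalization undefined")
        return out
    out[scored] = (raws[scored] - mean) / sd
    return out


# ------------------------------------------------------------ genome scan ---

@njit(cache=True)
def _ihh_kernel(haps, pos, cores, cutoff, max_gap):  # pragma: no cover
    n, m = haps.shape
    npairs = n * (n - 1) / 2.0
    ihh_out = np.zeros(len(cores))
    trunc = np.zeros(len(cores), dtype=np.uint8)
    labels = np.empty(n, dtype=np.int64)
    newlab = np.empty(n, dtype=np.int64)
    lut = np.full(2 * n + 2, -1, dtype=np.int64)
    counts = np.empty(n, dtype=np.int64)
    for ci in range(len(cores)):
        c = cores[ci]
        n1 = 0
        for i in range(n):
            n1 += haps[i, c]
        n0 = n - n1
        e0 = (n0 * (n0 - 1) / 2.0 + n1 * (n1 - 1) / 2.0) / npairs
        if e0 < cutoff:
            ihh_out[ci] = 0.0
            trunc[ci] = 1
            continue
        total = 0.0
        truncated = False
        for direction in (-1, 1):
            for i in range(n):
                labels[i] = haps[i, c]
            prev_ehh = e0
            prev_x = 0
            j = c + direction
            decayed = False
            while 0 <= j < m:
                gap = pos[j] - pos[j - direction]
                if gap < 0:
                    gap = -gap
                if gap > max_gap:
                    truncated = True
                    break
                k = 0
                for i in range(n):
                    key = labels[i] * 2 + haps[i, j]
                    if lut[key] < 0:
                        lut[key] = k
                        counts[k] = 1
                        newlab[i] = k
                        k += 1
                    else:
                        counts[lut[key]] += 1
                        newlab[i] = lut[key]
                pairs = 0.0
                for t in range(k):
                    pairs += counts[t] * (counts[t] - 1) / 2.0
                e = pairs / npairs
                for i in range(n):
                    lut[labels[i] * 2] = -1
                    lut[labels[i] * 2 + 1] = -1
                    labels[i] = newlab[i]
                x = pos[j] - pos[c]
                if x < 0:
                    x = -x
                total += (prev_ehh + e) / 2.0 * (x - prev_x)
                prev_ehh = e
                prev_x = x
                if e < cutoff:
                    decayed = True
                    break
                j += direction
            if not decayed and not truncated:
                truncated = True  # chromosome end
        ihh_out[ci] = total
        trunc[ci] = 1 if truncated else 0
    return ihh_out, trunc


def xpehh_scan(
    panel: HaplotypePanel,
    popA: str,
    popB: str,
    cutoff: float = DEFAULT_CUTOFF,
    maf_min: float = DEFAULT_MAF_MIN,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> pd.DataFrame:
    """Per-SNP XP-EHH over all chromosomes, normalized genome-wide.

    Cores with pooled (A+B haplotypes) MAF below ``maf_min`` are left
    unscored. Returns chrom, pos, ihh_a, ihh_b, raw, norm, scored plus
    per-side truncation flags.
    """
    frames = []
    for chrom in sorted(panel.chroms):
        hapsA = panel.haplotypes(chrom, popA)
        hapsB = panel.haplotypes(chrom, popB)
        pos = panel.chroms[chrom].pos
        m = pos.size
        pooled = np.concatenate([hapsA, hapsB], axis=0)
        freq = pooled.mean(axis=0)
        maf = np.minimum(freq, 1.0 - freq)
        cores = np.flatnonzero(maf >= maf_min).astype(np.int64)

        ihh_a = np.full(m, np.nan)
        ihh_b = np.full(m, np.nan)
        trunc_a = np.zeros(m, dtype=bool)
        trunc_b = np.zeros(m, dtype=bool)
        if cores.size:
            va, ta = _ihh_kernel(
                np.ascontiguousarray(hapsA), pos.astype(np.int64),
                cores, float(cutoff), float(max_gap_bp),
            )
            vb, tb = _ihh_kernel(
                np.ascontiguousarray(hapsB), pos.astype(np.int64),
                cores, float(cutoff), float(max_gap_bp),
            )
            ihh_a[cores] = va
            ihh_b[cores] = vb
            trunc_a[cores] = ta.astype(bool)
            trunc_b[cores] = tb.astype(bool)
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(
                (ihh_a > 0) & (ihh_b > 0), np.log(ihh_a / ihh_b), np.nan
            )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ihh_a": ihh_a,
                    "ihh_b": ihh_b,
                    "raw": raw,
                    "trunc_a": trunc_a,
                    "trunc_b": trunc_b,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["norm"] = normalize_xpehh(out["raw"].to_numpy())
    out["scored"] = np.isfinite(out["norm"].to_numpy())
    return out
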