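"""Per-site and windowed frequency-based statistics.

Implements allele frequencies, the Weir–Cockerham (1984) two-population F_ST
variance components (a, b, c), windowed F_ST as the ratio-of-sums estimator
sum(a)/sum(a+b+c), per-window nucleotide diversity pi (per-bp, dividing by the
window length), the log2 pi-ratio oriented as log2(pi_ref/pi_target), the
allele-frequency contrast dAF = |AF_target - mean(AF_ref1, AF_ref2)|, and
breed-specific SNV calling (target AF > 0.95, every other population < 0.05).

A genotype with any missing allele is treated as fully missing, so allele
counts are always twice the fully-called diploid count; this matches the
diploid sample sizes and observed heterozygosities the WC84 estimator needs.
Negative F_ST values are reported as-is (never clamped): empirical-tail
thresholding is unaffected and the estimator's distribution is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HaplotypePanel
from .sweep_scan import WindowGrid


# --------------------------------------------------------- site frequencies --

def site_frequencies(panel: HaplotypePanel, populations: list[str]) -> pd.DataFrame:
    """Per-site allele counts and frequencies for the requested populations.

    Returns a frame with ``chrom``/``pos`` plus, per population ``P``:
    ``n_alleles_P`` (non-missing allele count), ``alt_count_P``, ``af_P``
    (alternate-allele frequency, NaN when no data), ``het_P`` (observed
    heterozygous diploids) and ``n_dip_P`` (fully-called diploids).
    """
    for pop in populations:
        panel.sample_indices(pop)  # raises on unknown label
    frames = []
    for chrom in sorted(panel.chroms):
        d = panel.chroms[chrom]
        cols: dict[str, np.ndarray] = {
            "chrom": np.full(d.n_sites, chrom, dtype=object),
            "pos": d.pos,
        }
        for pop in populations:
            idx = panel.sample_indices(pop)
            gt = d.gt[:, idx, :]
            called = (gt >= 0).all(axis=2)
            n_dip = called.sum(axis=1)
            alt = np.where(called[:, :, None], gt, 0).sum(axis=(1, 2))
            het = (called & (gt[:, :, 0] != gt[:, :, 1])).sum(axis=1)
            n_alleles = 2 * n_dip
            with np.errstate(invalid="ignore", divide="ignore"):
                af = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
            cols[f"n_alleles_{pop}"] = n_alleles
            cols[f"alt_count_{pop}"] = alt
            cols[f"af_{pop}"] = af
            cols[f"het_{pop}"] = het
            cols[f"n_dip_{pop}"] = n_dip
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------ WC84 F_ST -----

@dataclass
class FstSiteComponents:
    """Weir–Cockerham (1984) per-site variance components for r=2 populations.

    ``a`` is the among-population component, ``b`` among individuals within
    populations, ``c`` within individuals; ``defined`` is False where the
    estimator is not computable (a population without data, or n_bar <= 1).
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    nbar: np.ndarray
    nc: np.ndarray
    pbar: np.ndarray
    s2: np.ndarray
    hbar: np.ndarray
    defined: np.ndarray

    @property
    def fst(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.defined & (denom != 0), self.a / denom, np.nan)
        return out


def wc_fst_components(
    n1: np.ndarray,
    p1: np.ndarray,
    het1: np.ndarray,
    n2: np.ndarray,
    p2: np.ndarray,
    het2: np.ndarray,
) -> FstSiteComponents:
    """WC84 components from diploid sample sizes, alt frequencies, het counts.

    ``n1``/``n2`` are fully-called diploid counts, ``p1``/``p2`` the
    alternate-allele frequencies among those diploids, ``het1``/``het2`` the
    observed heterozygote counts. Vectorized over sites.
    """
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    het1 = np.asarray(het1, dtype=np.float64)
    het2 = np.asarray(het2, dtype=np.float64)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nsum = n1 + n2
        nbar = nsum / r
        nc = nsum - (n1**2 + n2**2) / nsum  # already divided by (r-1)=1
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (het1 + het2) / nsum
        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    defined = (n1 > 0) & (n2 > 0) & (nbar > 1.0) & (nc > 0)
    bad = ~defined
    for arr in (a, b, c):
        arr[bad] = np.nan
    return FstSiteComponents(
        a=a, b=b, c=c, nbar=nbar, nc=nc, pbar=pbar, s2=s2, hbar=hbar,
        defined=defined,
    )


def _components_for(panel: HaplotypePanel, popA: str, popB: str):
    freqs = site_frequencies(panel, [popA, popB])
    comp = wc_fst_components(
        freqs[f"n_dip_{popA}"].to_numpy(),
        freqs[f"af_{popA}"].to_numpy(),
        freqs[f"het_{popA}"].to_numpy(),
        freqs[f"n_dip_{popB}"].to_numpy(),
        freqs[f"af_{popB}"].to_numpy(),
        freqs[f"het_{popB}"].to_numpy(),
    )
    return freqs, comp


def _window_reduce(grid: WindowGrid, chrom: str, pos0: np.ndarray, *value_arrays):
    """Per-window sums of each value array (NaN-skipped) plus finite counts."""
    starts, ends = grid.windows[chrom][:, 0], grid.windows[chrom][:, 1]
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, ends, side="left")
    sums = []
    for v in value_arrays:
        cs = np.concatenate(([0.0], np.cumsum(np.nan_to_num(v, nan=0.0))))
        sums.append(cs[hi] - cs[lo])
    finite = np.isfinite(value_arrays[0]).astype(np.int64)
    cc = np.concatenate(([0], np.cumsum(finite)))
    counts = cc[hi] - cc[lo]
    return sums, counts


def windowed_fst(
    panel: HaplotypePanel,
    popA: str,
    popB: str,
    grid: WindowGrid,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Sliding-window WC84 F_ST, weighted estimator sum(a)/sum(a+b+c).

    Windows with fewer than ``min_snps`` defined sites are unscored (NaN).
    Returns one row per grid window: chrom, start, end, n_snps, fst.
    """
    freqs, comp = _components_for(panel, popA, popB)
    abc = comp.a + comp.b + comp.c
    rows = []
    for chrom in grid.chroms():
        in_chrom = (freqs["chrom"] == chrom).to_numpy()
        pos0 = freqs.loc[in_chrom, "pos"].to_numpy() - 1
        a = comp.a[in_chrom]
        denom = abc[in_chrom]
        (sa, sd), counts = _window_reduce(grid, chrom, pos0, a, denom)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where((counts >= min_snps) & (sd != 0), sa / sd, np.nan)
        w = grid.windows[chrom]
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": w[:, 0],
                    "end": w[:, 1],
                    "n_snps": counts,
                    "fst": fst,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def site_pi(n_alleles: np.ndarray, alt_count: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity 2*c_ref*c_alt / (n*(n-1)).

    NaN where fewer than two alleles were observed. Invariant to swapping the
    ref/alt labels.
    """
    n = np.asarray(n_alleles, dtype=np.float64)
    alt = np.asarray(alt_count, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * (n - alt) * alt / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def windowed_pi(
    panel: HaplotypePanel,
    pop: str,
    grid: WindowGrid,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Per-window nucleotide diversity: sum of site pi over the window length.

    Divides by the full window length in bp regardless of SNP count (vcftools
    ``--window-pi`` semantics). Windows below ``min_snps`` are unscored.
    """
    freqs = site_frequencies(panel, [pop])
    pi_site = site_pi(
        freqs[f"n_alleles_{pop}"].to_numpy(), freqs[f"alt_count_{pop}"].to_numpy()
    )
    rows = []
    for chrom in grid.chroms():
        in_chrom = (freqs["chrom"] == chrom).to_numpy()
        pos0 = freqs.loc[in_chrom, "pos"].to_numpy() - 1
        (s,), counts = _window_reduce(grid, chrom, pos0, pi_site[in_chrom])
        w = grid.windows[chrom]
        lengths = (w[:, 1] - w[:, 0]).astype(np.float64)
        pi = np.where(counts >= min_snps, s / lengths, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": w[:, 0],
                    "end": w[:, 1],
                    "n_snps": counts,
                    "pi": pi,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def log2_pi_ratio(pi_ref, pi_target) -> np.ndarray:
    """log2(pi_ref / pi_target); NaN (unscored) when either side is 0 or NaN.

    Oriented so that reduced diversity in the target population falls in the
    right tail.
    """
    ref = np.asarray(pi_ref, dtype=np.float64)
    tgt = np.asarray(pi_target, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((ref > 0) & (tgt > 0), np.log2(ref / tgt), np.nan)
    return out


# ----------------------------------------------------------------- dAF ------

def delta_af(freq_target, freq_ref1, freq_ref2) -> np.ndarray:
    """|AF_target - mean(AF_ref1, AF_ref2)|; NaN if any frequency is undefined."""
    t = np.asarray(freq_target, dtype=np.float64)
    r1 = np.asarray(freq_ref1, dtype=np.float64)
    r2 = np.asarray(freq_ref2, dtype=np.float64)
    return np.abs(t - (r1 + r2) / 2.0)


def daf_table(
    panel: HaplotypePanel, target: str, refs: tuple[str, str]
) -> pd.DataFrame:
    """Per-site dAF table (chrom, pos, af per population, daf)."""
    freqs = site_frequencies(panel, [target, refs[0], refs[1]])
    freqs["daf"] = delta_af(
        freqs[f"af_{target}"], freqs[f"af_{refs[0]}"], freqs[f"af_{refs[1]}"]
    )
    return freqs[["chrom", "pos", f"af_{target}",
                  f"af_{refs[0]}", f"af_{refs[1]}", "daf"]]


def breed_specific_snvs(
    freqs: pd.DataFrame,
    target: str,
    others: list[str],
    hi: float = 0.95,
    lo: float = 0.05,
    include_symmetric: bool = False,
) -> pd.DataFrame:
    """Sites nearly fixed for the alternate allele in the target population
    and nearly absent everywhere else (strict inequalities).

    With ``include_symmetric`` the mirrored pattern (target < lo, all others
    > hi) is also reported.
    """
    t = freqs[f"af_{target}"].to_numpy()
    other_af = np.stack([freqs[f"af_{p}"].to_numpy() for p in others])
    mask = (t > hi) & (other_af < lo).all(axis=0)
    if include_symmetric:
        mask |= (t < lo) & (other_af > hi).all(axis=0)
    return freqs.loc[mask].reset_index(drop=True)
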