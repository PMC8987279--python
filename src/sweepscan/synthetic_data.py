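"""Synthetic multi-population haplotype panels with injected selective sweeps.

The generator emulates the downstream form of a multi-breed resequencing
study: phased biallelic SNV genotypes for several populations with

* tunable differentiation — per-population allele frequencies follow the
  Balding–Nichols model, Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral
  frequency p ~ Uniform(0.05, 0.95);
* realistic linkage disequilibrium — each sample haplotype is a mosaic of a
  finite founder pool, switching founders between adjacent SNPs with
  probability 1 - exp(-switch_rate * gap_bp);
* localized sweeps — within a chosen interval of the target population, a
  fraction of haplotypes is replaced by one donor haplotype's segment,
  creating a single long high-frequency haplotype (reduced diversity,
  elevated differentiation, extended haplotype homozygosity) with exact
  ground truth.

Selection dynamics, demography and rate heterogeneity are deliberately out of
scope: ground truth must be exact and generation must run at desk scale.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import ChromData, GenomicInterval, HaplotypePanel, SweepTruth

_NUC = np.array(list("ACGT"))


@dataclass
class SimulationParams:
    """Parameters of the neutral multi-population panel.

    Defaults are the default study preset: one target and two reference
    populations of 25 diploids each, F_ST 0.05, two 10 Mb chromosomes carrying
    20,000 SNPs, a 30-founder haplotype pool and a founder-switch rate of
    1e-6 per bp (mean mosaic segment ~1 Mb).
    """

    n_pops: int = 3
    n_diploids_per_pop: int = 25
    fst_target: float = 0.05
    n_snps: int = 20_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    n_founders: int = 30
    switch_rate: float = 1e-6
    seed: int = 0
    pop_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fst_target < 1.0):
            raise ValueError("fst_target must be in (0, 1)")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be >= 0")
        if self.pop_labels is None:
            labels = ["target"] + [f"ref{i}" for i in range(1, self.n_pops)]
            self.pop_labels = tuple(labels)
        if len(self.pop_labels) != self.n_pops:
            raise ValueError("pop_labels length must equal n_pops")

    def to_dict(self) -> dict:
        return asdict(self)


def default_study_params(seed: int = 0) -> SimulationParams:
    """The default study preset (3 pops x 25 diploids, 2 x 10 Mb, 20k SNPs)."""
    return SimulationParams(seed=seed)


def default_study_sweeps() -> list[dict]:
    """Five 300 kb sweeps at haplotype frequency 0.95 in the target population,
    spread over both chromosomes."""
    centers = [
        ("chr1", 2_000_000),
        ("chr1", 5_000_000),
        ("chr1", 8_000_000),
        ("chr2", 3_000_000),
        ("chr2", 7_000_000),
    ]
    return [
        {
            "pop": "target",
            "chrom": c,
            "center_bp": x,
            "width_bp": 300_000,
            "sweep_freq": 0.95,
        }
        for c, x in centers
    ]


def _allocate_snps(n_snps: int, chrom_lengths: dict[str, int]) -> dict[str, int]:
    """Largest-remainder allocation of SNPs proportional to chromosome length."""
    total = sum(chrom_lengths.values())
    exact = {c: n_snps * length / total for c, length in chrom_lengths.items()}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    left = n_snps - sum(counts.values())
    for c in sorted(exact, key=lambda c: exact[c] - counts[c], reverse=True)[:left]:
        counts[c] += 1
    return counts


def simulate_panel(params: SimulationParams) -> HaplotypePanel:
    """Draw a neutral phased panel under the Balding–Nichols founder-mosaic model.

    Fully phased, no missing data; byte-reproducible given ``params.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n_dip = params.n_diploids_per_pop
    n_hap = 2 * n_dip
    pops = list(params.pop_labels)
    samples = [f"{pop}_{i:02d}" for pop in pops for i in range(n_dip)]
    pop_of = {f"{pop}_{i:02d}": pop for pop in pops for i in range(n_dip)}
    counts = _allocate_snps(params.n_snps, params.chrom_lengths)
    F = params.fst_target
    conc = (1.0 - F) / F

    chroms: dict[str, ChromData] = {}
    for chrom in sorted(params.chrom_lengths):
        length = params.chrom_lengths[chrom]
        m = counts[chrom]
        pos = np.sort(rng.choice(length, size=m, replace=False)) + 1
        p = rng.uniform(0.05, 0.95, size=m)
        ref_idx = rng.integers(0, 4, size=m)
        alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
        gaps = np.diff(pos).astype(np.float64)
        p_switch = 1.0 - np.exp(-params.switch_rate * gaps)

        gt = np.empty((m, len(samples), 2), dtype=np.int8)
        for pi, pop in enumerate(pops):
            q = rng.beta(p * conc, (1.0 - p) * conc)
            founders = (rng.random((params.n_founders, m)) < q).astype(np.int8)
            haps = np.empty((n_hap, m), dtype=np.int8)
            for h in range(n_hap):
                switches = rng.random(m - 1) < p_switch if m > 1 else np.zeros(0, bool)
                seg = np.concatenate(([0], np.cumsum(switches)))
                founder_ids = rng.integers(
                    0, params.n_founders, size=int(seg[-1]) + 1
                )
                haps[h] = founders[founder_ids[seg], np.arange(m)]
            cols = np.arange(pi * n_dip, (pi + 1) * n_dip)
            gt[:, cols, 0] = haps[0::2].T
            gt[:, cols, 1] = haps[1::2].T

        chroms[chrom] = ChromData(
            pos=pos.astype(np.int64),
            ref=_NUC[ref_idx],
            alt=_NUC[alt_idx],
            qual=np.full(m, np.nan),
            gt=gt,
            phased=np.ones((m, len(samples)), dtype=bool),
        )

    return HaplotypePanel(
        samples=samples,
        pop_of=pop_of,
        chroms=chroms,
        chrom_lengths=dict(params.chrom_lengths),
    )


def inject_sweep(
    panel: HaplotypePanel,
    pop: str,
    chrom: str,
    center_bp: int,
    width_bp: int,
    sweep_freq: float,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[HaplotypePanel, SweepTruth]:
    """Plant a near-fixed sweep haplotype in ``pop`` over a given interval.

    A fraction ``sweep_freq`` of the population's haplotypes (sampled without
    replacement) has its alleles over the interval replaced by the segment of
    the population's first haplotype. Returns a new panel plus the truth
    record; other populations are untouched.
    """
    start = center_bp - width_bp // 2
    end = center_bp + width_bp // 2
    if start < 0 or end > panel.chrom_lengths[chrom]:
        raise ValueError("sweep interval outside chromosome")
    data = panel.chroms[chrom]
    lo = int(np.searchsorted(data.pos - 1, start, side="left"))
    hi = int(np.searchsorted(data.pos - 1, end, side="left"))
    if hi <= lo:
        raise ValueError("sweep interval contains no SNPs")

    cols = panel.sample_indices(pop)
    n_hap = 2 * cols.size
    k = int(round(sweep_freq * n_hap))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_hap, size=k, replace=False)

    new_panel = copy.deepcopy(panel)
    gt = new_panel.chroms[chrom].gt
    donor = gt[lo:hi, cols[0], 0].copy()
    for h in chosen:
        gt[lo:hi, cols[h // 2], h % 2] = donor

    truth = SweepTruth(
        pop=pop,
        interval=GenomicInterval(chrom, start, end, payload=pop),
        sweep_freq=sweep_freq,
    )
    return new_panel, truth


def simulate_study(
    params: SimulationParams, sweeps: list[dict] | None = None
) -> tuple[HaplotypePanel, list[SweepTruth]]:
    """Neutral panel plus a list of injected sweeps (default: default-study five)."""
    if sweeps is None:
        sweeps = default_study_sweeps()
    panel = simulate_panel(params)
    ss = np.random.SeedSequence(params.seed).spawn(len(sweeps) + 1)
    truths: list[SweepTruth] = []
    for child, spec in zip(ss[1:], sweeps):
        panel, truth = inject_sweep(
            panel,
            pop=spec["pop"],
            chrom=spec["chrom"],
            center_bp=spec["center_bp"],
            width_bp=spec["width_bp"],
            sweep_freq=spec["sweep_freq"],
            seed=child,
        )
        truths.append(truth)
    return panel, truths


def write_truth_bed(truths: list[SweepTruth], path) -> None:
    with open(path, "w") as fh:
        for t in truths:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.pop}\t{t.sweep_freq:g}\n"
            )


def read_truth_bed(path) -> list[SweepTruth]:
    out: list[SweepTruth] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, pop, freq = line.split("\t")
            out.append(
                SweepTruth(
                    pop=pop,
                    interval=GenomicInterval(chrom, int(start), int(end), pop),
                    sweep_freq=float(freq),
                )
            )
    return out
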