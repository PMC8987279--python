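"""End-to-end orchestration: filter -> per-contrast scans -> consensus ->
cross-contrast intersection -> dAF enrichment -> annotation.

Every stage writes its table under the output directory and the run manifest
records the configuration echo, package version, seed and per-stage row
counts, so a rerun with the same configuration and seed reproduces the output
bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from functools import reduce
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import HaplotypePanel, SweepTruth
from .vcf_io import (
    read_vcf, write_vcf, write_popmap, filter_sites, read_intervals, write_bed,
)
from .synthetic_data import (
    SimulationParams, simulate_study, default_study_sweeps, write_truth_bed,
)
from .diversity_stats import (
    windowed_fst, windowed_pi, log2_pi_ratio, site_frequencies, delta_af,
    breed_specific_snvs,
)
from .haplotype_stats import xpehh_scan
from .sweep_scan import (
    make_windows, window_xpehh, flag_tail, consensus_regions,
    intersect_contrasts, count_high_daf, recovery_metrics, regions_to_bed,
    SweepRegion,
)
from .annotate import genes_in_regions, qtl_overlap, regions_as_intervals

logger = logging.getLogger(__name__)

_TSV_KW = dict(sep="\t", index=False, na_rep="NA", float_format="%.6g")


@dataclass
class ScanConfig:
    """One configuration object for the whole scan."""

    vcf: str | None = None
    popmap: str | None = None
    gtf: str | None = None
    qtl_bed: str | None = None
    outdir: str = "sweepscan_out"
    target_pop: str = "target"
    reference_pops: list[str] = field(default_factory=lambda: ["ref1", "ref2"])
    # site filters
    maf_min: float = 0.01
    min_call_rate: float = 0.3
    qual_min: float = 30.0
    # windowing / consensus
    window_size: int = 100_000
    window_step: int = 10_000
    tail: float = 0.05
    min_methods: int = 2
    min_snps: int = 10
    daf_cutoff: float = 0.8
    xpehh_summary: str = "mean"
    use_xpehh: bool = True
    # XP-EHH scoring
    xpehh_cutoff: float = 0.05
    xpehh_maf_min: float = 0.05
    xpehh_max_gap_bp: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_pop in self.reference_pops:
            raise ValueError("target_pop must not appear in reference_pops")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScanConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class ScanResult:
    regions: list[SweepRegion]
    regions_by_contrast: dict[str, list[SweepRegion]]
    windows_by_contrast: dict[str, pd.DataFrame]
    thresholds: pd.DataFrame
    daf: pd.DataFrame
    enrichment: dict
    manifest: dict


def _multi_ref_daf(panel: HaplotypePanel, target: str, refs: list[str]) -> pd.DataFrame:
    freqs = site_frequencies(panel, [target] + refs)
    if len(refs) == 2:
        daf = delta_af(
            freqs[f"af_{target}"], freqs[f"af_{refs[0]}"], freqs[f"af_{refs[1]}"]
        )
    else:
        ref_mean = np.nanmean(
            np.stack([freqs[f"af_{p}"].to_numpy() for p in refs]), axis=0
        )
        daf = np.abs(freqs[f"af_{target}"].to_numpy() - ref_mean)
    out = freqs[["chrom", "pos"] + [f"af_{p}" for p in [target] + refs]].copy()
    out["daf"] = daf
    return out


def run_scan(config: ScanConfig, panel: HaplotypePanel | None = None) -> ScanResult:
    """Run the full consensus scan; returns the result bundle and writes it
    under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    stage = "load"
    try:
        if panel is None:
            if not config.vcf or not config.popmap:
                raise ValueError("config needs vcf and popmap when no panel is given")
            panel = read_vcf(config.vcf, config.popmap)
        n_before = panel.n_sites
        panel = filter_sites(
            panel, config.maf_min, config.min_call_rate, config.qual_min
        )
        manifest["stages"]["filter"] = {
            "sites_in": n_before, "sites_kept": panel.n_sites,
        }

        stage = "windows"
        grid = make_windows(panel.chrom_lengths, config.window_size, config.window_step)
        manifest["stages"]["windows"] = {"n_windows": grid.n_windows}

        methods = ["FST", "PI_RATIO"] + (["XPEHH"] if config.use_xpehh else [])
        regions_by_contrast: dict[str, list[SweepRegion]] = {}
        windows_by_contrast: dict[str, pd.DataFrame] = {}
        threshold_rows = []
        for ref in config.reference_pops:
            contrast = f"{config.target_pop}_vs_{ref}"
            stage = f"fst[{contrast}]"
            wfst = windowed_fst(panel, config.target_pop, ref, grid, config.min_snps)
            stage = f"pi[{contrast}]"
            pi_t = windowed_pi(panel, config.target_pop, grid, config.min_snps)
            pi_r = windowed_pi(panel, ref, grid, config.min_snps)
            ratio = log2_pi_ratio(pi_r["pi"].to_numpy(), pi_t["pi"].to_numpy())
            win = wfst.copy()
            win["pi_target"] = pi_t["pi"]
            win["pi_ref"] = pi_r["pi"]
            win["log2_pi_ratio"] = ratio
            scores = {"FST": win["fst"].to_numpy(), "PI_RATIO": ratio}
            if config.use_xpehh:
                stage = f"xpehh[{contrast}]"
                try:
                    xp = xpehh_scan(
                        panel, config.target_pop, ref,
                        cutoff=config.xpehh_cutoff,
                        maf_min=config.xpehh_maf_min,
                        max_gap_bp=config.xpehh_max_gap_bp,
                    )
                except ValueError as exc:
                    if "unphased" in str(exc):
                        raise ValueError(
                            f"{exc}; XP-EHH needs phased data "
                            "(disable with use_xpehh=False / --no-xpehh)"
                        ) from exc
                    raise
                wxp = window_xpehh(xp, grid, config.min_snps, config.xpehh_summary)
                win["xpehh"] = wxp["xpehh"]
                scores["XPEHH"] = wxp["xpehh"].to_numpy()
                xp.to_csv(outdir / f"xpehh_{contrast}.tsv", **_TSV_KW)

            stage = f"thresholds[{contrast}]"
            flags: dict[str, np.ndarray] = {}
            for method in methods:
                f, cutoff = flag_tail(scores[method], config.tail)
                flags[method] = f
                win[f"flag_{method}"] = f
                threshold_rows.append(
                    {
                        "contrast": contrast, "method": method,
                        "tail": config.tail, "cutoff": cutoff,
                        "n_scored": int(np.isfinite(scores[method]).sum()),
                        "n_flagged": int(f.sum()),
                    }
                )
            stage = f"consensus[{contrast}]"
            regions_c = consensus_regions(flags, grid, config.min_methods, contrast)
            regions_by_contrast[contrast] = regions_c
            windows_by_contrast[contrast] = win
            win.to_csv(outdir / f"windows_{contrast}.tsv", **_TSV_KW)
            regions_to_bed(regions_c, outdir / f"regions_{contrast}.bed")
            manifest["stages"][contrast] = {
                "n_regions": len(regions_c),
                "n_windows_scored": int(np.isfinite(scores["FST"]).sum()),
            }

        stage = "intersect"
        regions = reduce(intersect_contrasts, regions_by_contrast.values())
        manifest["stages"]["intersect"] = {"n_regions": len(regions)}

        stage = "daf"
        daf = _multi_ref_daf(panel, config.target_pop, config.reference_pops)
        regions, enrichment = count_high_daf(regions, daf, config.daf_cutoff)
        daf.to_csv(outdir / "daf.tsv", **_TSV_KW)
        manifest["stages"]["daf"] = {
            k: v for k, v in enrichment.items() if isinstance(v, int)
        }
        freqs_bs = breed_specific_snvs(
            site_frequencies(
                panel, [config.target_pop] + list(config.reference_pops)
            ),
            config.target_pop,
            list(config.reference_pops),
        )
        freqs_bs.to_csv(outdir / "breed_specific_snvs.tsv", **_TSV_KW)
        manifest["stages"]["breed_specific"] = {"n_snvs": len(freqs_bs)}

        regions_to_bed(regions, outdir / "regions_final.bed")

        stage = "annotate"
        if config.gtf:
            genes = read_intervals(config.gtf, "gtf")
            anns, gene_list = genes_in_regions(regions_as_intervals(regions), genes)
            _write_gene_tsv(anns, outdir / "region_genes.tsv")
            (outdir / "gene_list.txt").write_text(
                "".join(g + "\n" for g in gene_list)
            )
            manifest["stages"]["genes"] = {"n_genes": len(gene_list)}
        if config.qtl_bed:
            qtls = read_intervals(config.qtl_bed, "bed")
            anns, tally, fractions = qtl_overlap(
                regions_as_intervals(regions), qtls
            )
            _write_qtl_tsv(anns, tally, fractions, outdir)
            manifest["stages"]["qtls"] = {"n_qtls": sum(tally.values())}
    except Exception as exc:
        raise RuntimeError(f"scan failed at stage {stage!r}: {exc}") from exc

    thresholds = pd.DataFrame(threshold_rows)
    thresholds.to_csv(outdir / "thresholds.tsv", **_TSV_KW)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return ScanResult(
        regions=regions,
        regions_by_contrast=regions_by_contrast,
        windows_by_contrast=windows_by_contrast,
        thresholds=thresholds,
        daf=daf,
        enrichment=enrichment,
        manifest=manifest,
    )


def _write_gene_tsv(anns, path) -> None:
    rows = []
    for ann in anns:
        for label, bp in ann.genes:
            rows.append(
                {
                    "chrom": ann.region.chrom,
                    "start": ann.region.start,
                    "end": ann.region.end,
                    "gene": label,
                    "overlap_bp": bp,
                }
            )
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene", "overlap_bp"]
    ).to_csv(path, **_TSV_KW)


def _write_qtl_tsv(anns, tally, fractions, outdir: Path) -> None:
    rows = []
    for ann in anns:
        for trait, bp in ann.qtls:
            rows.append(
                {
                    "chrom": ann.region.chrom,
                    "start": ann.region.start,
                    "end": ann.region.end,
                    "trait": trait,
                    "overlap_bp": bp,
                }
            )
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "trait", "overlap_bp"]
    ).to_csv(outdir / "region_qtls.tsv", **_TSV_KW)
    pd.DataFrame(
        [
            {"trait": t, "n_qtls": c, "fraction": fractions.get(t, 0.0)}
            for t, c in sorted(tally.items())
        ],
        columns=["trait", "n_qtls", "fraction"],
    ).to_csv(outdir / "qtl_trait_tally.tsv", **_TSV_KW)


def run_simulate(
    params: SimulationParams,
    outdir: str | Path,
    sweeps: list[dict] | None = None,
) -> dict[str, str]:
    """Simulate a study panel with injected sweeps and write the bundle
    (phased VCF, popmap, truth BED, parameter echo, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sweeps is None:
        sweeps = default_study_sweeps()
    panel, truths = simulate_study(params, sweeps)
    paths = {
        "vcf": str(outdir / "panel.vcf"),
        "popmap": str(outdir / "popmap.txt"),
        "truth_bed": str(outdir / "truth.bed"),
        "params": str(outdir / "params.yaml"),
    }
    write_vcf(panel, paths["vcf"])
    write_popmap(panel.pop_of, paths["popmap"])
    write_truth_bed(truths, paths["truth_bed"])
    with open(paths["params"], "w") as fh:
        yaml.safe_dump(
            {"simulation": params.to_dict(), "sweeps": sweeps}, fh, sort_keys=True
        )
    manifest = {
        "version": __version__,
        "seed": params.seed,
        "n_samples": panel.n_samples,
        "n_sites": panel.n_sites,
        "n_sweeps": len(truths),
        "paths": paths,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def evaluate_recovery(result: ScanResult, truths: list[SweepTruth],
                      chrom_lengths: dict[str, int]) -> dict:
    """Convenience: recovery metrics of a scan against simulator truth."""
    return recovery_metrics(result.regions, truths, chrom_lengths)
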