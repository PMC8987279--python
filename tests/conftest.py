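import numpy as np
import pytest

from sweepscan.core import ChromData, HaplotypePanel


def build_panel(
    gt,
    pos=None,
    chrom="chr1",
    samples=None,
    pop_of=None,
    chrom_length=None,
    phased=True,
    qual=None,
):
    """Assemble a single-chromosome panel from an (m, n, 2) genotype array."""
    gt = np.asarray(gt, dtype=np.int8)
    m, n, _ = gt.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if pop_of is None:
        pop_of = {s: "pop1" for s in samples}
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    pos = np.asarray(pos, dtype=np.int64)
    if qual is None:
        qual = np.full(m, np.nan)
    data = ChromData(
        pos=pos,
        ref=np.full(m, "A"),
        alt=np.full(m, "C"),
        qual=np.asarray(qual, dtype=np.float64),
        gt=gt,
        phased=np.full((m, n), bool(phased)),
    )
    length = int(chrom_length) if chrom_length is not None else int(pos.max())
    return HaplotypePanel(
        samples=list(samples),
        pop_of=dict(pop_of),
        chroms={chrom: data},
        chrom_lengths={chrom: length},
    )


def panel_from_haps(haps, pos=None, chrom="chr1", pops=None, chrom_length=None):
    """Panel from a (2n, m) haplotype matrix; haplotypes 2i, 2i+1 pair up."""
    haps = np.asarray(haps, dtype=np.int8)
    n_hap, m = haps.shape
    assert n_hap % 2 == 0
    n = n_hap // 2
    gt = np.empty((m, n, 2), dtype=np.int8)
    gt[:, :, 0] = haps[0::2].T
    gt[:, :, 1] = haps[1::2].T
    if pops is None:
        pops = ["pop1"] * n
    samples = [f"s{i}" for i in range(n)]
    return build_panel(
        gt,
        pos=pos,
        chrom=chrom,
        samples=samples,
        pop_of=dict(zip(samples, pops)),
        chrom_length=chrom_length,
    )


@pytest.fixture
def three_sample_vcf(tmp_path):
    """A tiny phased VCF (3 samples, 2 sites) plus its popmap."""
    vcf = tmp_path / "tiny.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
        "chr1\t100\t.\tA\tC\t50\t.\t.\tGT\t0|0\t0|1\t1|1\n"
        "chr1\t200\t.\tG\tT\t60\t.\t.\tGT\t1|0\t0|0\t0|1\n"
    )
    popmap = tmp_path / "pops.txt"
    popmap.write_text("# sample pop\na p1\nb p1\nc p2\n")
    return vcf, popmap
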