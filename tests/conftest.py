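"""Shared fixtures: the toy two-exon transcript used across coordinate tests
and a session-scoped synthetic exome bundle (reference, transcript DB, BED,
BAM, VCF) generated by the fixtures module."""

import numpy as np
import pytest

from opexlite.coverage_qc import BedRegion
from opexlite.fixtures import (
    FixtureSpec,
    RegionSpec,
    VariantTruth,
    make_reference,
    simulate_alignments,
    spike_variants,
    write_bed,
)
from opexlite.transcripts import Transcript, write_transcript_db


@pytest.fixture
def toy_transcript():
    """Two-exon plus-strand transcript: exons [(100,200),(300,400)] 0-based
    half-open, CDS [150,350); coding length 100."""
    return Transcript(
        gene_symbol="GENE",
        transcript_id="TX1",
        is_ccds=False,
        chrom="chr1",
        strand="+",
        exons=[(100, 200), (300, 400)],
        cds_start=150,
        cds_end=350,
    )


@pytest.fixture
def toy_transcript_minus():
    """Same exon structure on the minus strand (CDS mirrored by symmetry)."""
    return Transcript(
        gene_symbol="GENE",
        transcript_id="TX1M",
        is_ccds=False,
        chrom="chr1",
        strand="-",
        exons=[(100, 200), (300, 400)],
        cds_start=150,
        cds_end=350,
    )


def _bundle_transcripts():
    t1 = Transcript(
        gene_symbol="GENE1",
        transcript_id="TX_A",
        is_ccds=True,
        chrom="chr1",
        strand="+",
        exons=[(1000, 1200), (1400, 1600), (1800, 2000)],
        cds_start=1050,
        cds_end=1900,
    )
    t2 = Transcript(
        gene_symbol="GENE2",
        transcript_id="TX_B",
        is_ccds=False,
        chrom="chr1",
        strand="-",
        exons=[(5000, 5300), (5600, 5900)],
        cds_start=5100,
        cds_end=5800,
    )
    return [t1, t2]


@pytest.fixture(scope="session")
def exome_bundle(tmp_path_factory):
    """A complete small synthetic exome: 20-kb contig, two genes, three BED
    targets (one shallow and intergenic), ~50x alignments and five spiked
    variants with known intended flags."""
    out = tmp_path_factory.mktemp("bundle")
    spec = FixtureSpec(
        seed=20_160_803,
        contigs={"chr1": 20_000},
        homopolymers=[("chr1", 9_001, "A", 20)],
    )
    ref_path, reference = make_reference(spec, str(out))
    transcripts = _bundle_transcripts()
    db_path = str(out / "transcripts.tsv")
    write_transcript_db(transcripts, db_path)

    regions = [
        RegionSpec("chr1", 1000, 1200, depth=50, frac_low_mq=0.1),
        RegionSpec("chr1", 1400, 1600, depth=50),
        RegionSpec("chr1", 15_000, 15_200, depth=5),  # shallow, gene desert
    ]
    bed_path = str(out / "targets.bed")
    write_bed([r.to_bed_region(f"r{i}") for i, r in enumerate(regions)], bed_path)
    bam_path = str(out / "sample.bam")
    read_truth = simulate_alignments(spec.seed, reference, regions, bam_path)

    seq = reference["chr1"]

    def sub(pos, flag):
        ref_base = seq[pos - 1]
        alt = "A" if ref_base != "A" else "G"
        return VariantTruth.for_flag("chr1", pos, ref_base, alt, flag)

    def dele(pos, length, flag):
        return VariantTruth.for_flag(
            "chr1", pos, seq[pos - 1 : pos + length], seq[pos - 1], flag
        )

    variants = [
        sub(1100, "high"),  # GENE1 CDS
        sub(1450, "low"),
        dele(1500, 2, "high"),
        VariantTruth.for_flag("chr1", 5650, seq[5649], seq[5649] + "TT", "low"),
        sub(15_050, "high"),  # intergenic: removed downstream
    ]
    vcf_path = str(out / "sample.vcf")
    spike_variants(variants, reference, vcf_path)

    return {
        "dir": out,
        "spec": spec,
        "reference_path": ref_path,
        "reference": reference,
        "transcripts": transcripts,
        "transcripts_path": db_path,
        "regions": regions,
        "bed_path": bed_path,
        "bam_path": bam_path,
        "read_truth": read_truth,
        "variant_truth": variants,
        "vcf_path": vcf_path,
    }


def build_trio_bundle(out_dir, seed=11, n_inherited=200, father_shallow_index=None):
    """A proband-parent trio with known truth: inherited variants shared by
    all three members (indels written right-aligned in the mother's VCF),
    five de novo variants confined to the proband, and parental alignments
    covering the de novo sites at ~50x (optionally one site at 10x in the
    father, to exercise the parental-coverage filter)."""
    from pathlib import Path

    from opexlite.fixtures import TrioSpec, make_trio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = FixtureSpec(seed=seed, contigs={"chr1": 30_000})
    _, reference = make_reference(spec, str(out_dir))
    seq = reference["chr1"]
    gene = Transcript(
        gene_symbol="GENE1",
        transcript_id="TX_A",
        is_ccds=True,
        chrom="chr1",
        strand="+",
        exons=[(1000, 1400), (1600, 2000), (2200, 2600)],
        cds_start=1100,
        cds_end=2500,
    )
    db_path = str(out_dir / "transcripts.tsv")
    write_transcript_db([gene], db_path)

    def sub(pos):
        ref_base = seq[pos - 1]
        return VariantTruth.for_flag(
            "chr1", pos, ref_base, "A" if ref_base != "A" else "G", "high"
        )

    def dele(pos, length):
        return VariantTruth.for_flag(
            "chr1", pos, seq[pos - 1 : pos + length], seq[pos - 1], "high"
        )

    def ins(pos, insert):
        return VariantTruth.for_flag(
            "chr1", pos, seq[pos - 1], seq[pos - 1] + insert, "high"
        )

    # sites spaced >= 200 bp apart so each parental mini-region (50-bp reads,
    # +/-50 bp) covers exactly one site
    denovo_sites = [1150, 1350, 1700, 1950, 2300]
    denovo = [
        sub(1150),
        sub(1350),
        dele(1700, 2),
        ins(1950, "CT"),
        sub(2300),
    ]
    for v in denovo:
        v.is_denovo = True

    rng = np.random.default_rng(seed + 100)
    positions = rng.choice(np.arange(3000, 29_000), size=n_inherited, replace=False)
    inherited = []
    for k, pos in enumerate(sorted(int(p) for p in positions)):
        if k % 4 == 0:
            inherited.append(dele(pos, 1 + k % 3))
        elif k % 4 == 1:
            inherited.append(ins(pos, "ACGT"[: 1 + k % 4]))
        else:
            inherited.append(sub(pos))

    parent_regions = [
        RegionSpec("chr1", site - 50, site + 50, depth=50, read_len=50)
        for site in denovo_sites
    ]
    father_regions = None
    if father_shallow_index is not None:
        father_regions = list(parent_regions)
        shallow = denovo_sites[father_shallow_index]
        father_regions[father_shallow_index] = RegionSpec(
            "chr1", shallow - 50, shallow + 50, depth=5, read_len=50
        )
    spec.trio = TrioSpec(
        inherited=inherited,
        denovo=denovo,
        parent_regions=parent_regions,
        father_regions=father_regions,
        write_3prime_reps_in=frozenset({"mother"}),
    )
    truth = make_trio(spec, reference, str(out_dir / "trio"))
    return {
        "spec": spec,
        "reference": reference,
        "gene": gene,
        "db_path": db_path,
        "denovo_sites": denovo_sites,
        "paths": truth["paths"],
        "truth": truth,
    }


def brute_force_pileup(read_truth, region: BedRegion, mq_good=20, bq_low=10):
    """Independent per-base recount from the generator's truth table.

    Returns (cov, qcov, flmq, flbq) arrays; FLMQ/FLBQ are NaN where COV==0.
    """
    n = len(region)
    cov = np.zeros(n, dtype=int)
    qcov = np.zeros(n, dtype=int)
    low_mq = np.zeros(n, dtype=int)
    low_bq = np.zeros(n, dtype=int)
    nbq = np.zeros(n, dtype=int)
    for r in read_truth:
        if r.chrom != region.chrom or r.is_dup or r.is_secondary:
            continue
        lo = max(r.start, region.start)
        hi = min(r.end, region.end)
        for p in range(lo, hi):
            i = p - region.start
            cov[i] += 1
            if r.mq >= mq_good:
                qcov[i] += 1
            else:
                low_mq[i] += 1
            nbq[i] += 1
            if r.bq < bq_low:
                low_bq[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        flmq = np.where(cov > 0, low_mq / np.maximum(cov, 1), np.nan)
        flbq = np.where(nbq > 0, low_bq / np.maximum(nbq, 1), np.nan)
    flmq[cov == 0] = np.nan
    flbq[nbq == 0] = np.nan
    return cov, qcov, flmq, flbq
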