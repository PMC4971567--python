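"""Deterministic synthetic-data generation for exercising the pipeline.

Every generator is a pure function of a :class:`FixtureSpec` (or an explicit
seed), so identical specs produce byte-identical files.  Each generator also
returns a machine-readable truth table (read spans and qualities, intended
variant flags, de novo status) sufficient to recompute every downstream
metric without re-parsing the generated files — reads are error-free at
spiked positions, which keeps oracle bookkeeping exact.

The generated genome is small (tens of kb to ~1 Mb) so the full test suite
runs in minutes on one CPU; declared homopolymer or repeat tracts can be
inserted to exercise the sequence contexts where short-read indel calling is
known to struggle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pysam

from .consequence import fetch_ref, shift_indel
from .coverage_qc import BedRegion
from .transcripts import Transcript
from .variants import classify_variant_type

__all__ = [
    "FixtureSpec",
    "RegionSpec",
    "VariantTruth",
    "ReadTruth",
    "TrioSpec",
    "make_reference",
    "simulate_alignments",
    "spike_variants",
    "make_trio",
    "write_bed",
    "random_transcript",
    "random_indel_record",
    "DEFAULT_READ_LEN",
]

DEFAULT_READ_LEN = 100


@dataclass(frozen=True)
class RegionSpec:
    """Read-simulation parameters for one target region (0-based half-open).

    Depth is the target mean coverage; ``frac_low_mq``/``frac_low_bq`` are
    the per-read probabilities of drawing the low mapping/base quality value
    instead of the good one; ``dup_rate`` flags reads as PCR duplicates.
    """

    chrom: str
    start: int
    end: int
    depth: int = 50
    read_len: int = DEFAULT_READ_LEN
    frac_low_mq: float = 0.0
    frac_low_bq: float = 0.0
    dup_rate: float = 0.0
    mq_good_value: int = 60
    mq_low_value: int = 10
    bq_good_value: int = 35
    bq_low_value: int = 5

    def to_bed_region(self, name: str = ".") -> BedRegion:
        return BedRegion(self.chrom, self.start, self.end, name)


@dataclass
class VariantTruth:
    """One spiked variant with the caller fields chosen to hit a flag."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 150.0
    filter: str = "PASS"
    tr: int = 20
    tc: int = 50
    intended_flag: str = "high"
    is_denovo: bool = False

    @classmethod
    def for_flag(
        cls,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        flag: str,
        tc: int = 50,
        **kwargs,
    ) -> "VariantTruth":
        """Choose QUAL/FILTER/TR so the quality-flag rule reproduces ``flag``."""
        vtype, _, _ = classify_variant_type(ref, alt)
        if vtype == "substitution":
            qual = 150.0 if flag == "high" else 50.0
            return cls(chrom, pos, ref, alt, qual=qual, filter="PASS",
                       tr=max(1, tc // 2), tc=tc, intended_flag=flag, **kwargs)
        # indel/complex: flag is driven by VAF and FILTER
        if flag == "high":
            tr = max(1, int(np.ceil(0.4 * tc)))
            filt = "PASS"
        else:
            tr = max(1, int(0.08 * tc))
            filt = "PASS" if tr / tc < 0.2 else "badReads"
        return cls(chrom, pos, ref, alt, qual=150.0, filter=filt,
                   tr=tr, tc=tc, intended_flag=flag, **kwargs)


@dataclass(frozen=True)
class ReadTruth:
    """Side-channel record of one simulated read: enough to recompute every
    pileup metric without parsing the alignment file."""

    name: str
    chrom: str
    start: int  # 0-based
    end: int  # 0-based exclusive (start + read_len, all-match alignment)
    mq: int
    bq: int  # uniform base quality across the read
    is_dup: bool = False
    is_secondary: bool = False


@dataclass
class TrioSpec:
    """Declared truth for a proband-parent trio fixture."""

    inherited: list[VariantTruth] = field(default_factory=list)
    denovo: list[VariantTruth] = field(default_factory=list)
    parent_regions: list[RegionSpec] = field(default_factory=list)
    father_regions: Optional[list[RegionSpec]] = None
    mother_regions: Optional[list[RegionSpec]] = None
    # family members whose VCF writes inherited indels right-aligned (3')
    write_3prime_reps_in: frozenset = frozenset()


@dataclass
class FixtureSpec:
    """Top-level fixture description: contigs, repeat tracts, targets and
    variant truth.  Identical specs yield byte-identical outputs."""

    seed: int
    contigs: dict = field(default_factory=lambda: {"chr1": 20_000})
    # (chrom, 1-based start, base, length)
    homopolymers: list = field(default_factory=list)
    regions: list = field(default_factory=list)
    variants: list = field(default_factory=list)
    trio: Optional[TrioSpec] = None


# -- reference ---------------------------------------------------------------


def make_reference(spec: FixtureSpec, out_dir: str, name: str = "ref") -> tuple[str, dict]:
    """Write a FASTA (plus .fai index) of uniform-random ACGT contigs with
    any declared homopolymer tracts; returns (path, {contig: sequence})."""
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    for contig, length in spec.contigs.items():
        if length < 1000:
            raise ValueError(f"contig {contig} shorter than 1 kb")
        arr = bases[rng.integers(0, 4, size=length)]
        seqs[contig] = "".join(arr)
    for chrom, start1, base, ln in spec.homopolymers:
        s = seqs[chrom]
        seqs[chrom] = s[: start1 - 1] + base * ln + s[start1 - 1 + ln :]
    path = os.path.join(out_dir, f"{name}.fa")
    with open(path, "w") as fh:
        for contig, seq in seqs.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(path)
    return path, seqs


# -- alignments --------------------------------------------------------------


def _simulate_region_reads(
    rng: np.random.Generator,
    reference: dict,
    region: RegionSpec,
    name_prefix: str,
) -> list[ReadTruth]:
    contig_len = len(reference[region.chrom])
    rl = region.read_len
    lo = max(0, region.start - rl + 1)
    hi = min(contig_len - rl, region.end - 1)
    if hi < lo:
        return []
    window = hi - lo + 1
    n_reads = int(round(region.depth * window / rl))
    starts = np.sort(rng.integers(lo, hi + 1, size=n_reads))
    low_mq = rng.random(n_reads) < region.frac_low_mq
    low_bq = rng.random(n_reads) < region.frac_low_bq
    dup = rng.random(n_reads) < region.dup_rate
    out = []
    for i, s in enumerate(starts):
        out.append(
            ReadTruth(
                name=f"{name_prefix}_{region.chrom}_{region.start}_{i}",
                chrom=region.chrom,
                start=int(s),
                end=int(s) + rl,
                mq=region.mq_low_value if low_mq[i] else region.mq_good_value,
                bq=region.bq_low_value if low_bq[i] else region.bq_good_value,
                is_dup=bool(dup[i]),
            )
        )
    return out


def simulate_alignments(
    spec_seed: int,
    reference: dict,
    regions: Sequence[RegionSpec],
    bam_path: str,
    name_prefix: str = "read",
) -> list[ReadTruth]:
    """Write a coordinate-sorted, indexed BAM of error-free paired reads
    tiling the declared regions, and return the read truth table."""
    rng = np.random.default_rng(spec_seed)
    truths: list[ReadTruth] = []
    for region in regions:
        truths.extend(_simulate_region_reads(rng, reference, region, name_prefix))
    truths.sort(key=lambda r: (r.chrom, r.start, r.name))
    write_alignments(truths, reference, bam_path)
    return truths


def write_alignments(truths: Sequence[ReadTruth], reference: dict, bam_path: str) -> None:
    """Write an explicit read list as a sorted, indexed BAM.

    Consecutive reads on the same contig are flagged as mates so the file
    resembles paired-end data; pairing does not affect any metric.
    """
    contigs = list(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in contigs],
    }
    tid = {c: i for i, c in enumerate(contigs)}
    ordered = sorted(truths, key=lambda r: (tid[r.chrom], r.start, r.name))
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for i, r in enumerate(ordered):
            a = pysam.AlignedSegment()
            a.query_name = r.name
            a.query_sequence = reference[r.chrom][r.start : r.end]
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = r.mq
            a.cigarstring = f"{r.end - r.start}M"
            a.query_qualities = pysam.qualitystring_to_array(
                chr(r.bq + 33) * (r.end - r.start)
            )
            flag = 0x1 | (0x40 if i % 2 == 0 else 0x80)
            if r.is_dup:
                flag |= 0x400
            if r.is_secondary:
                flag |= 0x100
            a.flag = flag
            a.next_reference_id = a.reference_id
            a.next_reference_start = r.start
            bam.write(a)
    pysam.index(bam_path)


# -- variants ----------------------------------------------------------------


def spike_variants(
    truths: Sequence[VariantTruth],
    reference: dict,
    vcf_path: str,
) -> list[VariantTruth]:
    """Write the truth variants as a VCF with QUAL/FILTER/INFO TR,TC chosen
    to reproduce each intended flag; returns the (sorted) truth list.

    Raises when a truth REF allele disagrees with the reference sequence.
    """
    for v in truths:
        genome_ref = fetch_ref(reference, v.chrom, v.pos, v.pos + len(v.ref) - 1)
        if genome_ref != v.ref.upper():
            raise ValueError(
                f"truth variant {v.chrom}:{v.pos} REF {v.ref!r} != genome {genome_ref!r}"
            )
        if v.tr > v.tc:
            raise ValueError(f"truth variant {v.chrom}:{v.pos}: TR > TC")
    ordered = sorted(truths, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, seq in reference.items():
            fh.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        fh.write('##INFO=<ID=TR,Number=A,Type=Integer,Description="Reads supporting variant">\n')
        fh.write('##INFO=<ID=TC,Number=1,Type=Integer,Description="Total reads at site">\n')
        fh.write('##FILTER=<ID=badReads,Description="Poor read evidence">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in ordered:
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{v.qual:g}\t{v.filter}\t"
                f"TR={v.tr};TC={v.tc}\n"
            )
    return ordered


def _to_3prime_truth(v: VariantTruth, reference: dict) -> VariantTruth:
    """Rewrite an indel truth record in its most-3' representation."""
    from .variants import VariantRecord

    vtype, _, _ = classify_variant_type(v.ref, v.alt)
    if vtype not in ("insertion", "deletion"):
        return v
    rec = VariantRecord(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt)
    s = shift_indel(reference, rec)
    return replace(v, pos=s.pos_3prime, ref=s.ref_3prime, alt=s.alt_3prime)


def make_trio(
    spec: FixtureSpec, reference: dict, out_dir: str
) -> dict:
    """Write proband/father/mother VCFs and two parental BAMs per the trio
    spec; returns paths plus the truth tables.

    Parents carry the inherited variants (optionally in their most-3'
    representation, to exercise representation-invariant matching); de novo
    variants appear only in the proband.
    """
    trio = spec.trio
    if trio is None:
        raise ValueError("FixtureSpec has no trio section")
    os.makedirs(out_dir, exist_ok=True)

    def member_variants(member: str) -> list[VariantTruth]:
        inherited = trio.inherited
        if member in trio.write_3prime_reps_in:
            inherited = [_to_3prime_truth(v, reference) for v in inherited]
        if member == "proband":
            return inherited + trio.denovo
        return inherited

    paths = {}
    for member in ("proband", "father", "mother"):
        vcf_path = os.path.join(out_dir, f"{member}.vcf")
        spike_variants(member_variants(member), reference, vcf_path)
        paths[f"{member}_vcf"] = vcf_path

    truth_reads = {}
    for member, regions in (
        ("father", trio.father_regions or trio.parent_regions),
        ("mother", trio.mother_regions or trio.parent_regions),
    ):
        bam_path = os.path.join(out_dir, f"{member}.bam")
        truth_reads[member] = simulate_alignments(
            spec.seed + (1 if member == "father" else 2),
            reference,
            regions,
            bam_path,
            name_prefix=member,
        )
        paths[f"{member}_bam"] = bam_path
    return {
        "paths": paths,
        "denovo_truth": list(trio.denovo),
        "inherited_truth": list(trio.inherited),
        "read_truth": truth_reads,
    }


# -- misc helpers ------------------------------------------------------------


def write_bed(regions: Sequence[BedRegion], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


def random_transcript(
    rng: np.random.Generator,
    chrom: str,
    contig_len: int,
    gene: str = "GENE",
    transcript_id: str = "TX1",
    n_exons: Optional[int] = None,
    strand: Optional[str] = None,
    is_ccds: bool = False,
) -> Transcript:
    """Generate a structurally valid random transcript for property tests:
    2-6 exons of 30-200 bp separated by 30-300 bp introns, CDS bounds
    strictly inside the exonic span so both UTRs are non-empty."""
    if n_exons is None:
        n_exons = int(rng.integers(2, 7))
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = int(rng.integers(100, max(101, contig_len // 4)))
    for _ in range(n_exons):
        length = int(rng.integers(30, 201))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(30, 301))
    if exons[-1][1] >= contig_len:
        raise ValueError("contig too short for requested transcript layout")
    # pick CDS bounds on exonic bases, leaving >=1 exonic base of UTR each side
    exonic = [p for s, e in exons for p in range(s, e)]
    i = int(rng.integers(1, len(exonic) // 2))
    j = int(rng.integers(len(exonic) // 2 + 1, len(exonic) - 1))
    return Transcript(
        gene_symbol=gene,
        transcript_id=transcript_id,
        is_ccds=is_ccds,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=exonic[i],
        cds_end=exonic[j] + 1,
    )


def random_indel_record(
    rng: np.random.Generator, reference: dict, chrom: str, max_len: int = 12
):
    """Generate a random anchored insertion or deletion consistent with the
    reference, away from the contig edges."""
    from .variants import VariantRecord

    seq = reference[chrom]
    ln = int(rng.integers(1, max_len + 1))
    pos = int(rng.integers(50, len(seq) - 50 - ln))
    anchor = seq[pos - 1]
    if rng.random() < 0.5:  # deletion of ln bases after the anchor
        ref = seq[pos - 1 : pos + ln]
        alt = anchor
    else:  # insertion of ln random bases after the anchor
        ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=ln)])
        ref = anchor
        alt = anchor + ins
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt)
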