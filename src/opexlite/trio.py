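"""Proband-parent trio analysis: candidate de novo variants.

A proband call is a candidate de novo variant when it is absent from both
parents (after representation-invariant matching of indels), its quality
flag is high, its total read depth TC is at least 15x, and both parents have
at least 15x good-quality coverage (mapping quality >= 20 by default) at the
site.  Candidates are partitioned into protein-altering and
protein-truncating sets by consequence class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .annotate import flag_and_annotate
from .consequence import normalized_key, protein_altering, protein_truncating
from .coverage_qc import DEFAULT_MQ_GOOD, BedRegion, pileup_profile
from .transcripts import Transcript, TranscriptIndex
from .variants import FlaggedVariant, VariantRecord, parse_vcf

__all__ = [
    "TrioCandidate",
    "subtract_parents",
    "parental_coverage",
    "apply_denovo_filters",
    "partition_by_consequence",
    "run_trio",
    "DEFAULT_TC_MIN",
    "DEFAULT_PARENT_COV_MIN",
]

DEFAULT_TC_MIN = 15
DEFAULT_PARENT_COV_MIN = 15


@dataclass
class TrioCandidate:
    """A proband variant surviving the de novo filters."""

    variant: FlaggedVariant
    father_qcov: int
    mother_qcov: int

    @property
    def is_protein_altering(self) -> bool:
        return self.variant.consequence != "." and protein_altering(self.variant.consequence)

    @property
    def is_protein_truncating(self) -> bool:
        return self.variant.consequence != "." and protein_truncating(self.variant.consequence)


def subtract_parents(
    proband: Sequence[VariantRecord],
    father: Sequence[VariantRecord],
    mother: Sequence[VariantRecord],
    ref_genome,
) -> list[VariantRecord]:
    """Proband variants present in neither parent.

    Matching is exact-allele on the representation-invariant key (indels are
    5'-normalised on both sides), ignoring quality: a low-quality parental
    call still counts as present, which is conservative against false de
    novo claims.
    """
    parental = {normalized_key(ref_genome, v) for v in father}
    parental |= {normalized_key(ref_genome, v) for v in mother}
    return [v for v in proband if normalized_key(ref_genome, v) not in parental]


def parental_coverage(
    bam_path: str,
    chrom: str,
    pos: int,
    mq_good: int = DEFAULT_MQ_GOOD,
    use_mq_filter: bool = True,
) -> int:
    """Depth at one 1-based position: mapping-quality-filtered (QCOV) by
    default, plain depth when ``use_mq_filter`` is False."""
    profile = pileup_profile(bam_path, BedRegion(chrom, pos - 1, pos), mq_good=mq_good)
    return int(profile.qcov[0] if use_mq_filter else profile.cov[0])


def apply_denovo_filters(
    candidates: Sequence[FlaggedVariant],
    father_bam: str,
    mother_bam: str,
    ref_genome=None,
    tc_min: int = DEFAULT_TC_MIN,
    parent_cov_min: int = DEFAULT_PARENT_COV_MIN,
    mq_good: int = DEFAULT_MQ_GOOD,
    use_mq_filter: bool = True,
) -> list[TrioCandidate]:
    """Keep candidates with flag high, TC >= tc_min and both parents'
    coverage >= parent_cov_min at the variant position.

    For indels the position checked is the anchor base of the most-5'
    representation (requires ``ref_genome``); substitutions use their
    reported position.
    """
    out: list[TrioCandidate] = []
    for fv in candidates:
        r = fv.record
        if fv.flag != "high":
            continue
        if r.tc is None or r.tc < tc_min:
            continue
        pos = r.pos
        if ref_genome is not None and fv.vtype in ("insertion", "deletion"):
            from .consequence import shift_indel

            pos = shift_indel(ref_genome, r).pos_5prime
        f_cov = parental_coverage(father_bam, r.chrom, pos, mq_good, use_mq_filter)
        if f_cov < parent_cov_min:
            continue
        m_cov = parental_coverage(mother_bam, r.chrom, pos, mq_good, use_mq_filter)
        if m_cov < parent_cov_min:
            continue
        out.append(TrioCandidate(variant=fv, father_qcov=f_cov, mother_qcov=m_cov))
    return out


def partition_by_consequence(
    candidates: Sequence[TrioCandidate],
) -> tuple[list[TrioCandidate], list[TrioCandidate], list[TrioCandidate]]:
    """(protein_altering, protein_truncating, other); the truncating list is
    a subset of the altering list."""
    altering = [c for c in candidates if c.is_protein_altering]
    truncating = [c for c in candidates if c.is_protein_truncating]
    other = [c for c in candidates if not c.is_protein_altering]
    return altering, truncating, other


def run_trio(
    proband_vcf: str,
    father_vcf: str,
    mother_vcf: str,
    father_bam: str,
    mother_bam: str,
    db: "Sequence[Transcript] | TranscriptIndex",
    ref_genome,
    tc_min: int = DEFAULT_TC_MIN,
    parent_cov_min: int = DEFAULT_PARENT_COV_MIN,
    mq_good: int = DEFAULT_MQ_GOOD,
    use_mq_filter: bool = True,
    qual_high: float = 100.0,
    vaf_high: float = 0.2,
) -> list[TrioCandidate]:
    """End-to-end trio analysis from three VCFs and two parental BAMs."""
    proband = parse_vcf(proband_vcf)
    father = parse_vcf(father_vcf)
    mother = parse_vcf(mother_vcf)
    novel = subtract_parents(proband, father, mother, ref_genome)
    flagged = flag_and_annotate(novel, db, ref_genome, qual_high=qual_high, vaf_high=vaf_high)
    return apply_denovo_filters(
        flagged,
        father_bam,
        mother_bam,
        ref_genome=ref_genome,
        tc_min=tc_min,
        parent_cov_min=parent_cov_min,
        mq_good=mq_good,
        use_mq_filter=use_mq_filter,
    )
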