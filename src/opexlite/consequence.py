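"""Simplified variant-consequence classes and most-5'/most-3' indel
representations.

An indel embedded in repetitive sequence has several equally valid VCF
representations; the most-5' (left-aligned) and most-3' (right-aligned)
forms are both computed by repeat-walk shifting so that downstream users can
compare against either convention.  Classes are a simplified ten-value
vocabulary:

SY   synonymous substitution          NSY  non-synonymous substitution
SG   stop gain                        FS   frameshifting coding indel
IF   in-frame coding indel            ESS  essential splice site (intron +/-1-2)
SS   splice-region (intron +/-3-8)    EE   first/last 3 exonic bases of an
INT  other intronic                        internal exon
UTR  untranslated exonic

Protein-altering classes are {NSY, EE, IF, ESS, SG, FS}; the
protein-truncating subset is {ESS, SG, FS}.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .transcripts import Transcript, genomic_to_csn
from .variants import VariantRecord, classify_variant_type

__all__ = [
    "ShiftedIndel",
    "ReferenceMismatchError",
    "fetch_ref",
    "contig_length",
    "shift_indel",
    "assign_class",
    "protein_altering",
    "protein_truncating",
    "normalized_key",
    "CLASS_SEVERITY",
    "PROTEIN_ALTERING_CLASSES",
    "PROTEIN_TRUNCATING_CLASSES",
]

PROTEIN_ALTERING_CLASSES = frozenset({"NSY", "EE", "IF", "ESS", "SG", "FS"})
PROTEIN_TRUNCATING_CLASSES = frozenset({"ESS", "SG", "FS"})
_ALL_CLASSES = frozenset({"SY", "NSY", "SG", "FS", "IF", "ESS", "EE", "SS", "INT", "UTR"})

# most severe first; ties in multi-zone variants resolve to the highest rank
CLASS_SEVERITY = ["SG", "FS", "ESS", "NSY", "EE", "IF", "SS", "SY", "UTR", "INT"]
_SEVERITY_RANK = {c: i for i, c in enumerate(CLASS_SEVERITY)}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class ReferenceMismatchError(ValueError):
    """The REF allele does not match the reference genome sequence."""


def fetch_ref(ref_genome, chrom: str, start: int, end: int) -> str:
    """Fetch reference sequence for a 1-based inclusive interval.

    Accepts a pysam.FastaFile, a pyfaidx.Fasta, or a plain mapping of contig
    name to sequence string.
    """
    if end < start:
        return ""
    if hasattr(ref_genome, "fetch"):
        return ref_genome.fetch(chrom, start - 1, end).upper()
    seq = ref_genome[chrom]
    if isinstance(seq, str):
        return seq[start - 1 : end].upper()
    return str(seq[start - 1 : end]).upper()


def contig_length(ref_genome, chrom: str) -> int:
    if hasattr(ref_genome, "get_reference_length"):
        return ref_genome.get_reference_length(chrom)
    return len(ref_genome[chrom])


@dataclass(frozen=True)
class ShiftedIndel:
    """The most-5' and most-3' anchored representations of one indel.

    Positions are the 1-based anchor base of the VCF-style representation;
    ``seq_*`` is the inserted/deleted sequence at each representation.
    Applying either representation to the reference yields the identical
    edited sequence.
    """

    chrom: str
    vtype: str  # insertion | deletion
    pos_5prime: int
    ref_5prime: str
    alt_5prime: str
    seq_5prime: str
    pos_3prime: int
    ref_3prime: str
    alt_3prime: str
    seq_3prime: str

    def __post_init__(self) -> None:
        if self.pos_5prime > self.pos_3prime:
            raise ValueError("5' representation must not lie 3' of the 3' one")


def shift_indel(ref_genome, v: VariantRecord) -> ShiftedIndel:
    """Compute the most-5' and most-3' representations of an anchored indel
    by repeat-walk shifting.

    Shifting stops at the contig edges; the REF allele must match the
    reference genome at the variant position.
    """
    vtype, ln, _ = classify_variant_type(v.ref, v.alt)
    if vtype not in ("insertion", "deletion"):
        raise ValueError(f"shift_indel requires an anchored indel, got {vtype}")
    genome_ref = fetch_ref(ref_genome, v.chrom, v.pos, v.pos + len(v.ref) - 1)
    if genome_ref != v.ref.upper():
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos} REF {v.ref!r} != genome {genome_ref!r}"
        )
    clen = contig_length(ref_genome, v.chrom)
    base = lambda p: fetch_ref(ref_genome, v.chrom, p, p)  # noqa: E731

    if vtype == "deletion":
        L = ln
        p5 = v.pos
        while p5 > 1 and base(p5) == base(p5 + L):
            p5 -= 1
        p3 = v.pos
        while p3 + L + 1 <= clen and base(p3 + 1) == base(p3 + L + 1):
            p3 += 1
        seq5 = fetch_ref(ref_genome, v.chrom, p5 + 1, p5 + L)
        seq3 = fetch_ref(ref_genome, v.chrom, p3 + 1, p3 + L)
        return ShiftedIndel(
            chrom=v.chrom,
            vtype=vtype,
            pos_5prime=p5,
            ref_5prime=base(p5) + seq5,
            alt_5prime=base(p5),
            seq_5prime=seq5,
            pos_3prime=p3,
            ref_3prime=base(p3) + seq3,
            alt_3prime=base(p3),
            seq_3prime=seq3,
        )

    # insertion of S after the anchor base
    s5 = v.alt[len(v.ref) :].upper()
    p5 = v.pos
    while p5 > 1 and s5[-1] == base(p5):
        s5 = s5[-1] + s5[:-1]
        p5 -= 1
    s3 = v.alt[len(v.ref) :].upper()
    p3 = v.pos
    while p3 + 1 <= clen and s3[0] == base(p3 + 1):
        s3 = s3[1:] + s3[0]
        p3 += 1
    return ShiftedIndel(
        chrom=v.chrom,
        vtype=vtype,
        pos_5prime=p5,
        ref_5prime=base(p5),
        alt_5prime=base(p5) + s5,
        seq_5prime=s5,
        pos_3prime=p3,
        ref_3prime=base(p3),
        alt_3prime=base(p3) + s3,
        seq_3prime=s3,
    )


def normalized_key(ref_genome, v: VariantRecord) -> tuple[str, int, str, str]:
    """Representation-invariant identity key: indels are keyed by their
    most-5' form; substitutions and complex variants by their literal form."""
    vtype, _, _ = classify_variant_type(v.ref, v.alt)
    if vtype in ("insertion", "deletion"):
        s = shift_indel(ref_genome, v)
        return (v.chrom, s.pos_5prime, s.ref_5prime, s.alt_5prime)
    return (v.chrom, v.pos, v.ref.upper(), v.alt.upper())


# -- class assignment --------------------------------------------------------


def _zone_class(t: Transcript, pos: int, for_indel: bool, indel_len: int) -> str:
    """Candidate class for one affected genomic position."""
    csn = genomic_to_csn(t, pos)
    if csn.kind == "intronic":
        k = abs(csn.intron_offset)
        if k <= 2:
            return "ESS"
        if k <= 8:
            return "SS"
        return "INT"
    if csn.anchor_kind in ("utr5", "utr3"):
        return "UTR"
    # coding exonic
    if for_indel:
        cls = "FS" if indel_len % 3 != 0 else "IF"
        if t.is_internal_exon_edge(pos) and _SEVERITY_RANK["EE"] < _SEVERITY_RANK[cls]:
            cls = "EE"
        return cls
    return "coding-substitution"  # resolved by the caller with codon translation


def _translate_substitution(t: Transcript, pos: int, alt: str, ref_genome) -> str:
    """SY/NSY/SG for a coding substitution by translating the affected codon."""
    coding = t.coding_positions()
    csn = genomic_to_csn(t, pos)
    c = csn.coding_index  # 1-based coding position
    codon_start = ((c - 1) // 3) * 3
    codon_pos = coding[codon_start : codon_start + 3]
    if len(codon_pos) < 3:  # trailing partial codon: cannot translate
        return "NSY"
    bases = []
    for p in codon_pos:
        b = fetch_ref(ref_genome, t.chrom, p, p)
        if t.strand == "-":
            b = b.translate(_COMPLEMENT)
        bases.append(b)
    ref_codon = "".join(bases)
    i = (c - 1) % 3
    alt_base = alt.upper()
    if t.strand == "-":
        alt_base = alt_base.translate(_COMPLEMENT)
    alt_codon = ref_codon[:i] + alt_base + ref_codon[i + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        return "SG"
    return "SY" if ref_aa == alt_aa else "NSY"


def assign_class(v: VariantRecord, t: Transcript, ref_genome) -> str:
    """Assign the consequence class of a variant on one transcript.

    Indels are evaluated at their most-5' representation.  When the affected
    bases span multiple annotation zones (e.g. a deletion crossing an
    exon/intron boundary), the most severe applicable class is returned.
    """
    vtype, indel_len, _ = classify_variant_type(v.ref, v.alt)
    lo, hi = t.span
    if vtype in ("insertion", "deletion"):
        s = shift_indel(ref_genome, v)
        if vtype == "deletion":
            affected = range(s.pos_5prime + 1, s.pos_5prime + indel_len + 1)
        else:
            affected = (s.pos_5prime, s.pos_5prime + 1)
    elif vtype == "complex":
        affected = range(v.pos, v.pos + len(v.ref))
    else:
        affected = (v.pos,)
    candidates: list[str] = []
    for p in affected:
        if not (lo <= p <= hi):
            continue
        cls = _zone_class(t, p, for_indel=(vtype != "substitution"), indel_len=indel_len)
        if cls == "coding-substitution":
            cls = _translate_substitution(t, p, v.alt, ref_genome)
            if cls != "SG" and t.is_internal_exon_edge(p):
                cls = "EE"
        candidates.append(cls)
    if not candidates:
        raise ValueError(
            f"variant {v.chrom}:{v.pos} does not overlap transcript {t.transcript_id}"
        )
    return min(candidates, key=lambda c: _SEVERITY_RANK[c])


def protein_altering(cls: str) -> bool:
    """True for classes expected to alter the protein product."""
    if cls not in _ALL_CLASSES:
        raise ValueError(f"unknown consequence class {cls!r}")
    return cls in PROTEIN_ALTERING_CLASSES


def protein_truncating(cls: str) -> bool:
    """True for classes expected to truncate the protein product."""
    if cls not in _ALL_CLASSES:
        raise ValueError(f"unknown consequence class {cls!r}")
    return cls in PROTEIN_TRUNCATING_CLASSES
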