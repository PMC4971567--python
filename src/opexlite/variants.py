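"""Variant-call post-processing: parsing, allele fractions, quality flags,
intergenic removal, type classification and the tab-separated clinical output.

The flagging rule follows the caller's per-sample quality model: a base
substitution is high quality when its QUAL score is at least 100; an
insertion, deletion or complex variant is high quality when the variant
allele fraction TR/TC is at least 0.2 *and* the FILTER field is exactly
"PASS".  Records with missing TR/TC/QUAL are flagged low, never dropped.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from cyvcf2 import VCF

from .transcripts import Transcript, TranscriptIndex

__all__ = [
    "VariantRecord",
    "FlaggedVariant",
    "parse_vcf",
    "variant_allele_fraction",
    "classify_variant_type",
    "assign_quality_flag",
    "remove_intergenic",
    "write_variant_tsv",
    "write_variant_vcf",
    "SHORT_INDEL_MAX",
    "DEFAULT_QUAL_HIGH",
    "DEFAULT_VAF_HIGH",
]

logger = logging.getLogger(__name__)

SHORT_INDEL_MAX = 10  # indels of <= 10 bp are "short"
DEFAULT_QUAL_HIGH = 100.0
DEFAULT_VAF_HIGH = 0.2


@dataclass
class VariantRecord:
    """One called variant (one ALT allele) with its caller quality fields."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: Optional[float] = None
    filter: str = "PASS"
    tr: Optional[int] = None  # reads supporting the variant
    tc: Optional[int] = None  # total reads at the site
    source_line: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"REF equals ALT ({self.ref}) at {self.chrom}:{self.pos}")
        if self.tr is not None and self.tc is not None and self.tr > self.tc:
            raise ValueError(
                f"TR {self.tr} exceeds TC {self.tc} at {self.chrom}:{self.pos}"
            )

    @property
    def vaf(self) -> Optional[float]:
        if self.tr is None or self.tc is None:
            return None
        return variant_allele_fraction(self.tr, self.tc)


@dataclass
class FlaggedVariant:
    """A classified variant with its quality flag and annotation context."""

    record: VariantRecord
    vtype: str  # substitution | insertion | deletion | complex
    indel_len: int
    length_class: str  # short | long | n/a
    flag: str = "low"  # high | low
    gene: str = "."
    transcript: str = "."
    consequence: str = "."
    csn_5prime: str = "."
    csn_3prime: str = "."
    extras: dict = field(default_factory=dict)


def parse_vcf(path: str) -> list[VariantRecord]:
    """Parse a VCF (plain or bgzipped) into one record per ALT allele.

    Multi-allelic rows are split positionally: the i-th TR value pairs with
    the i-th ALT allele; TC is shared.  TR/TC are looked up in INFO first,
    then in the first sample's FORMAT fields.  Missing TR/TC produce a
    warning and a record with those fields unset (flagged low downstream).
    """
    records: list[VariantRecord] = []
    vcf = VCF(path)
    try:
        for lineno, v in enumerate(vcf, start=1):
            alts = v.ALT or []
            tr_values = _per_allele_ints(v, "TR", len(alts))
            tc = _site_int(v, "TC")
            filt = v.FILTER or "PASS"  # cyvcf2 reports PASS as None
            for i, alt in enumerate(alts):
                tr = tr_values[i] if tr_values is not None else None
                if tr is None or tc is None:
                    warnings.warn(
                        f"{path} record {lineno} ({v.CHROM}:{v.POS}): missing TR/TC",
                        stacklevel=2,
                    )
                if tr is not None and tc is not None and tr > tc:
                    raise ValueError(
                        f"{path} record {lineno}: TR {tr} > TC {tc}"
                    )
                records.append(
                    VariantRecord(
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        qual=v.QUAL,
                        filter=filt,
                        tr=tr,
                        tc=tc,
                        source_line=lineno,
                    )
                )
    finally:
        vcf.close()
    return records


def _per_allele_ints(v, key: str, n_alts: int) -> Optional[list[Optional[int]]]:
    raw = v.INFO.get(key)
    if raw is None:
        fmt = _format_first_sample(v, key)
        if fmt is None:
            return None
        raw = fmt
    if isinstance(raw, (int, float)):
        values = [int(raw)]
    else:
        values = [int(x) for x in raw]
    if len(values) == 1 and n_alts > 1:
        values = values * n_alts
    if len(values) < n_alts:
        return None
    return values[:n_alts]


def _site_int(v, key: str) -> Optional[int]:
    raw = v.INFO.get(key)
    if raw is None:
        raw = _format_first_sample(v, key)
        if raw is None:
            return None
    if isinstance(raw, (tuple, list)):
        raw = raw[0]
    try:
        return int(raw)
    except (TypeError, ValueError):
        return None


def _format_first_sample(v, key: str):
    try:
        arr = v.format(key)
    except KeyError:
        return None
    if arr is None or len(arr) == 0:
        return None
    row = arr[0]
    try:
        return [int(x) for x in row]
    except (TypeError, ValueError):
        return None


def variant_allele_fraction(tr: int, tc: int) -> float:
    """TR/TC; returns 0.0 with a warning when TC is zero."""
    if tr < 0 or tc < 0:
        raise ValueError("TR and TC must be non-negative")
    if tr > tc:
        raise ValueError(f"TR {tr} exceeds TC {tc}")
    if tc == 0:
        warnings.warn("TC is zero; allele fraction reported as 0.0", stacklevel=2)
        return 0.0
    return tr / tc


def classify_variant_type(ref: str, alt: str) -> tuple[str, int, str]:
    """Classify the REF/ALT pair: (vtype, indel_len, length_class).

    Anchored length-changing alleles (REF a prefix of ALT, or vice versa)
    are insertions/deletions; everything else non-1:1 is complex.  An indel
    is short when its length is <= 10 bp.  Substitutions have
    length_class "n/a" and indel_len 0.
    """
    if not ref or not alt:
        raise ValueError("empty allele")
    if ref == alt:
        raise ValueError("REF equals ALT")
    if len(ref) == 1 and len(alt) == 1:
        return "substitution", 0, "n/a"
    if len(alt) > len(ref) and alt.startswith(ref):
        ln = len(alt) - len(ref)
        vtype = "insertion"
    elif len(ref) > len(alt) and ref.startswith(alt):
        ln = len(ref) - len(alt)
        vtype = "deletion"
    else:
        ln = abs(len(ref) - len(alt))
        if ln == 0:  # equal-length block substitution: class by its size
            ln = len(ref)
        vtype = "complex"
    return vtype, ln, ("short" if ln <= SHORT_INDEL_MAX else "long")


def assign_quality_flag(
    v: FlaggedVariant,
    qual_high: float = DEFAULT_QUAL_HIGH,
    vaf_high: float = DEFAULT_VAF_HIGH,
) -> str:
    """Assign "high"/"low" per the post-processing rule (inclusive bounds).

    Substitutions: high iff QUAL >= qual_high.  Indels and complex variants:
    high iff VAF >= vaf_high and FILTER is exactly "PASS".  Missing
    QUAL/TR/TC force "low".
    """
    r = v.record
    if v.vtype == "substitution":
        flag = "high" if (r.qual is not None and r.qual >= qual_high) else "low"
    else:
        vaf = r.vaf
        flag = (
            "high"
            if (vaf is not None and vaf >= vaf_high and r.filter == "PASS")
            else "low"
        )
    v.flag = flag
    return flag


def remove_intergenic(
    records: Sequence[VariantRecord],
    db: "Sequence[Transcript] | TranscriptIndex",
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition records into (kept, removed): kept records overlap at least
    one transcript span (introns included)."""
    index = db if isinstance(db, TranscriptIndex) else TranscriptIndex(db)
    kept, removed = [], []
    for r in records:
        if index.at(r.chrom, r.pos):
            kept.append(r)
        else:
            removed.append(r)
    return kept, removed


_TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "type",
    "indel_len",
    "length_class",
    "qual",
    "filter",
    "tr",
    "tc",
    "vaf",
    "flag",
    "gene",
    "transcript",
    "class",
    "csn_5prime",
    "csn_3prime",
]


def write_variant_tsv(records: Sequence[FlaggedVariant], path: str) -> None:
    """Write the clinical tab-separated variant table (fixed column order)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for fv in records:
            r = fv.record
            vaf = r.vaf
            w.writerow(
                [
                    r.chrom,
                    r.pos,
                    r.ref,
                    r.alt,
                    fv.vtype,
                    fv.indel_len,
                    fv.length_class,
                    "." if r.qual is None else f"{r.qual:g}",
                    r.filter,
                    "." if r.tr is None else r.tr,
                    "." if r.tc is None else r.tc,
                    "." if vaf is None else f"{vaf:.4f}",
                    fv.flag,
                    fv.gene,
                    fv.transcript,
                    fv.consequence,
                    fv.csn_5prime,
                    fv.csn_3prime,
                ]
            )


def write_variant_vcf(records: Sequence[FlaggedVariant], path: str) -> None:
    """Write records as a minimal VCF preserving the original fields and
    adding FLAG/VCLASS INFO tags for downstream annotation tools."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=TR,Number=A,Type=Integer,Description="Reads supporting variant">\n')
        fh.write('##INFO=<ID=TC,Number=1,Type=Integer,Description="Total reads at site">\n')
        fh.write('##INFO=<ID=FLAG,Number=1,Type=String,Description="high/low quality flag">\n')
        fh.write('##INFO=<ID=VCLASS,Number=1,Type=String,Description="Consequence class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for fv in records:
            r = fv.record
            info = []
            if r.tr is not None:
                info.append(f"TR={r.tr}")
            if r.tc is not None:
                info.append(f"TC={r.tc}")
            info.append(f"FLAG={fv.flag}")
            if fv.consequence != ".":
                info.append(f"VCLASS={fv.consequence}")
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.pos),
                        ".",
                        r.ref,
                        r.alt,
                        "." if r.qual is None else f"{r.qual:g}",
                        r.filter,
                        ";".join(info),
                    ]
                )
                + "\n"
            )
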