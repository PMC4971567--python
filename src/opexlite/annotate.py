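"""Glue between raw variant records and the annotated clinical table:
classify type, flag quality, attach gene/transcript context, consequence
class and both indel representations."""

from __future__ import annotations

from typing import Optional, Sequence

from .consequence import ReferenceMismatchError, assign_class, shift_indel
from .transcripts import Transcript, TranscriptIndex, genomic_to_csn, select_default_transcript
from .variants import (
    DEFAULT_QUAL_HIGH,
    DEFAULT_VAF_HIGH,
    FlaggedVariant,
    VariantRecord,
    assign_quality_flag,
    classify_variant_type,
)

__all__ = ["flag_and_annotate"]


def _context_transcript(index: TranscriptIndex, r: VariantRecord) -> Optional[Transcript]:
    """Pick the annotation transcript at the variant position: the default
    transcript of the first gene (by span), preferring CCDS."""
    hits = index.at(r.chrom, r.pos)
    if not hits:
        return None
    by_gene: dict[str, list[Transcript]] = {}
    for t in hits:
        by_gene.setdefault(t.gene_symbol, []).append(t)
    gene = min(by_gene)  # deterministic when several genes overlap
    return select_default_transcript(by_gene[gene])


def flag_and_annotate(
    records: Sequence[VariantRecord],
    db: "Sequence[Transcript] | TranscriptIndex",
    ref_genome=None,
    qual_high: float = DEFAULT_QUAL_HIGH,
    vaf_high: float = DEFAULT_VAF_HIGH,
) -> list[FlaggedVariant]:
    """Build FlaggedVariants: type/length class, high-low flag, and — when a
    reference genome is available — consequence class and 5'/3' indel
    representations on the context transcript."""
    index = db if isinstance(db, TranscriptIndex) else TranscriptIndex(db)
    out: list[FlaggedVariant] = []
    for r in records:
        vtype, ln, length_class = classify_variant_type(r.ref, r.alt)
        fv = FlaggedVariant(record=r, vtype=vtype, indel_len=ln, length_class=length_class)
        assign_quality_flag(fv, qual_high=qual_high, vaf_high=vaf_high)
        t = _context_transcript(index, r)
        if t is not None:
            fv.gene = t.gene_symbol
            fv.transcript = t.transcript_id
            if ref_genome is not None:
                try:
                    fv.consequence = assign_class(r, t, ref_genome)
                except (ReferenceMismatchError, ValueError):
                    fv.consequence = "."
                if vtype in ("insertion", "deletion") and ref_genome is not None:
                    try:
                        s = shift_indel(ref_genome, r)
                    except ReferenceMismatchError:
                        s = None
                    if s is not None:
                        fv.csn_5prime = _render_rep(t, s.pos_5prime, s.ref_5prime, s.alt_5prime)
                        fv.csn_3prime = _render_rep(t, s.pos_3prime, s.ref_3prime, s.alt_3prime)
            if vtype == "substitution":
                if t.contains(r.pos):
                    label = f"{genomic_to_csn(t, r.pos)}{r.ref}>{r.alt}"
                    fv.csn_5prime = fv.csn_3prime = label
        out.append(fv)
    return out


def _render_rep(t: Transcript, pos: int, ref: str, alt: str) -> str:
    """Render one anchored indel representation as pos:REF>ALT with the
    transcript-relative coordinate when the anchor lies inside the span."""
    if t.contains(pos):
        return f"{genomic_to_csn(t, pos)}:{ref}>{alt}"
    return f"g.{pos}:{ref}>{alt}"
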