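"""Transcript models, default-transcript selection and genomic<->CDS coordinate mapping.

A :class:`Transcript` stores its exon structure in 0-based half-open genomic
coordinates (the UCSC/BED dialect used by the tab-separated transcript
database), while every position accepted or returned by the public API is
1-based (the VCF dialect).  CDS coordinates follow HGVS-style ``c.`` notation:
coding bases are ``c.1 .. c.L`` in translation order, 5'UTR exonic bases are
``c.-N``, 3'UTR bases ``c.*N``, and intronic bases anchor to the nearest exon
boundary base with a signed offset (``c.N+k`` / ``c.N-k``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

__all__ = [
    "Transcript",
    "CsnPosition",
    "TranscriptValidationError",
    "TranscriptParseError",
    "load_transcript_db",
    "write_transcript_db",
    "filter_gene_candidates",
    "select_default_transcript",
    "genomic_to_csn",
    "region_to_csn_label",
    "overlapping_transcripts",
    "TranscriptIndex",
]

_STANDARD_CHROMS = frozenset(
    [str(i) for i in range(1, 23)]
    + ["X", "Y"]
    + [f"chr{i}" for i in range(1, 23)]
    + ["chrX", "chrY"]
)


class TranscriptValidationError(ValueError):
    """A transcript violates a structural invariant."""


class TranscriptParseError(ValueError):
    """A transcript database row could not be parsed."""


@dataclass
class Transcript:
    """One transcript: gene/ID, strand, exon structure and CDS bounds.

    ``exons`` are 0-based half-open genomic intervals, non-overlapping and
    sorted by start.  ``cds_start``/``cds_end`` are 0-based genomic offsets
    (end exclusive) that must fall within the exon span.
    """

    gene_symbol: str
    transcript_id: str
    is_ccds: bool
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    has_start_codon: bool = True
    has_stop_codon: bool = True
    is_pseudogene: bool = False

    # lazy caches, not part of equality
    _tx_pos: Optional[list[int]] = field(default=None, repr=False, compare=False)
    _pos_to_idx: Optional[dict[int, int]] = field(default=None, repr=False, compare=False)
    _coding_bounds: Optional[tuple[int, int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        tid = self.transcript_id
        if self.strand not in ("+", "-"):
            raise TranscriptValidationError(f"{tid}: strand must be '+' or '-'")
        if not self.exons:
            raise TranscriptValidationError(f"{tid}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise TranscriptValidationError(f"{tid}: exon end {e} <= start {s}")
            if prev_end is not None and s < prev_end:
                raise TranscriptValidationError(f"{tid}: exons overlap or unsorted")
            prev_end = e
        if not (self.cds_start < self.cds_end):
            raise TranscriptValidationError(f"{tid}: cds_start >= cds_end")
        span_start, span_end = self.exons[0][0], self.exons[-1][1]
        if not (span_start <= self.cds_start and self.cds_end <= span_end):
            raise TranscriptValidationError(f"{tid}: CDS outside exon span")
        if self.coding_length() < 1:
            raise TranscriptValidationError(f"{tid}: empty coding region")

    # -- geometry -----------------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (1-based inclusive), introns included."""
        return self.exons[0][0] + 1, self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        """True if 1-based genomic ``pos`` lies within the transcript span."""
        lo, hi = self.span
        return lo <= pos <= hi

    def coding_length(self) -> int:
        return sum(
            max(0, min(e, self.cds_end) - max(s, self.cds_start)) for s, e in self.exons
        )

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def transcript_order_positions(self) -> list[int]:
        """All exonic 1-based genomic positions in 5'->3' transcript order."""
        if self._tx_pos is None:
            if self.strand == "+":
                pos = [p for s, e in self.exons for p in range(s + 1, e + 1)]
            else:
                pos = [p for s, e in reversed(self.exons) for p in range(e, s, -1)]
            self._tx_pos = pos
            self._pos_to_idx = {p: i for i, p in enumerate(pos)}
        return self._tx_pos

    def _index_of(self, pos: int) -> Optional[int]:
        self.transcript_order_positions()
        assert self._pos_to_idx is not None
        return self._pos_to_idx.get(pos)

    def is_coding_genomic(self, pos: int) -> bool:
        """Whether the exonic 1-based position lies in [cds_start, cds_end)."""
        return self.cds_start <= pos - 1 < self.cds_end

    def coding_positions(self) -> list[int]:
        """Genomic 1-based positions of c.1..c.L in translation order."""
        return [p for p in self.transcript_order_positions() if self.is_coding_genomic(p)]

    def exon_index(self, pos: int) -> Optional[int]:
        """Genomic-order index of the exon containing 1-based ``pos``, else None."""
        for k, (s, e) in enumerate(self.exons):
            if s < pos <= e:
                return k
        return None

    def is_internal_exon_edge(self, pos: int, width: int = 3) -> bool:
        """True if ``pos`` sits within the first/last ``width`` bases of an
        internal (non-terminal) exon."""
        k = self.exon_index(pos)
        if k is None or k == 0 or k == len(self.exons) - 1:
            return False
        s, e = self.exons[k]
        return pos <= s + width or pos > e - width


@dataclass(frozen=True)
class CsnPosition:
    """A transcript-relative (c.) coordinate.

    ``anchor_kind`` identifies the exonic anchor base (coding, utr5 or utr3);
    ``kind`` is ``intronic`` when ``intron_offset`` is non-zero, otherwise it
    equals ``anchor_kind``.  ``coding_index`` is the positive magnitude N of
    c.N / c.-N / c.*N.
    """

    kind: str
    coding_index: int
    intron_offset: int = 0
    anchor_kind: str = "coding"

    def __post_init__(self) -> None:
        if (self.intron_offset != 0) != (self.kind == "intronic"):
            raise ValueError("intron_offset must be non-zero iff kind is intronic")
        if self.coding_index < 1:
            raise ValueError("coding_index must be >= 1")

    def __str__(self) -> str:
        if self.anchor_kind == "utr5":
            base = f"-{self.coding_index}"
        elif self.anchor_kind == "utr3":
            base = f"*{self.coding_index}"
        else:
            base = str(self.coding_index)
        off = f"{self.intron_offset:+d}" if self.intron_offset else ""
        return f"c.{base}{off}"


def genomic_to_csn(t: Transcript, pos: int) -> CsnPosition:
    """Map a 1-based genomic position inside the transcript span to a c. coordinate.

    Coding exonic bases map to c.1..c.L in translation order; 5'UTR exonic
    bases to c.-N counting away from c.1; 3'UTR to c.*N.  Intronic bases
    anchor to the donor exon base (c.N+k) when in the 5' half of the intron
    (transcript orientation; exact midpoint anchors to the donor), otherwise
    to the acceptor exon base (c.N-k).
    """
    lo, hi = t.span
    if not (lo <= pos <= hi):
        raise ValueError(f"position {pos} outside transcript span [{lo},{hi}]")
    idx = t._index_of(pos)
    if idx is not None:
        return _exonic_csn(t, idx)
    # intronic: find flanking exons in genomic order
    left_end = right_start = None
    for s, e in t.exons:
        if e < pos:
            left_end = e  # last exonic 1-based base of upstream (genomic) exon
        if s >= pos and right_start is None:
            right_start = s + 1  # first exonic base of downstream (genomic) exon
    assert left_end is not None and right_start is not None
    if t.strand == "+":
        donor_base, acceptor_base = left_end, right_start
        d_donor, d_acceptor = pos - left_end, right_start - pos
    else:
        donor_base, acceptor_base = right_start, left_end
        d_donor, d_acceptor = right_start - pos, pos - left_end
    if d_donor <= d_acceptor:
        anchor = _exonic_csn(t, t._index_of(donor_base))  # type: ignore[arg-type]
        offset = d_donor
    else:
        anchor = _exonic_csn(t, t._index_of(acceptor_base))  # type: ignore[arg-type]
        offset = -d_acceptor
    return CsnPosition(
        kind="intronic",
        coding_index=anchor.coding_index,
        intron_offset=offset,
        anchor_kind=anchor.anchor_kind,
    )


def _exonic_csn(t: Transcript, idx: int) -> CsnPosition:
    if t._coding_bounds is None:
        tx = t.transcript_order_positions()
        coding_idx = [i for i, p in enumerate(tx) if t.is_coding_genomic(p)]
        t._coding_bounds = (coding_idx[0], coding_idx[-1])
    i0, i1 = t._coding_bounds
    if idx < i0:
        return CsnPosition(kind="utr5", coding_index=i0 - idx, anchor_kind="utr5")
    if idx > i1:
        return CsnPosition(kind="utr3", coding_index=idx - i1, anchor_kind="utr3")
    return CsnPosition(kind="coding", coding_index=idx - i0 + 1, anchor_kind="coding")


def region_to_csn_label(t: Transcript, start: int, end: int) -> str:
    """Label a 1-based inclusive genomic interval as ``GENE:c.X-c.Y``.

    Endpoints are the strand-ordered first/last base of the interval clipped
    to the transcript span.
    """
    lo, hi = t.span
    cstart, cend = max(start, lo), min(end, hi)
    if cstart > cend:
        raise ValueError(
            f"interval [{start},{end}] does not overlap {t.transcript_id} span [{lo},{hi}]"
        )
    first, last = (cstart, cend) if t.strand == "+" else (cend, cstart)
    return f"{t.gene_symbol}:{genomic_to_csn(t, first)}-{genomic_to_csn(t, last)}"


# -- database I/O -----------------------------------------------------------

_DB_COLUMNS = [
    "GENE",
    "TRANSCRIPT",
    "CCDS",
    "CHROM",
    "STRAND",
    "EXON_STARTS",
    "EXON_ENDS",
    "CDS_START",
    "CDS_END",
]
_OPT_COLUMNS = ["START_CODON", "STOP_CODON", "PSEUDOGENE"]


def _parse_bool(token: str) -> bool:
    return token.strip().lower() in ("1", "true", "yes", "y")


def load_transcript_db(path: str) -> list[Transcript]:
    """Load the tab-separated transcript database, preserving row order.

    Required columns: GENE, TRANSCRIPT, CCDS, CHROM, STRAND, EXON_STARTS,
    EXON_ENDS, CDS_START, CDS_END (comma-separated exon lists, 0-based
    half-open).  Optional columns START_CODON, STOP_CODON, PSEUDOGENE default
    to true/true/false.
    """
    out: list[Transcript] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise TranscriptParseError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in _DB_COLUMNS if c not in header]
        if missing:
            raise TranscriptParseError(f"{path}: missing columns {missing}")
        col = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(_DB_COLUMNS):
                raise TranscriptParseError(f"{path}:{lineno}: expected >= {len(_DB_COLUMNS)} fields")
            try:
                starts = [int(x) for x in fields[col["EXON_STARTS"]].rstrip(",").split(",")]
                ends = [int(x) for x in fields[col["EXON_ENDS"]].rstrip(",").split(",")]
                if len(starts) != len(ends):
                    raise ValueError("EXON_STARTS and EXON_ENDS lengths differ")
                kwargs = dict(
                    gene_symbol=fields[col["GENE"]],
                    transcript_id=fields[col["TRANSCRIPT"]],
                    is_ccds=_parse_bool(fields[col["CCDS"]]),
                    chrom=fields[col["CHROM"]],
                    strand=fields[col["STRAND"]],
                    exons=list(zip(starts, ends)),
                    cds_start=int(fields[col["CDS_START"]]),
                    cds_end=int(fields[col["CDS_END"]]),
                )
                for name, attr in zip(_OPT_COLUMNS, ("has_start_codon", "has_stop_codon", "is_pseudogene")):
                    if name in col and len(fields) > col[name]:
                        kwargs[attr] = _parse_bool(fields[col[name]])
            except TranscriptValidationError:
                raise
            except (ValueError, IndexError) as exc:
                raise TranscriptParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(Transcript(**kwargs))
    return out


def write_transcript_db(transcripts: Iterable[Transcript], path: str) -> None:
    """Write transcripts in the tab-separated database format read back by
    :func:`load_transcript_db`."""
    with open(path, "w") as fh:
        fh.write("\t".join(_DB_COLUMNS + _OPT_COLUMNS) + "\n")
        for t in transcripts:
            fh.write(
                "\t".join(
                    [
                        t.gene_symbol,
                        t.transcript_id,
                        "1" if t.is_ccds else "0",
                        t.chrom,
                        t.strand,
                        ",".join(str(s) for s, _ in t.exons),
                        ",".join(str(e) for _, e in t.exons),
                        str(t.cds_start),
                        str(t.cds_end),
                        "1" if t.has_start_codon else "0",
                        "1" if t.has_stop_codon else "0",
                        "1" if t.is_pseudogene else "0",
                    ]
                )
                + "\n"
            )


# -- default transcript selection -------------------------------------------


def filter_gene_candidates(
    records: Sequence[Transcript],
) -> tuple[list[Transcript], list[tuple[Transcript, str]]]:
    """Split transcripts into default-set candidates and excluded records.

    A candidate must lie on chromosomes 1-22/X/Y, have both a start and a
    stop codon, and not be a known pseudogene.  Each excluded record carries
    a machine-readable reason: ``chromosome``, ``incomplete_cds`` or
    ``pseudogene``.
    """
    included: list[Transcript] = []
    excluded: list[tuple[Transcript, str]] = []
    for t in records:
        if t.chrom not in _STANDARD_CHROMS:
            excluded.append((t, "chromosome"))
        elif not (t.has_start_codon and t.has_stop_codon):
            excluded.append((t, "incomplete_cds"))
        elif t.is_pseudogene:
            excluded.append((t, "pseudogene"))
        else:
            included.append(t)
    return included, excluded


def select_default_transcript(candidates: Sequence[Transcript]) -> Transcript:
    """Choose the default transcript for one gene.

    CCDS transcripts are preferred; remaining ties break by longest coding
    length, then longest total exonic length, then lexicographically smallest
    transcript ID, giving a deterministic total order.
    """
    if not candidates:
        raise ValueError("select_default_transcript requires a non-empty candidate list")
    genes = {t.gene_symbol for t in candidates}
    if len(genes) > 1:
        raise ValueError(f"candidates span multiple genes: {sorted(genes)}")
    return min(
        candidates,
        key=lambda t: (
            not t.is_ccds,
            -t.coding_length(),
            -t.exonic_length(),
            t.transcript_id,
        ),
    )


# -- overlap queries ---------------------------------------------------------


class TranscriptIndex:
    """Interval-tree index over transcript spans (introns included)."""

    def __init__(self, db: Sequence[Transcript]):
        self._trees: dict[str, IntervalTree] = {}
        for t in db:
            lo, hi = t.span
            self._trees.setdefault(t.chrom, IntervalTree()).addi(lo, hi + 1, t)

    def at(self, chrom: str, pos: int) -> list[Transcript]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        hits.sort(key=lambda t: (t.span, t.transcript_id))
        return hits

    def overlapping(self, chrom: str, start: int, end: int) -> list[Transcript]:
        """Transcripts whose span overlaps the 1-based inclusive interval."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        hits.sort(key=lambda t: (t.span, t.transcript_id))
        return hits


def overlapping_transcripts(db: Sequence[Transcript], chrom: str, pos: int) -> list[Transcript]:
    """All transcripts whose genomic span (introns included) contains the
    1-based position."""
    return [t for t in db if t.chrom == chrom and t.contains(pos)]
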