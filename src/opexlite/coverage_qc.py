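"""Per-base coverage/quality metrics over BED targets, pass/fail evaluation,
and transcript-coordinate annotation of failing subregions.

Metrics per base of a target region:

COV    read depth: aligned, non-duplicate primary reads whose alignment spans
       the base (match or deletion blocks).
QCOV   the subset of COV with mapping quality >= ``mq_good``.
MEDBQ  median base quality of read bases aligned to the position.
FLBQ   fraction of those bases with base quality < ``bq_low``.
MEDMQ  median mapping quality of covering reads.
FLMQ   fraction of covering reads with mapping quality < ``mq_good``.

A region passes when every base has QCOV >= ``qcov_threshold`` (default 15x
at mapping quality >= 20, the good-quality coverage definition used for
clinical fill-in decisions).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .transcripts import Transcript, TranscriptIndex, region_to_csn_label

__all__ = [
    "BedRegion",
    "RegionProfile",
    "RegionSummary",
    "read_bed",
    "pileup_profile",
    "failed_subregions",
    "annotate_failed_regions",
    "region_summary",
    "write_coverage_report",
]

DEFAULT_MQ_GOOD = 20
DEFAULT_BQ_LOW = 10
DEFAULT_QCOV_THRESHOLD = 15


@dataclass(frozen=True)
class BedRegion:
    """A BED target: 0-based half-open genomic interval with optional name."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty BED region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


def read_bed(path: str) -> list[BedRegion]:
    """Read a standard 3+ column BED file (0-based half-open)."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            name = fields[3] if len(fields) > 3 else "."
            regions.append(BedRegion(fields[0], int(fields[1]), int(fields[2]), name))
    return regions


@dataclass
class RegionProfile:
    """Per-base metric arrays over one BED region.

    Array index i corresponds to genomic 1-based position region.start+1+i.
    MEDBQ/MEDMQ/FLBQ/FLMQ are NaN where undefined (no covering reads /
    no aligned base).
    """

    region: BedRegion
    cov: np.ndarray
    qcov: np.ndarray
    medbq: np.ndarray
    flbq: np.ndarray
    medmq: np.ndarray
    flmq: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.region)
        for arr in (self.cov, self.qcov, self.medbq, self.flbq, self.medmq, self.flmq):
            if len(arr) != n:
                raise ValueError("profile arrays must match region length")
        if np.any(self.qcov > self.cov):
            raise ValueError("QCOV exceeds COV")

    def positions(self) -> np.ndarray:
        """Genomic 1-based positions of the array entries."""
        return np.arange(self.region.start + 1, self.region.end + 1)


def _read_reference_spans(read: pysam.AlignedSegment):
    """Yield (ref_pos0, base_quality or None) for every reference base the
    alignment spans; quality is None inside deletions."""
    ref = read.reference_start
    q = 0
    quals = read.query_qualities
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            for k in range(length):
                yield ref + k, (quals[q + k] if quals is not None else None)
            ref += length
            q += length
        elif op == 2 or op == 3:  # D, N: consume reference only
            for k in range(length):
                yield ref + k, None
            ref += length
        elif op in (1, 4):  # I, S: consume query only
            q += length
        # H, P consume neither


def pileup_profile(
    alignments: "pysam.AlignmentFile | str",
    region: BedRegion,
    mq_good: int = DEFAULT_MQ_GOOD,
    bq_low: int = DEFAULT_BQ_LOW,
) -> RegionProfile:
    """Compute the per-base metric arrays for one region from an indexed BAM.

    Duplicate, secondary, supplementary and unmapped reads are excluded from
    every metric.  A read contributes depth at a base when its alignment
    spans the base (match or deletion); deleted bases carry no base quality
    but still count toward COV/QCOV and the mapping-quality metrics.
    """
    close = False
    if isinstance(alignments, str):
        alignments = pysam.AlignmentFile(alignments, "rb")
        close = True
    try:
        if region.chrom not in alignments.references:
            raise ValueError(f"contig {region.chrom!r} not present in alignment file")
        n = len(region)
        cov = np.zeros(n, dtype=np.int64)
        qcov = np.zeros(n, dtype=np.int64)
        mqs: list[list[int]] = [[] for _ in range(n)]
        bqs: list[list[int]] = [[] for _ in range(n)]
        for read in alignments.fetch(region.chrom, region.start, region.end):
            if (
                read.is_unmapped
                or read.is_duplicate
                or read.is_secondary
                or read.is_supplementary
            ):
                continue
            mq = read.mapping_quality
            for ref0, bq in _read_reference_spans(read):
                i = ref0 - region.start
                if 0 <= i < n:
                    cov[i] += 1
                    if mq >= mq_good:
                        qcov[i] += 1
                    mqs[i].append(mq)
                    if bq is not None:
                        bqs[i].append(bq)
        medbq = np.full(n, np.nan)
        flbq = np.full(n, np.nan)
        medmq = np.full(n, np.nan)
        flmq = np.full(n, np.nan)
        for i in range(n):
            if mqs[i]:
                m = np.asarray(mqs[i])
                medmq[i] = np.median(m)
                flmq[i] = np.mean(m < mq_good)
            if bqs[i]:
                b = np.asarray(bqs[i])
                medbq[i] = np.median(b)
                flbq[i] = np.mean(b < bq_low)
        return RegionProfile(region, cov, qcov, medbq, flbq, medmq, flmq)
    finally:
        if close:
            alignments.close()


def failed_subregions(
    profile: RegionProfile, qcov_threshold: int = DEFAULT_QCOV_THRESHOLD
) -> list[tuple[str, int, int]]:
    """Maximal runs of bases with QCOV < threshold, as sorted disjoint
    (chrom, start, end) intervals, 1-based inclusive."""
    below = profile.qcov < qcov_threshold
    out: list[tuple[str, int, int]] = []
    start1 = profile.region.start + 1
    run_start: Optional[int] = None
    for i, bad in enumerate(below):
        if bad and run_start is None:
            run_start = i
        elif not bad and run_start is not None:
            out.append((profile.region.chrom, start1 + run_start, start1 + i - 1))
            run_start = None
    if run_start is not None:
        out.append((profile.region.chrom, start1 + run_start, start1 + len(below) - 1))
    return out


def annotate_failed_regions(
    fails: Sequence[tuple[str, int, int]],
    db: "Sequence[Transcript] | TranscriptIndex",
) -> list[tuple[tuple[str, int, int], str]]:
    """Label each failing interval with ``GENE:c.X-c.Y`` against every
    overlapping transcript (comma-joined), or "." when none overlaps."""
    index = db if isinstance(db, TranscriptIndex) else TranscriptIndex(db)
    out = []
    for chrom, start, end in fails:
        hits = index.overlapping(chrom, start, end)
        if hits:
            label = ",".join(region_to_csn_label(t, start, end) for t in hits)
        else:
            label = "."
        out.append(((chrom, start, end), label))
    return out


@dataclass
class RegionSummary:
    """Summary statistics and pass/fail verdict for one target region."""

    region: BedRegion
    min_qcov: int
    median_qcov: float
    max_flmq: float
    max_flbq: float
    pass_flag: bool
    failed: list[tuple[tuple[str, int, int], str]] = field(default_factory=list)


def region_summary(
    profile: RegionProfile,
    qcov_threshold: int = DEFAULT_QCOV_THRESHOLD,
    db: "Sequence[Transcript] | TranscriptIndex | None" = None,
) -> RegionSummary:
    """Summarise a profile: the region passes iff min QCOV >= threshold.

    When a transcript database/index is supplied, failing subregions are
    annotated with their transcript-coordinate labels.
    """
    fails = failed_subregions(profile, qcov_threshold)
    if db is not None:
        annotated = annotate_failed_regions(fails, db)
    else:
        annotated = [(iv, ".") for iv in fails]
    flmq = profile.flmq[~np.isnan(profile.flmq)]
    flbq = profile.flbq[~np.isnan(profile.flbq)]
    return RegionSummary(
        region=profile.region,
        min_qcov=int(profile.qcov.min()),
        median_qcov=float(np.median(profile.qcov)),
        max_flmq=float(flmq.max()) if len(flmq) else float("nan"),
        max_flbq=float(flbq.max()) if len(flbq) else float("nan"),
        pass_flag=not fails,
        failed=annotated,
    )


_REGION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "min_qcov",
    "median_qcov",
    "max_flmq",
    "max_flbq",
    "status",
]
_FAILED_COLUMNS = ["chrom", "start", "end", "region_name", "csn_label"]
_PROFILE_COLUMNS = ["chrom", "pos", "COV", "QCOV", "MEDBQ", "FLBQ", "MEDMQ", "FLMQ"]


def _fmt(x: float) -> str:
    return "." if isinstance(x, float) and np.isnan(x) else f"{x:.4g}"


def write_coverage_report(
    summaries: Sequence[RegionSummary],
    out_prefix: str,
    profiles: Optional[Sequence[RegionProfile]] = None,
) -> dict[str, str]:
    """Write ``<prefix>_regions.tsv`` and ``<prefix>_failed.tsv`` (and
    optionally ``<prefix>_profiles.tsv``); returns the paths written."""
    paths = {
        "regions": f"{out_prefix}_regions.tsv",
        "failed": f"{out_prefix}_failed.tsv",
    }
    with open(paths["regions"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_REGION_COLUMNS)
        for s in summaries:
            w.writerow(
                [
                    s.region.chrom,
                    s.region.start,
                    s.region.end,
                    s.region.name,
                    s.min_qcov,
                    _fmt(s.median_qcov),
                    _fmt(s.max_flmq),
                    _fmt(s.max_flbq),
                    "PASS" if s.pass_flag else "FAIL",
                ]
            )
    with open(paths["failed"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_FAILED_COLUMNS)
        for s in summaries:
            for (chrom, start, end), label in s.failed:
                w.writerow([chrom, start, end, s.region.name, label])
    if profiles is not None:
        paths["profiles"] = f"{out_prefix}_profiles.tsv"
        with open(paths["profiles"], "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(_PROFILE_COLUMNS)
            for p in profiles:
                for i, pos in enumerate(p.positions()):
                    w.writerow(
                        [
                            p.region.chrom,
                            pos,
                            int(p.cov[i]),
                            int(p.qcov[i]),
                            _fmt(p.medbq[i]),
                            _fmt(p.flbq[i]),
                            _fmt(p.medmq[i]),
                            _fmt(p.flmq[i]),
                        ]
                    )
    return paths
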