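"""Single-command orchestration: coverage QC + variant post-processing with
shared thresholds, structured logging and a JSON run manifest.

The pipeline starts from a coordinate-sorted BAM and a called VCF (alignment,
duplicate marking and variant calling are upstream concerns) and produces the
coverage reports, the clinical variant table and a manifest recording every
parameter and output checksum, so a run can be reproduced and verified.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import pyfaidx
import yaml

from . import __version__
from .annotate import flag_and_annotate
from .coverage_qc import (
    DEFAULT_BQ_LOW,
    DEFAULT_MQ_GOOD,
    DEFAULT_QCOV_THRESHOLD,
    pileup_profile,
    read_bed,
    region_summary,
    write_coverage_report,
)
from .transcripts import TranscriptIndex, load_transcript_db
from .variants import (
    DEFAULT_QUAL_HIGH,
    DEFAULT_VAF_HIGH,
    parse_vcf,
    remove_intergenic,
    write_variant_tsv,
    write_variant_vcf,
)

__all__ = ["RunConfig", "run"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated inputs and thresholds for one pipeline run."""

    bam: str
    vcf: str
    bed: str
    transcripts: str
    reference: Optional[str] = None
    out_prefix: str = "opexlite"
    qual_high: float = DEFAULT_QUAL_HIGH
    vaf_high: float = DEFAULT_VAF_HIGH
    qcov_threshold: int = DEFAULT_QCOV_THRESHOLD
    mq_good: int = DEFAULT_MQ_GOOD
    bq_low: int = DEFAULT_BQ_LOW
    write_profiles: bool = False
    write_vcf: bool = False
    mode: str = "single"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        for label in ("bam", "vcf", "bed", "transcripts"):
            p = getattr(self, label)
            if not os.path.exists(p):
                raise FileNotFoundError(f"{label} input not found: {p}")
        if self.reference is not None and not os.path.exists(self.reference):
            raise FileNotFoundError(f"reference input not found: {self.reference}")
        for label in ("qual_high", "vaf_high", "qcov_threshold", "mq_good", "bq_low"):
            if getattr(self, label) < 0:
                raise ValueError(f"threshold {label} must be >= 0")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute coverage QC and variant post-processing with one threshold
    set; returns the manifest dict (also written to ``<prefix>_manifest.json``).

    On a stage failure, partial outputs are removed and the exception is
    re-raised so a wrapper can exit non-zero.
    """
    config.validate()
    out_dir = os.path.dirname(os.path.abspath(config.out_prefix))
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    try:
        db = load_transcript_db(config.transcripts)
        index = TranscriptIndex(db)
        ref = pyfaidx.Fasta(config.reference) if config.reference else None

        logger.info("coverage QC over %s", config.bed)
        regions = read_bed(config.bed)
        profiles = [
            pileup_profile(config.bam, r, mq_good=config.mq_good, bq_low=config.bq_low)
            for r in regions
        ]
        summaries = [
            region_summary(p, qcov_threshold=config.qcov_threshold, db=index)
            for p in profiles
        ]
        cov_paths = write_coverage_report(
            summaries,
            config.out_prefix,
            profiles=profiles if config.write_profiles else None,
        )
        written.extend(cov_paths.values())

        logger.info("variant post-processing of %s", config.vcf)
        records = parse_vcf(config.vcf)
        kept, removed = remove_intergenic(records, index)
        flagged = flag_and_annotate(
            kept, index, ref, qual_high=config.qual_high, vaf_high=config.vaf_high
        )
        variants_path = f"{config.out_prefix}_variants.tsv"
        write_variant_tsv(flagged, variants_path)
        written.append(variants_path)
        if config.write_vcf:
            vcf_out = f"{config.out_prefix}_variants.vcf"
            write_variant_vcf(flagged, vcf_out)
            written.append(vcf_out)

        manifest = {
            "tool": "opexlite",
            "version": __version__,
            "parameters": asdict(config),
            "n_regions": len(regions),
            "n_regions_failed": sum(not s.pass_flag for s in summaries),
            "n_variants_input": len(records),
            "n_variants_intergenic_removed": len(removed),
            "n_variants_kept": len(kept),
            "n_variants_high": sum(fv.flag == "high" for fv in flagged),
            "outputs": {os.path.basename(p): _sha256(p) for p in written},
        }
        manifest_path = f"{config.out_prefix}_manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["manifest_path"] = manifest_path
        return manifest
    except Exception:
        logger.exception("pipeline stage failed; removing partial outputs")
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise
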