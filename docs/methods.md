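# Methods

This document describes the model implemented by `opexlite`: the data it
consumes, the quantities it computes, every tunable parameter with its
default and rationale, what the synthetic fixtures do and do not emulate,
the numerical and design choices made, and the known limitations.

## 1. Inputs and coordinate conventions

The pipeline entry point (`opexlite run`, `opexlite.pipeline.run`) starts
from the outputs of an upstream alignment-and-calling stack:

| Input | Format | Produced by (upstream) |
|---|---|---|
| `--bam` | coordinate-sorted, indexed BAM | aligner + duplicate marker |
| `--vcf` | VCF with `TR` (variant reads) and `TC` (total reads) INFO fields | variant caller |
| `--bed` | BED of target regions | capture design |
| `--transcripts` | tab-separated transcript database (see §2) | annotation source |
| `--ref` | indexed FASTA (optional; needed for consequence classes and indel representations) | genome build |

**Coordinates.** Internally everything is stored 0-based half-open (the
BED/UCSC convention): exons, CDS bounds, BED regions, per-base arrays.
Every *public API position argument and every reported position* is 1-based
(the VCF convention). Each function's docstring states which side of the
boundary it is on; conversions happen exactly once, at the API surface.

## 2. Transcript model and c. coordinates (`opexlite.transcripts`)

A `Transcript` is a gene symbol, transcript ID, CCDS membership flag,
chromosome, strand, an ordered exon list and CDS bounds. `validate()`
enforces sorted non-overlapping exons and CDS bounds inside the exon span.

**Default transcript per gene.** When several transcripts of one gene
overlap a position, `select_default_transcript` picks by, in order: CCDS
member first, then longest coding sequence, then longest exonic span, then
lexicographically smallest transcript ID. The last key exists purely to
make the choice deterministic.

**Genomic → c. map.** `genomic_to_csn` labels every base of the transcript
span:

- Coding bases are `c.1 … c.L` in transcript orientation (L = coding
  length). The map is bijective on the span: the test suite enumerates all
  spanned bases of random transcripts on both strands and checks label
  uniqueness and that the coding labels are exactly `1..L`.
- 5′ UTR bases count backwards from the start codon as `c.-1, c.-2, …`
  (there is no `c.0`); 3′ UTR bases count forwards from the stop as
  `c.*1, c.*2, …`.
- Intronic bases anchor to the nearest exonic coordinate: `c.N+k` from the
  donor (the exon edge 5′ of the intron in transcript orientation) and
  `c.N-k` from the acceptor. A base equidistant from both edges anchors to
  the donor. Anchors may themselves be UTR coordinates (e.g. `c.-12+3`).

`region_to_csn_label(t, start, end)` renders an interval by mapping its two
endpoints, producing labels like `GENE1:c.130-c.178+5`; the coverage module
uses it to describe failing subregions.

`TranscriptIndex` wraps an interval tree for O(log n) point and range
queries over a transcript database.

## 3. Coverage quality control (`opexlite.coverage_qc`)

For each BED region, `pileup_profile` computes per-base vectors from the
BAM:

| Metric | Definition |
|---|---|
| COV | reads whose alignment consumes the reference at the base (CIGAR M/=/X and D) |
| QCOV | same, restricted to mapping quality ≥ `mq_good` |
| MEDBQ | median base quality of aligned (non-deletion) bases |
| FLBQ | fraction of aligned bases with base quality < `bq_low` |
| MEDMQ | median mapping quality of covering reads |
| FLMQ | fraction of covering reads with mapping quality < `mq_good` |

Duplicate, secondary and supplementary alignments are excluded everywhere.
Reads deleted at a base (CIGAR D) still count toward COV/QCOV/MEDMQ/FLMQ —
the read does span the locus — but contribute no base quality, so
MEDBQ/FLBQ denominators can be smaller than COV. Bases with no coverage
report NaN for the median/fraction metrics.

**Pass/fail.** A region passes iff QCOV ≥ `qcov_threshold` at *every* base.
`failed_subregions` extracts the maximal runs of failing bases (an exact
run-length encoding; verified against an independent RLE oracle), and
`annotate_failed_regions` labels each run with the default transcript's
c. coordinates, or `.` when no transcript overlaps.

Parameters and defaults:

- `qcov_threshold = 15` — the clinical adequacy bound: below ~15 good-quality
  reads, a heterozygous variant has appreciable probability of being missed.
- `mq_good = 20` — MQ 20 ≈ 1% misplacement probability; reads below it are
  both excluded from QCOV and counted by FLMQ, so the two metrics partition
  coverage consistently.
- `bq_low = 10` — BQ 10 ≈ 10% base error; FLBQ flags loci where miscalls
  could imitate variants.

## 4. Variant flagging (`opexlite.variants`)

`parse_vcf` (cyvcf2) splits multi-allelic records positionally — the i-th
`TR` value follows the i-th ALT — and preserves the original record index.
A missing FILTER is read as `PASS` (the VCF meaning of `.` from callers
that only write failures).

**Typing.** `classify_variant_type(ref, alt)`:

- equal length 1 → substitution;
- ALT extends REF → insertion of `len(alt) − len(ref)` bp;
- REF extends ALT → deletion;
- anything else → complex, with indel length `|len(ref) − len(alt)|`
  (equal-length complex events use their full length).

Indels and complex events are `short` iff their length ≤ 10 bp. Longer
indels exceed what short-read gapped alignment detects reliably, so the
boundary doubles as a confidence covariate.

**Flag rule.** Each call is flagged `high` or `low`:

- substitutions: high iff QUAL ≥ 100 (inclusive);
- insertions, deletions and complex events: high iff VAF = TR/TC ≥ 0.2
  (inclusive) **and** FILTER is exactly the string `PASS`.

Missing QUAL, TR or TC flags low (conservative: absent evidence is not
treated as good evidence), and `parse_vcf` warns. QUAL is deliberately not
consulted for indels — caller QUAL is poorly calibrated for gapped events,
where allele fraction plus the caller's own filters discriminate better.
Applying the indel rule to complex events is an extension: they are
length-changing-style events with the same QUAL-calibration problem.

Calls outside every transcript span are removed (`remove_intergenic`)
before reporting; the pipeline counts them in the manifest.

## 5. Consequence classes and indel representations (`opexlite.consequence`)

**Representations.** An indel adjacent to a repeat has many equivalent
VCF spellings. `shift_indel` computes the 5′-most and 3′-most anchored
representations by repeat-walking (for a deletion, step the anchor left
while the base at the anchor equals the base one deleted-length further
right; insertions rotate the inserted allele correspondingly). The defining
invariant — checked for 500 random indels per run — is that both
representations edit the reference to byte-identical sequences, with the 5′
anchor ≤ the 3′ anchor. Both spellings are reported (`csn_5prime`,
`csn_3prime`), because variant databases disagree on normalization and a
clinician must be able to match either.

**Classes.** One class per variant, assigned from the 5′ representation,
choosing the most severe zone it touches:

| Class | Meaning | Zone |
|---|---|---|
| ESS | essential splice site | first/last 8 bp of an intron |
| FS | frameshift | coding indel with length not divisible by 3 |
| SG | stop gain | substitution creating a stop codon |
| IF | in-frame indel | coding indel, length divisible by 3 |
| NSY | non-synonymous | amino-acid-changing substitution |
| EE | exon-end | substitution in the outer 3 bp of an internal exon end |
| SS | splice-region | intron positions 9–10 beyond the ESS window |
| SY | synonymous | amino-acid-preserving substitution |
| UTR | untranslated | exonic, outside the CDS |
| INT | deep intronic | intron, beyond the SS window |

The severity order for tie-breaking is the table order (ESS most severe).
Codon effects are computed by translating the reference and alternate
codons (Biopython), reverse-complementing on minus-strand transcripts. The
EE/ESS/SS window widths are a deliberate simplification of full splice-model
annotation: fixed windows rather than motif scoring. `protein_altering`
(NSY, EE, IF, ESS, SG, FS) and `truncating` (ESS, SG, FS) are the derived
category predicates used by the trio report.

## 6. Trio de novo analysis (`opexlite.trio`)

A proband call is a candidate de novo variant iff all of:

1. **Absent from both parents** under representation-invariant matching:
   variants are compared by their 5′-normalized key, so a right-aligned
   spelling in a parent VCF still suppresses the left-aligned proband call.
2. **High confidence** under the §4 flag rule.
3. **Proband depth** TC ≥ 15.
4. **Parental coverage**: each parent's BAM shows ≥ 15 reads with MQ ≥ 20
   at the site (the 5′-anchored position for indels, when a reference is
   available). This is the crucial guard: a parent cannot demonstrate
   absence of an allele at a locus they are not covered on, so an uncovered
   parental site must veto the call rather than support it.

Candidates are partitioned into protein-altering / truncating / other using
the §5 predicates. The thresholds reuse the coverage-QC constants (15,
MQ 20) so "adequately covered" means the same thing in both analyses.

## 7. Synthetic fixtures (`opexlite.fixtures`)

All test and acceptance data are generated, never shipped. A `FixtureSpec`
(seed, contig lengths, optional planted homopolymers, optional `TrioSpec`)
drives:

- `make_reference` — random FASTA (indexed) with planted repeat stretches so
  indel shifting is exercised;
- `simulate_alignments` — paired reads tiled over target regions at a given
  depth, with configurable fractions of low-MQ reads, low-BQ reads and
  duplicate/secondary records, written as a sorted indexed BAM *and*
  returned as a truth table of `ReadTruth` rows;
- `spike_variants` — `VariantTruth` records (constructed via `for_flag` to
  carry an intended high/low flag) validated against the reference and
  written as a sorted VCF;
- `make_trio` — three member VCFs (inherited variants shared, de novo
  confined to the proband, selectable members writing indels right-aligned)
  plus parental BAMs over the de novo sites.

Everything derives from `numpy.random.default_rng(seed)`; the same spec
yields byte-identical outputs.

**What the fixtures emulate:** depth structure, MQ/BQ mixtures, duplicates,
repeat-adjacent indels, multi-member representation disagreement, shallow
parental coverage. **What they do not emulate:** sequencing error in read
bases (reads match the reference, so variant evidence lives only in the
VCF's TR/TC), indel-containing alignments (CIGARs are pure matches), GC
bias, mate-pair insert-size structure, or caller behaviour itself. Each
read carries a single base quality so truth-table recounts are exact
rather than distributional — the fixtures are built for verifying the
post-processing arithmetic, not for benchmarking a caller.

## 8. Numerical and design choices

- **Oracles over examples.** The acceptance tests compare against
  independent recomputations: a per-base recount of the read truth table
  (pileup), run-length encoding (failed regions), exhaustive enumeration
  (flag rule, coordinate map), and brute-force edit application (indel
  representations). `scripts/acceptance.py` recomputes the same quantities
  standalone.
- **Determinism.** All randomness is seeded; pipeline reruns are
  byte-identical (checked by test and acceptance script); the manifest
  stores SHA-256 checksums of every output.
- **Inclusive thresholds.** All boundaries (QUAL ≥ 100, VAF ≥ 0.2,
  QCOV ≥ 15, 10-bp short indels) are inclusive and tested at value−ε,
  value, value+ε.
- **Median convention.** MEDBQ/MEDMQ use the standard midpoint median
  (`numpy.median`), so half-integer values occur at even depth.
- **NaN, not 0,** for fraction/median metrics at uncovered bases: zero
  would be a legitimate measured value and must remain distinguishable
  from "no data".
- **Established libraries** handle formats and numerics (pysam, cyvcf2,
  pyfaidx, intervaltree, Biopython, numpy/pandas); the package implements
  by hand only the primitives that are its actual subject — the coordinate
  map, the repeat-walk shifting, the flag rule, the pileup definitions.
- **Failure hygiene.** The pipeline validates all inputs before computing
  and deletes partial outputs if any stage fails, so an output prefix never
  holds a mixture of old and new files.

## 9. Limitations

- Consequence calling is codon-local: no protein-level HGVS, no multi-codon
  effects of in-frame indels, no stop-loss class, no motif-based splice
  scoring beyond the fixed windows.
- Splice-window classes are assigned to indels by zone overlap, not by
  re-aligning the edited sequence.
- Trio analysis assumes one VCF per member and does not model genotype
  likelihoods; it is a candidate screen, not a statistical de novo caller.
- The pileup does not recompute base alignment around indels (no local
  realignment); metrics reflect the alignments as given.
- Multi-sample VCFs are read per-record INFO only; per-sample FORMAT fields
  are not consulted.
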