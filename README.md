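# opexlite

Post-processing for clinical exome sequencing: per-base coverage quality
control, variant call flagging and annotation in transcript (c.) coordinates,
and candidate de novo variant detection in proband–parent trios.

Upstream of this package sit an aligner, a duplicate marker and a variant
caller; `opexlite` starts from their outputs — a coordinate-sorted BAM, a VCF
with `TR`/`TC` allele counts, a BED file of targets and a transcript database
— and produces the tables a clinical analyst reads:

- **Coverage QC** (`opexlite.coverage_qc`): per-base COV, QCOV (depth of
  reads with mapping quality ≥ 20), MEDBQ, FLBQ, MEDMQ and FLMQ across each
  target; a region passes only if QCOV ≥ 15 at every base. Failing
  subregions are reported with transcript-coordinate labels such as
  `GENE1:c.130-c.178` so a clinician can see which part of the coding
  sequence is inadequately covered.
- **Variant flagging** (`opexlite.variants`): each call is typed
  (substitution / insertion / deletion / complex, short ≤ 10 bp vs long) and
  flagged `high` or `low` confidence. Substitutions are high iff QUAL ≥ 100;
  indels are high iff the variant allele fraction TR/TC ≥ 0.2 **and** the
  caller's FILTER is `PASS`. Calls outside every transcript are removed.
- **Consequence classes** (`opexlite.consequence`): a simplified functional
  vocabulary (SY, NSY, SG, FS, IF, ESS, EE, SS, INT, UTR) assigned from the
  5′-most variant representation; indels near repeats get both their 5′ and
  3′ representations, which provably apply the same edit to the reference.
- **Transcript model** (`opexlite.transcripts`): exon/CDS geometry on either
  strand, CCDS-aware default-transcript selection, and an exact, bijective
  map between genomic positions and HGVS-style c. coordinates including UTR
  (`c.-12`, `c.*45`) and intronic (`c.130+2`, `c.131-8`) labels.
- **Trio analysis** (`opexlite.trio`): candidate de novo variants — present
  in the proband, absent from both parents under representation-invariant
  matching, high confidence, proband depth ≥ 15 and both parents covered by
  ≥ 15 good-quality reads at the site — partitioned into protein-altering /
  truncating / other.
- **Synthetic fixtures** (`opexlite.fixtures`): a deterministic generator
  for references, alignments, variant calls and whole trios with truth
  tables, used by the test suite and the acceptance script.
- **Pipeline** (`opexlite.pipeline` / the `opexlite` CLI): one command from
  BAM + VCF to all reports, plus a JSON manifest with parameters and output
  checksums.

## Worked example

The package can generate its own demonstration data (no external downloads).
The snippet below builds a 20-kb reference with two genes, ~50× alignments
over two coding targets plus one shallow off-target region, and four spiked
variant calls:

```python
from opexlite.fixtures import (FixtureSpec, RegionSpec, VariantTruth,
                               make_reference, simulate_alignments,
                               spike_variants, write_bed)
from opexlite.transcripts import Transcript, write_transcript_db

spec = FixtureSpec(seed=7, contigs={"chr1": 20_000})
ref_path, seqs = make_reference(spec, "demo")
seq = seqs["chr1"]
genes = [
    Transcript("GENE1", "TX_A", True, "chr1", "+",
               [(1000, 1200), (1400, 1600), (1800, 2000)], 1050, 1900),
    Transcript("GENE2", "TX_B", False, "chr1", "-",
               [(5000, 5300), (5600, 5900)], 5100, 5800),
]
write_transcript_db(genes, "demo/transcripts.tsv")
regions = [RegionSpec("chr1", 1000, 1200, depth=50, frac_low_mq=0.1),
           RegionSpec("chr1", 1400, 1600, depth=50),
           RegionSpec("chr1", 15_000, 15_200, depth=5)]
write_bed([r.to_bed_region(f"r{i}") for i, r in enumerate(regions)],
          "demo/targets.bed")
simulate_alignments(7, seqs, regions, "demo/sample.bam")

def sub(pos, flag):
    b = seq[pos - 1]
    return VariantTruth.for_flag("chr1", pos, b, "A" if b != "A" else "G", flag)

spike_variants([sub(1100, "high"), sub(1450, "low"),
                VariantTruth.for_flag("chr1", 1500, seq[1499:1502], seq[1499], "high"),
                sub(15_050, "high")],          # intergenic; removed downstream
               seqs, "demo/sample.vcf")
```

Then run the whole pipeline with one command:

```console
$ cd demo
$ opexlite run --bam sample.bam --vcf sample.vcf --bed targets.bed \
      --transcripts transcripts.tsv --ref ref.fa --out-prefix out/run
INFO opexlite.pipeline: coverage QC over targets.bed
INFO opexlite.pipeline: variant post-processing of sample.vcf
run complete; manifest at out/run_manifest.json
```

The coverage report shows the two 50× coding targets passing and the 5×
region failing, with the failing run of bases listed separately:

```console
$ cat out/run_regions.tsv
chrom	start	end	name	min_qcov	median_qcov	max_flmq	max_flbq	status
chr1	1000	1200	r0	36	44.5	0.1778	0	PASS
chr1	1400	1600	r1	35	47	0	0	PASS
chr1	15000	15200	r2	4	5.5	0	0	FAIL

$ cat out/run_failed.tsv
chrom	start	end	region_name	csn_label
chr1	15001	15200	r2	.
```

(`csn_label` is `.` here because the failing region lies outside every
transcript; a failing coding region would read e.g. `GENE1:c.1-c.48`.)

The variant table carries the type, flag, consequence class and both indel
representations in c. coordinates; the intergenic call at 15,050 was removed:

```console
$ cut -f1-5,8,13-18 out/run_variants.tsv
chrom	pos	ref	alt	type	qual	flag	gene	transcript	class	csn_5prime	csn_3prime
chr1	1100	A	G	substitution	150	high	GENE1	TX_A	NSY	c.50A>G	c.50A>G
chr1	1450	A	G	substitution	50	low	GENE1	TX_A	NSY	c.200A>G	c.200A>G
chr1	1500	ACC	A	deletion	150	high	GENE1	TX_A	FS	c.250:ACC>A	c.250:ACC>A
```

The manifest (`out/run_manifest.json`) records every parameter, the headline
counts (`"n_regions_failed": 1`, `"n_variants_high": 2`,
`"n_variants_intergenic_removed": 1`) and a SHA-256 checksum of each output,
so a rerun can be verified byte-for-byte.

Each stage is also available separately (`opexlite coverage`,
`opexlite variants`, `opexlite trio`) and as plain Python functions; see
`docs/methods.md` for the full model and parameter reference.

## Layout

```
src/opexlite/      package modules
tests/             pytest suite (tests/test_acceptance.py holds the
                   end-to-end property checks)
scripts/acceptance.py   standalone metrics recomputation
docs/methods.md    model, parameters, numerical choices and limitations
```
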