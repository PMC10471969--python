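# Methods

## Problem and approach

HLA genes are too polymorphic for reads to be aligned reliably to a single
universal reference, and their transcript isoforms differ between alleles of
the same locus in the same person. `hlasplice` quantifies allele-specific
exon utilization and full-length transcript isoforms from long-read cDNA by:

1. building a **donor-specific genomic reference** from the donor's known
   HLA type — each typed allele is resolved to the database allele with the
   lowest four-field name consistent with the type, and its genomic sequence
   (exons + introns) becomes one reference contig;
2. extracting **reference-coordinate aligned blocks** per read from spliced
   alignments (intron skips appear as N CIGAR operations);
3. calling, per read and per annotated exon, **RETAINED / EXCLUDED /
   UNASSESSED**, and aggregating to per-allele exon retention rates;
4. counting **exon-presence patterns** of full-span reads as transcript
   isoforms;
5. computing coverage diagnostics (breadth at depth, gene-body profile,
   3'/5' depth ratio) and replicate concordance.

## Exon status model

For a read with aligned blocks B and an allele with ordered exons E₁…Eₙ:

- **RETAINED(k)** — some block overlaps Eₖ by ≥ 1 base. A single base
  suffices: any aligned overlap is direct evidence the exon is present in
  the transcript.
- **EXCLUDED(k)** — no block overlaps Eₖ, and retained exons exist both at
  some index < k and some index > k. The read demonstrably extends past the
  exon on both sides, so its absence is splicing.
- **UNASSESSED(k)** — otherwise. The read is truncated relative to Eₖ and
  carries no splicing information for it.

The flanking requirement is the load-bearing choice: oligo(dT)-primed
nanopore cDNA loses 5' sequence constantly, and without it every truncated
read would be miscounted as exon loss. Terminal exons can never be EXCLUDED
under this rule.

**Retention rate** for exon k of an allele = retained / (retained +
excluded). UNASSESSED reads are omitted from the denominator by default
because they carry no information about the exon; otherwise 3'-biased
truncation would masquerade as 5'-exon loss. A sensitivity mode
(`denominator="all"`, CLI `--denominator all`) divides by all reads
assigned to the allele instead.

**Read thresholds.** An allele enters analysis only with ≥ 20 reads
(class I: HLA-A/B/C) or ≥ 10 reads (class II), counted over all reads
assigned to the allele, not per-exon assessable reads. Below-threshold
alleles keep their table rows with `passes_threshold = False`.

## Allele resolution

Typed alleles (often two-field, e.g. `DQB1*05:03`) are resolved to the
database allele whose name has the typed name as a field-prefix and is
minimal under field-wise numeric ordering (field 1, then 2, 3, 4).
Expression suffixes (N/Q/L/S/A/C) are ignored for consistency matching; a
name without a suffix wins a full-field tie, then suffixes compare by
character. The study's alleles are expressed, so this tie-break exists only
to make resolution deterministic. Homozygous genotypes collapse to a single
reference allele so reads are not split arbitrarily between two identical
sequences.

## Isoform quantification

Full-span reads are those whose first and last exon are RETAINED — the
"spanning all known exons" criterion is terminal-exon overlap, not
retention of every exon, since only truncation (not splicing) disqualifies
a read. Each full-span read contributes one bit pattern; counts are
normalized per allele. Patterns with weak support (fewer than `min_reads`
reads in every sample and fewer than `min_samples` samples) can be flagged
rare; the default is annotation, not removal, with an optional hard filter
that renormalizes.

By construction, the pattern-weighted inclusion of exon k over the isoform
table equals the retention rate computed from the same full-span read
subset exactly; this identity is asserted in the tests.

## Coverage diagnostics

- **Breadth at depth**: fraction of *all* reference positions (introns
  included, since the reference is genomic) with depth ≥ X, at X ∈
  {10, 25, 50, 75, 100} by default, with a 90%-breadth pass flag per
  allele.
- **Gene-body profile**: each allele's depth vector is averaged within 100
  equal-width position bins and scaled to its own maximum (so alleles with
  different expression levels are comparable), then the per-bin median and
  inner-50%/inner-90% bands are taken across alleles. Max-scaling before
  aggregation is a package choice; the bin count and scaling are exposed as
  parameters.
- **3' bias ratio**: mean depth over the 3'-most 20% of positions divided
  by the 5'-most 20%; 1.0 for flat coverage, > 1 under 5' truncation,
  undefined (NaN) when the 5' tail has zero depth.

## Replicate concordance

Usage tables from two replicates of the same donor are inner-joined on
(allele, exon); rows where either replicate fails the read threshold or has
an undefined rate are dropped. Each row is a Bland-Altman point: mean read
count versus rate difference. Aggregates (mean absolute difference,
fraction of rows within tolerance) are reported per locus class at
tolerances 0.02 and 0.04 by default. Whether to aggregate per (allele,
exon) point or per allele was open; per (allele, exon) was chosen as the
finer-grained option.

## Synthetic data

The simulator is first-class, tested code; its defaults encode the study
conditions rather than convenient values.

- **Toy database**: seeded random sequences laid out as alternating
  exons/introns. The DQB1-like default layout has six exons of
  100/270/282/111/24/200 nt — exon 5 is 24 nt, matching the biologically
  interesting tiny exon — with introns 500/400/300/200/100 nt. Same-locus
  alleles sharing a layout differ at 20 substituted positions, emulating
  near-identical HLA allele pairs.
- **Isoform mixtures**: each read draws a pattern from its allele's
  categorical mixture. The reference condition is 72% all-exons / 28%
  skip-exon-5 for the intact-acceptor allele and 100% skip for the
  lost-acceptor allele.
- **5' truncation**: with probability `truncation_rate` a read keeps only
  its 3'-most L exonic bases, L ~ Geometric(p) with mean 1/p (default
  800 nt, a realistic cDNA fragment scale). Geometric-from-the-3'-end
  captures oligo(dT) priming plus in-sequencing truncation and produces
  the characteristic 3' coverage bias.
- **Contamination**: with probability `contamination_rate` a read is
  emitted under the label and coordinates of the other same-locus allele
  (requires equal exon counts), emulating misalignment between
  near-identical alleles.
- Reads are emitted as a perfect, coordinate-sorted SAM (blocks = retained
  exon intervals, N across introns and skipped exons) *and* as FASTQ with
  substitution errors at `per_base_error`. The SAM path tests all
  downstream logic with no aligner in the loop; the FASTQ path feeds the
  optional minimap2 wrapper. A truth TSV records each read's true allele,
  pattern, truncation point, and contamination flag. Identical configs
  (including seed) produce byte-identical outputs.

What the simulator does **not** emulate: realistic nanopore error profiles
(homopolymer errors, quality calibration), novel/unannotated exons, intron
retention, alternative polyadenylation, or expression differences driven by
RNA degradation. Passing tests therefore demonstrate the correctness of the
interval logic, the statistics, and the robustness properties (truncation
is never called splicing; contamination produces the expected low-level
false retention) — not performance on raw nanopore data, which additionally
depends on basecalling, trimming, and aligner behavior.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internally and in BED
  outputs.
- Retention rate 0/0 is undefined (NaN), never 0 or 1; undefined rows are
  excluded from medians and concordance.
- Deletions (D) of any length stay within an aligned block; only N splits
  blocks, matching spliced-aligner conventions. Zero-length skips merge.
- Supplementary and secondary alignments are dropped so one molecule
  contributes one pattern; no MAPQ filter by default (configurable).
- Isoform rows are ordered (allele, count desc, pattern lexicographic);
  TSVs use fixed column order and 6-decimal fixed-point fractions so
  reruns are byte-identical.
- Empty inputs: empty callset collections yield structurally complete
  tables with zero counts; an empty reference bundle is rejected.

## Problem sizes

Tests and the acceptance script use 500–1000 reads per allele on the
two-allele DQB1-like locus, with statistical assertions placed at exact
binomial 99% intervals for the simulated depth. These sizes give stable
estimates (binomial SE ≈ 1.4% at n = 1000) while keeping the whole suite
in seconds.

## Known limitations

- Alleles with incomplete genomic reference sequences are out of scope; the
  database dialect requires a full genomic sequence per allele.
- The rs28688207 genotype is supplied as an input map derived from allele
  identity, not inferred from read sequence.
- Candidate selection in the two-pass wrapper is "any primary alignment to
  a CDS"; no score threshold is applied.
- No novel-exon or cryptic-splice-site discovery; patterns are defined over
  annotated exons only.
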