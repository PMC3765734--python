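# Methods

## Tag chemistry in silico

The pipeline models NlaIII/MmeI tag profiling. NlaIII cleaves cDNA at every
CATG; because the cDNA is synthesized on oligo-dT beads, the fragment that
remains bead-bound after digestion is the 3′-most one, so the sequenced tag
comes from the **3′-most CATG site** of each transcript. MmeI then cuts
17 bp downstream of the anchor, so a tag is 17 nt (reported without the
CATG; the anchored 21-mer is kept for provenance). Extraction therefore
returns, in `canonical` mode, the 3′-most CATG with at least 17 clean nt
downstream; `all_sites` mode returns every qualifying site because
truncated cDNAs can expose internal sites. A site whose 17 nt window
contains an N contributes no tag, mirroring the read-side N filter. Only
the sense strand is scanned (oligo-dT priming is strand-specific). The
anchor is a parameter, so a DpnII-style library can be indexed with
`anchor="GATC"`; only the CATG chemistry is exercised by the test suite.
Coordinates are 0-based sense-strand offsets.

## Cleaning rules and their order

Clean tags are raw tags surviving three filters, applied in a fixed order
so per-rule removal counts are reproducible: (1) any non-ACGT character
(N calls); (2) equality with — or being a prefix of — a configured adaptor
sequence (the adaptor is kit-specific and never published with the
libraries, so it is configuration, defaulting to a 21 nt Illumina DGE
adaptor-2 sequence); (3) copy number below `min_copy` (default 2; low-copy
tags are dominated by single-position sequencing errors). Filtering is
idempotent and never alters a surviving tag's count.

Singleton statistics are reported from the **pre-filter** distribution:
the ">50 % singletons" property that tag libraries show refers to distinct
raw tags of count 1, which the copy-number filter removes by construction.
Reporting both quantities separately resolves what would otherwise look
like a contradiction between "clean tags exclude copies < 2" and "half the
tags are singletons".

Reads are expected to begin with the anchor (adaptor-1 trimming leaves
CATG at the read start); reads that do not are counted as discarded, with a
`scan_anchor` escape hatch that searches for an internal anchor instead.

## Mapping

Assignment is exact-tier-first Hamming-≤1 matching: a tag with an exact
hit never consults its neighbors; otherwise all 51 single-substitution
variants are looked up in the exact-tag hash and the transcript hits
pooled. One transcript ⇒ `one_mismatch` (the mismatch position is
recorded); two or more at the winning tier ⇒ `ambiguous`; none ⇒
`unmapped`. Ambiguous tags did land on the reference, so by default they
count toward the library's mapped-uni-tag statistic but are excluded from
per-transcript expression counts; `distribute` (equal split) and `drop`
policies are available. The neighborhood lookup is verified against an
exhaustive quadratic Hamming scan in the test suite.

## Quantification and differential expression

A gene's count in a library is the summed clean count of its unambiguous
tags. TPM is `1e6 · x/N`; when `N` is not supplied it defaults to the
count-matrix column sum (in the pipeline it is the library's clean-tag
total, so TPM is per million clean tags, not per million mapped tags).
RPKM (`1e9 · x/(N·L)`) is provided for fidelity to the tag-profiling
literature but is documented as length-inappropriate here: each transcript
contributes at most one canonical tag site, so tag yield does not scale
with length. TPM is the default output.

With one library per condition and no replicates, dispersion cannot be
estimated; the standard choice for tag counts is the exact conditional
test of the Audic–Claverie tradition. Conditional on the pooled count
n = x + y, under equal expression y ~ Binomial(n, N₂/(N₁+N₂)). The
two-sided p-value doubles the smaller exact tail, capped at 1 — this
conditional form is exactly symmetric in the two libraries, and its upper
tail coincides term-for-term with the negative-binomial predictive form of
the original derivation. Tails are evaluated with scipy's regularized
incomplete-beta machinery and checked against exact rational summation to
1e-9 relative; the discrete test is conservative under the null (measured
rejection ≈ 0.036–0.040 at α = 0.05).

DE calls require both BH-FDR ≤ α (default 0.05; FDR computed across genes
with ≥ 1 count in the pair) and |log₂ FC| ≥ 1, with fold change on TPM
plus pseudocount 1 so unequal depths compare fairly. The S/D pattern rule
formalizes "similar vs different expression pattern": a gene is D iff at
least one developmental stage's between-species comparison yields a
direction other than unchanged. With the default thresholds this rule
reproduces the published S/D label of all 20 packaged exemplar rows.

The published summary table ships as a fixture
(`src/dgetag/data/table1.tsv`). Two arithmetic quirks of the printed
table are documented rather than reproduced: the first species' printed
gene total (88 857) is one below its own stage sum (88 858; the second
species' total matches its sum exactly), and one ratio cell (second
species, larva: 60 287/88 171 = 68.3751 %) prints as 68.37 although exact
half-up rounding gives 68.38 — no single rounding rule reproduces all ten
printed ratio cells, and this package rounds half-up, which matches the
other nine bit-for-bit. The printed "mapping gene ratio" row has an
unprinted denominator (the reference transcript count); the summary
reports `genes_hit / reference_size` against the user's own reference.

## Synthetic data generator

The generator emulates: a transcript reference (uniform random sequence at
configurable GC, default 0.42) in which a `taggable_fraction` (default
0.95) of transcripts is guaranteed a CATG site with ≥ 17 nt downstream
(inserted at a random admissible position when absent); heavy-tailed
per-transcript abundance, log-normal with σ = 1.2 (a realistic spread for
mRNA abundance — two orders of magnitude between the 5th and 95th
percentile — and heavy enough to reproduce the > 50 % singleton fraction
of real libraries at test depths); a multiplicative log-normal stage
effect (σ = 0.25) **shared between species**, so that within a stage the
injected fold changes are the only between-species signal; and a
`de_fraction` (default 10 %) of genes with ±`de_log2fc` (default 2)
between-species fold change, constant across stages.

Fold-change signs are assigned greedily so that the species' total
transcript output is approximately conserved. This matters because library
weights are renormalized to proportions: with unbalanced signs a single
high-abundance gene drawn up or down would shift every null gene's
expected proportion by a common factor, making the nominally-null genes
genuinely differentially expressed in proportion terms. Greedy balancing
keeps each injected |log₂ FC| exact while making that compositional shift
negligible.

Each library holds exactly `depth_per_library` reads: a binomial number of
adaptor-contaminated reads (default fraction 0.01, simulated as
CATG + the adaptor's first 17 nt — the product of adaptor ligation at the
NlaIII sticky end), the rest multinomial over transcript proportions. A
read is its transcript's canonical tag with i.i.d. per-base errors on the
17 nt payload: N-call probability `n_rate` (default 0.001), substitution
probability `substitution_rate` (default 0.002); the anchor is left
intact, since anchor errors would surface as discarded-no-anchor reads
rather than tag errors, and the per-read N fraction then follows the
closed form 1 − (1 − n_rate)¹⁷ asserted in the tests. Reads are emitted
as 21 nt (anchor + tag) by default, or padded with adaptor-2 bases to
35 nt in FASTQ mode (constant Q30 qualities) to exercise extraction.

Randomness: one `numpy` Generator per library, seeded by the master seed
plus CRC32 hashes of the species/stage names, so outputs are
byte-identical for a given configuration regardless of generation order.
Defaults are the study-shaped conditions scaled down — 500 transcripts,
2 species × 4 stages, depth 10⁵ (the sequenced libraries run to ~6 × 10⁶
clean tags; depth is a single parameter) — and the acceptance script and
tests use these defaults as-is.

What the generator does **not** model: PCR amplification bias, MmeI star
activity, position-specific Illumina error profiles, indels, partial
transcripts/isoforms, or biological replication (the emulated design
pools many individuals into one library per stage, as tag studies did).
Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and inference under a clean generative model, not robustness
to those real-data artifacts.

## Numerical and degenerate-input choices

- Ratio cells are exact `decimal` arithmetic, rounded half-up, so results
  do not depend on binary floating point.
- `ac_test` caps at p = 1 and returns 1 for the 0-vs-0 split.
- Venn partitions report all 2ᵏ − 1 regions (zeros included); region
  labels are '&'-joined sorted library ids, so output is
  permutation-invariant.
- Empty inputs (empty read stream, empty reference, empty tag map) yield
  empty outputs with zeroed statistics, never errors; a reference with no
  taggable transcript is a hard simulation error.
- A missing stage in the summary produces a warning and totals over the
  present stages.
- Pipeline reruns with identical config and inputs write byte-identical
  outputs; the manifest records SHA-256 checksums of all inputs and
  outputs and, on failure, the failing stage name.

## Problem sizes

The test suite and acceptance script run the simulator at 500 transcripts
and depth 10⁵ per library (8 libraries), the mapping oracle comparison on
100 random instances up to 300 reference × 200 query tags, the extraction
oracle on 1 000 random transcripts, and the null-calibration check on
10 000 simulated count pairs — sizes chosen so the full suite completes in
well under a minute while leaving every statistical assertion comfortably
powered.

## Known limitations

- Ambiguous-tag handling and the unpublished adaptor sequence are policy
  choices, configurable but not recoverable from the published tables.
- The S/D rule is a formalization; the published labels were assigned
  without printed thresholds, so agreement on the packaged exemplars is
  evidence of consistency, not a guarantee for other genes.
- RPKM values are reported only for comparability; see above.
- Cross-species tag comparison matches identical 17-mers only; diverged
  orthologous tags are out of scope without an annotation mapping.
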