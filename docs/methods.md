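# Methods

This note records the models, rules and numerical choices behind each
module, what the synthetic generators do and do not emulate, and the design
decisions taken where the underlying procedure left room.

## Diploid genome and read model

`simulate.simulate_diploid_genome` draws a uniform-composition sequence and
a second haplotype differing only by SNVs: each position is heterozygous
with probability `het_rate` and the alternate allele is uniform over the
three non-reference bases. Divergence is SNV-only by design — no indels —
so both haplotypes share coordinates and the k-mer and variant ground truth
is exact. This matches what the downstream analyses measure (spectrum
bimodality, SNV density); it deliberately does not model indel
heterozygosity or structural variation.

Reads are drawn uniformly from both haplotypes and both strands.
`reads_for_kmer_coverage` sizes the read set so the *total k-mer count*
(both haplotypes pooled) equals the requested k-mer depth times the
haplotype length; for 100-bp reads, k-mer depth and base depth differ by
the factor (100 − k + 1)/100. Sequencing error, when enabled, is a uniform
per-base substitution with no quality-by-cycle structure, GC bias or PCR
duplicates; passing tests therefore demonstrate correctness of the
decision rules under idealised noise, not robustness to real instrument
artefacts.

## Planted QC violations and label soundness

`simulate.simulate_reads` plants at most one violation class per pair
(drawn with the configured rates, hence disjoint labels):

- **N**: just over `max_n_fraction` of the read rewritten to N.
- **poly-A**: a terminal A-run long enough that the whole-read A fraction
  reaches the QC cutoff (~82 of 100 bases at the 0.80 default). A shorter
  tail could never trip an A-fraction rule, so planting is tied to the
  configured detector threshold.
- **low quality**: ≥ `lowq_max_count` bases rewritten below the Phred
  threshold (base quality is otherwise Q35 ± 2 jitter, Phred+33).
- **adapter**: the read suffix replaced by a 20-base adapter prefix.
- **overlap**: the pair drawn from a 1.5-read-length fragment so the mates
  genuinely read into each other.

Two guarantees make the planted label set *exactly* the droppable set.
First, every planted pair is verified to trip its own rule first (in the
a→e rule order). Second, clean pairs are rejection-sampled until they trip
no rule: a fixed ~30-bp adapter aligns ≥ 11 bases with ≤ 3 mismatches
against a uniform random 100-bp read at a rate of a few per thousand, so
without rejection "drop set equals planted set" would be statistically
false at any useful sample size. The non-circular content of the
planted-label tests is the detection of the planted reads and the per-rule
attribution; the cleanliness guarantee only removes background
coincidences the rule would correctly (but unlabelled-ly) fire on.
Because 100-bp mates from a 180-bp fragment always overlap by 20 bp,
clean pairs are drawn only from insert sizes ≥ 2·read_length +
overlap_min; with the default 180/500/800 insert list that means the two
longer libraries.

## QC rules

Rules and defaults (all configurable): N fraction strictly > 0.05 fails;
A fraction ≥ 0.80 fails (the "poly-A structure" definition); ≥ 20 bases at
Phred ≤ 7 fails; an ungapped adapter alignment with ≥ 11 aligned positions
and ≤ 3 mismatches fails — implemented as a sliding window of exactly 11
bases over every adapter/read diagonal, which is equivalent to scanning
all alignment lengths ≥ 11 because any longer qualifying alignment
contains a qualifying 11-window; mate overlap ≥ 10 bases at mismatch
fraction ≤ 0.10 fails (reverse complement of mate 2 slid over mate 1,
boundary 1/10 counts as a failure). A pair is dropped whole when either
mate fails any rule — mate files stay synchronised — and the report
attributes the drop to the first rule that fired. N bases count as
mismatches everywhere.

## K-mer spectrum

Counting is exact: each k-window without N contributes the lexicographic
minimum of itself and its reverse complement, 2-bit packed into an int64
(k ≤ 31, k odd to exclude reverse-complement palindromes), tallied with
vectorised sort/unique passes in ~4M-window batches. The spectrum is
smoothed with a centred moving average of window 3 (edge bins averaged
over existing neighbours); the window-3 average also breaks the
Poisson(λ = integer) tie between adjacent modes deterministically in
expectation, though at λ just above an integer the smoothed mode remains a
near-tie and individual runs can land one bin low (e.g. 31 for a 32×
simulation) — a one-bin, ~3% jitter inherent to the sampling, not to the
estimator.

The error trough is the smallest multiplicity ≥ 2 that is a local minimum
of the smoothed spectrum, or 1 when the spectrum rises from the start
(error-free input). Peaks are local maxima above the trough; maxima below
5% of the tallest are discarded as sampling noise (without this floor, a
haploid spectrum's low-multiplicity noise would masquerade as a second
peak), and the top two by height are kept. Across k ∈ {15, 17, 19, 21}
the two candidates are matched by position (± 20%) and the one whose
height has the smaller coefficient of variation across k is the coverage
peak; a het/coverage ratio outside [0.4, 0.6] triggers a warning. Genome
size divides the total k-mer count at or above the trough by the
coverage-peak depth; excluding sub-trough k-mers avoids error-k-mer
inflation on real reads and is a no-op on error-free simulations.

## Assembly and repeat summaries

Contigs are maximal scaffold substrings not interrupted by ≥ 25
consecutive Ns (the captured-gap convention; configurable). N50 is the
largest L such that scaffolds ≥ L sum to at least half the total. The
scaffolded/unscaffolded partition is computed over contig bases, so the
two percentages always sum to 100. Repeat summaries take masked intervals
(0-based half-open, BED in/out) and report per-family union lengths; a
base masked by two families counts once in the overall masked total but
once per family in the breakdown, whose per-class percentages therefore
partition the summed class total.

## Contamination screen

"Accumulated length of matched regions" is read as the *union* (merged
intervals), not the sum — overlapping matches should not double-count.
The candidate rule is strict (> 10%); confirmation requires the best
protein hit (lowest e-value, ties by highest bit-score) to be bacterial at
e ≤ 1e-6, and a surviving tie between bacterial and non-bacterial best
hits resolves conservatively to "not confirmed". The upstream classifiers
(k-mer taxonomy, protein search) are consumed as tabular input, not
re-implemented: the decision rule is the subject here.

## Mitochondrial pipeline

Alignment filtering applies the e-value and identity gates per record and
the ≥ 90% aligned-fraction gate per *contig* (accumulated union of its
query intervals — the per-contig reading of "contig alignment coverage").
Tiling is a greedy left-to-right chain: among records starting at or
before the current end plus `max_gap` (default 0, i.e. contiguous),
select the one extending furthest right; records contained in the tiled
span are skipped, holes are recorded as gaps and the chain restarts.
Records shorter than 100 bp on the reference are ignored, mirroring the
minimum-cluster convention of standard whole-genome aligners.

The minimal mapper seeds with exact 21-mers at staggered offsets on the
doubled reference (the circularity trick; every reported coordinate is
reduced modulo the length), extends ungapped, scores by mismatch count,
and reports a read as unmapped on a best-score tie between distinct
placements or when no seed hits. It stands in for an external mapper at
desk scale — SAM from a real mapper is equally accepted via
`placements_from_sam`.

SNV calling uses an explicit pileup rule: depth ≥ 10 and the most frequent
non-reference allele at count ≥ 4 and fraction ≥ 0.2. (Production callers
bury their thresholds in version-specific defaults; an explicit rule is
reproducible and testable. Real-data variant counts from any particular
historical toolchain are reproducible only with that toolchain.) Per-gene
density is variants per gene length as a percentage; a variant in two
overlapping genes is credited to both, while coding/non-coding/intergenic
totals count each site once.

The mitochondrial simulator plants exactly `round(divergence × length)`
SNVs (sampled without replacement), so pairwise identity is exact by
construction, and samples the M-like genome at `depth_f / copy_ratio` —
emulating the ~10:1 copy-number imbalance seen between dominant and
secondary organelle haplotypes.

## Completeness and enrichment

A core-gene match is "complete" only when its aligned span strictly
exceeds 90% of the protein; any significant match is "partial".
Percentages are computed from counts and rounded half-up to two decimals
(a printed source that disagrees with its own counts is not matched).
Repertoire extrapolation divides the predicted gene count by the
*partial* fraction by default — any recovered match is evidence the gene
space contains the gene — and the raw value is also reported alongside
the nearest-thousand rounding.

GO comparison tests each term's 2×2 table (annotated vs not, per set)
with the two-sided Fisher exact test (sum of hypergeometric probabilities
≤ the observed table's), delegated to scipy; BH-FDR comes from
statsmodels with flags at q ≤ α (default 0.05). Terms absent from both
tables are excluded from the multiple-testing burden. Direction symbols:
"++" over-represented in set A, "--" under-represented, "⌘"
non-significant. No GO-graph propagation is performed; counts are taken
as given. The table simulator draws per-term base proportions uniformly
in [0.002, 0.02] and counts as Binomial(total, p), with p multiplied by
the planted fold in table A.

## Problem sizes and test design

The test suite and acceptance script run everything from scratch at sizes
chosen to keep the full run within a few minutes on one CPU while leaving
the statistical properties comfortably measurable: the headline spectrum
simulation uses a 2-Mb genome at 32× 17-mer coverage (≈ 64M k-mers);
property suites use 100–500-kb genomes, 8-kb mitochondrial circles at
50× over 20 seeds, and 500 null GO comparisons. Scale-sensitive checks
(depth calibration, size recovery) are asserted at the tolerances at
which they hold for any genome ≥ 100 kb. The depth-rescaling invariance
test uses k-mer depths 30.5 and 61 so the smoothed Poisson modes are
unambiguous at the lower depth and the worst-case one-bin jitter at the
doubled depth stays inside the 2% assertion.

## Known limitations

- Simulated reads lack realistic error profiles; QC and SNV performance
  numbers on synthetic data are upper bounds for real libraries.
- The exact k-mer counter holds all window codes in memory (~8 bytes per
  k-mer instance); it is sized for desk-scale simulations, not for
  billion-read runs.
- The minimal mapper is ungapped and exact-seeded; highly diverged or
  indel-rich reads go unmapped rather than being soft-clipped.
- `classify_peaks` assumes the same one or two genuine modes exist at
  every k; spectra with repeat-driven shoulders need manual inspection.
- Adapter and poly-A rules are whole-read drop rules by design; no
  trimming is implemented.
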