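# genomesurvey

A toolkit for the computations behind a low-coverage ("genome survey")
whole-genome sequencing study of a non-model organism — the setting where a
diploid genome is sequenced with short paired-end reads at modest depth and
most conclusions must come from read-level and draft-assembly-level
statistics rather than a finished genome. The package re-implements each
analysis step as a tested, reusable library with a CLI, and ships a
synthetic-data generator that reproduces the statistical structure those
analyses assume, with ground-truth labels for every planted signal.

It is aimed at bioinformaticians who want desk-scale, verifiable versions of
the survey pipeline: to teach it, test it, or sanity-check a real run.

## What it computes

- **Read QC** (`readqc`): the five classic whole-read drop rules — N
  fraction > 5%, poly-A structure, ≥ 20 low-quality bases, ungapped adapter
  match (≥ 11 aligned bases, ≤ 3 mismatches), and mate overlap ≥ 10 bp at
  ≤ 10% mismatch — with per-rule drop attribution.
- **K-mer spectrum and genome size** (`kmers`): exact canonical k-mer
  counting (2-bit packed, k ≤ 31). A diploid genome at k-mer depth *d*
  yields a bimodal spectrum with the homozygous (coverage) peak at *d* and
  the heterozygous peak at *d*/2. Comparing spectra across k ∈ {15, 17,
  19, 21} identifies the coverage peak as the one whose height stays stable
  (a longer k-mer is more likely to overlap a heterozygous site, so only
  the heterozygous peak grows with k). Genome size is then

      G = (total k-mer count above the error trough) / (coverage-peak depth)

- **Assembly statistics** (`assembly`): scaffold/contig splits at ≥ 25-N
  captured gaps, N50, size-class tallies, scaffolded vs unscaffolded base
  partition, and repeat-landscape summaries from masked intervals.
- **Contamination screen** (`contamination`): candidate contigs whose
  accumulated matched regions exceed 10% of the contig, confirmed only when
  the best protein hit (lowest e-value, then highest bit-score) is
  bacterial at e ≤ 1e-6.
- **Mitochondrial analysis** (`mito`): alignment specificity filters
  (e ≤ 1e-6, identity ≥ 90%, per-contig aligned fraction ≥ 90%), reference
  coverage, a greedy tiling path, a minimal seed-and-extend read mapper for
  circular references, depth profiling with least-covered-window detection,
  pileup SNV calling, and per-gene variant density.
- **Gene-space completeness** (`completeness`): core-gene matches spanning
  > 90% of the protein are "complete", any significant match is "partial",
  and the gene repertoire extrapolates as `n_predicted / fraction_recovered`.
- **GO-set comparison** (`enrichment`): per-term two-sided Fisher's exact
  test on 2×2 count tables with Benjamini–Hochberg FDR control and
  over-/under-representation symbols.
- **Synthetic data** (`simulate`): diploid genomes with SNV-only
  heterozygosity, reads with planted QC violations at configured rates,
  diverged circular mitochondrial genome pairs at an unequal copy ratio,
  core-gene match tables, and GO count tables with planted enrichment —
  all deterministic per seed, all with verifiable labels.

## Worked example

Estimate genome size from a simulated survey of a 500-kb diploid genome
with 1% heterozygosity at 32× k-mer depth:

```python
from genomesurvey.simulate import simulate_diploid_genome, reads_for_kmer_coverage
from genomesurvey.kmers import (count_canonical_kmers, classify_peaks,
                                estimate_genome_size)

genome = simulate_diploid_genome(500_000, het_rate=0.01, seed=7)
hists = [count_canonical_kmers(reads_for_kmer_coverage(genome, 32, k, seed=8), k)
         for k in (15, 17, 19, 21)]
for k, ps in zip((15, 17, 19, 21), classify_peaks(hists)):
    print(k, ps.het_peak, ps.coverage_peak)
h17, ps17 = hists[1], classify_peaks(hists)[1]
est = estimate_genome_size(h17, ps17.coverage_peak, exclude_below=ps17.error_trough)
print(round(est.size_bp))
```

prints

```
15 16 31
17 16 32
19 16 31
21 16 32
500002
```

The heterozygous peak sits at 16 (half the 32× depth) for every k while the
coverage peak sits at 31–32 (the smoothed Poisson mode jitters by one bin);
the height-stability rule assigns them correctly at every k, and the size
estimate recovers the true 500 kb haplotype length to 0.001%.

The same operations are exposed on the command line:

```bash
genomesurvey qc --in1 r1.fastq --in2 r2.fastq --out-prefix clean
genomesurvey kmer count --reads clean.1.fastq --k 17 --out histo.tsv
genomesurvey kmer size --histo histo.tsv --k 17
genomesurvey asmstats --fasta assembly.fasta
genomesurvey ceg --table ceg.tsv --n-predicted 10891
```

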