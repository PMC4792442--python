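"""K-mer spectrum: counting correctness, peak logic, size estimation."""

from collections import Counter

import numpy as np
import pytest

from genomesurvey.kmers import (
    KmerHistogram,
    NoPeakError,
    classify_peaks,
    count_canonical_kmers,
    detect_peaks,
    estimate_genome_size,
    find_error_trough,
    smooth_histogram,
)
from genomesurvey.readqc import revcomp
from genomesurvey.simulate import reads_for_kmer_coverage, simulate_diploid_genome


def naive_histogram(seqs, k):
    """Explicit canonical string multiset — the independent counting oracle."""
    counter = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) <= set("ACGT"):
                counter[min(w, revcomp(w))] += 1
    return dict(Counter(counter.values()))


class TestCounting:
    def test_window_count_single_read(self):
        hist = count_canonical_kmers(["ACGTACGT"], 3)
        assert hist.total_kmers == 6

    def test_reverse_complement_identity(self):
        hist = count_canonical_kmers(["AAT", "ATT"], 3)
        assert hist.counts == {2: 1}

    def test_matches_naive_oracle_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1000))
        hist = count_canonical_kmers([seq], 15)
        assert hist.counts == naive_histogram([seq], 15)

    def test_matches_naive_oracle_with_ambiguous_bases_and_reads(self, rng):
        reads = [
            "".join(rng.choice(list("ACGTN"), rng.integers(20, 60), p=[0.23] * 4 + [0.08]))
            for _ in range(50)
        ]
        for k in (5, 7):
            assert count_canonical_kmers(reads, k).counts == naive_histogram(reads, k)

    def test_counting_conservation(self, rng):
        reads = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(100)]
        hist = count_canonical_kmers(reads, 21)
        assert hist.total_kmers == sum(len(r) - 20 for r in reads)

    def test_long_sequence_sliced_counting_is_exact(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 3000))
        direct = count_canonical_kmers([seq], 11, batch_windows=100)
        assert direct.counts == naive_histogram([seq], 11)

    @pytest.mark.parametrize("k", [4, 33, 0])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValueError):
            count_canonical_kmers(["ACGT"], k)


def _hist(counts, k=17):
    return KmerHistogram(k=k, counts=counts)


class TestTroughAndPeaks:
    def test_error_free_spectrum_has_trough_at_one(self):
        # rising from m=1: no error component
        h = _hist({1: 5, 2: 10, 3: 40, 4: 80, 5: 40})
        assert find_error_trough(h) == 1

    def test_descending_then_rising_trough(self):
        h = _hist({1: 1000, 2: 400, 3: 100, 4: 20, 5: 60, 6: 300, 7: 500, 8: 300})
        assert find_error_trough(h) == 4

    def test_monotone_decreasing_is_flagged(self):
        h = _hist({1: 1000, 2: 500, 3: 250, 4: 100, 5: 10})
        with pytest.raises(NoPeakError):
            find_error_trough(h)

    def test_single_class_histogram_rejected(self):
        with pytest.raises(NoPeakError):
            find_error_trough(_hist({30: 100}))

    def test_single_poisson_peak_detected_at_mode(self, rng):
        from scipy.stats import poisson

        m = np.arange(1, 80)
        counts = {int(i): int(1e6 * poisson.pmf(i, 30)) for i in m if poisson.pmf(i, 30) > 1e-8}
        ps = detect_peaks(_hist(counts), trough=1)
        assert len(ps.peaks) == 1
        assert ps.peaks[0][0] == 30

    def test_bimodal_histogram_peak_ratio_one_to_two(self):
        from scipy.stats import poisson

        counts = {}
        for i in range(2, 80):
            c = 6e5 * poisson.pmf(i, 16) + 1.5e6 * poisson.pmf(i, 32)
            if c >= 1:
                counts[i] = int(c)
        ps = detect_peaks(_hist(counts), trough=1)
        (lo, _), (hi, _) = ps.peaks
        assert hi / lo == pytest.approx(2.0, abs=0.15)

    def test_flat_histogram_has_no_peak(self):
        with pytest.raises(NoPeakError):
            detect_peaks(_hist({m: 100 for m in range(2, 12)}), trough=1)


class TestClassifyPeaks:
    @staticmethod
    def _family(het_heights, cov_height=1000.0):
        """Histogram family: peak at 16 with varying height, stable peak at 32."""
        from scipy.stats import poisson

        hists = []
        for hh in het_heights:
            counts = {}
            # modes at 16 and 32; lambdas off the integer so the smoothed
            # mode is unambiguous in this constructed fixture
            for i in range(2, 70):
                c = hh * 40 * poisson.pmf(i, 16.3) + cov_height * 40 * poisson.pmf(i, 32.6)
                if c >= 1:
                    counts[i] = int(c)
            hists.append(_hist(counts))
        return hists

    def test_height_stable_peak_is_coverage_peak(self):
        hists = self._family([300.0, 600.0, 900.0, 1200.0])
        classified = classify_peaks(hists)
        for ps in classified:
            assert ps.coverage_peak == 32
            assert ps.het_peak == 16

    def test_simulated_diploid_assigns_lower_peak_heterozygous(self):
        genome = simulate_diploid_genome(200_000, 0.01, seed=31)
        hists = []
        for k in (15, 17, 19, 21):
            reads = reads_for_kmer_coverage(genome, 32, k, seed=32)
            hists.append(count_canonical_kmers(reads, k))
        classified = classify_peaks(hists)
        for ps in classified:
            assert ps.het_peak < ps.coverage_peak
            assert ps.coverage_peak == pytest.approx(32, abs=2)
            assert ps.het_peak == pytest.approx(16, abs=2)

    def test_haploid_simulation_has_single_peak_no_het(self, haploid_genome):
        hists = [
            count_canonical_kmers(reads_for_kmer_coverage(haploid_genome, 30, k, seed=33), k)
            for k in (17, 21)
        ]
        classified = classify_peaks(hists)
        for ps in classified:
            assert ps.het_peak is None
            assert ps.coverage_peak == pytest.approx(30, abs=2)

    def test_unmatchable_peaks_raise(self):
        a = self._family([500.0])[0]
        from scipy.stats import poisson

        shifted = {
            i: int(2e4 * poisson.pmf(i, 8) + 4e4 * poisson.pmf(i, 60))
            for i in range(2, 90)
            if 2e4 * poisson.pmf(i, 8) + 4e4 * poisson.pmf(i, 60) >= 1
        }
        with pytest.raises(NoPeakError):
            classify_peaks([a, _hist(shifted)])


class TestGenomeSize:
    def test_closed_form(self):
        h = _hist({30: 1_000_000})  # 3.0e7 k-mers all at multiplicity 30
        est = estimate_genome_size(h, 30, exclude_below=1)
        assert est.size_bp == pytest.approx(1.0e6)
        assert est.kmers_used == 30_000_000

    def test_parameter_recovery_on_diploid_simulation(self):
        genome = simulate_diploid_genome(300_000, 0.01, seed=34)
        reads = reads_for_kmer_coverage(genome, 32, 17, seed=35)
        hist = count_canonical_kmers(reads, 17)
        ps = detect_peaks(hist)
        est = estimate_genome_size(hist, ps.peaks[-1][0], exclude_below=ps.error_trough)
        assert est.size_bp == pytest.approx(genome.length, rel=0.05)

    def test_scale_invariance_under_depth_rescaling(self):
        genome = simulate_diploid_genome(200_000, 0.01, seed=36)
        sizes = []
        for cov in (30.5, 61.0):
            reads = reads_for_kmer_coverage(genome, cov, 17, seed=37)
            hist = count_canonical_kmers(reads, 17)
            ps = detect_peaks(hist)
            est = estimate_genome_size(hist, ps.peaks[-1][0], exclude_below=ps.error_trough)
            sizes.append(est.size_bp)
        assert sizes[0] == pytest.approx(sizes[1], rel=0.02)

    def test_zero_kmers_above_trough_rejected(self):
        with pytest.raises(NoPeakError):
            estimate_genome_size(_hist({1: 10, 2: 5}), 30, exclude_below=10)

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            estimate_genome_size(_hist({30: 10}), 0, exclude_below=1)
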