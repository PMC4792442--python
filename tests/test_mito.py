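"""Mitochondrial pipeline: alignment filtering, tiling, mapping, SNVs, density."""

import numpy as np
import pytest

from genomesurvey.mito import (
    AlignmentRecord,
    Gene,
    Placement,
    build_tiling,
    call_snvs,
    depth_profile,
    filter_mito_alignments,
    map_reads_minimal,
    placements_from_sam,
    reference_coverage,
    variant_density_by_gene,
)
from genomesurvey.readqc import revcomp
from genomesurvey.simulate import simulate_mito_pair


def _rec(qid, r_start, r_end, *, qlen=1000, q_start=0, q_end=None, ident=99.0,
         ev=1e-30, rlen=16000, reverse=False):
    q_end = q_end if q_end is not None else min(qlen, r_end - r_start)
    return AlignmentRecord(
        query_id=qid, query_len=qlen, ref_id="mt", ref_len=rlen,
        q_start=q_start, q_end=q_end, r_start=r_start, r_end=r_end,
        identity=ident, evalue=ev, reverse=reverse,
    )


class TestAlignmentFilter:
    def test_identity_below_ninety_dropped(self):
        rec = _rec("c1", 0, 1000, ident=89.9, q_end=1000)
        assert filter_mito_alignments([rec]) == []

    def test_coverage_exactly_ninety_kept(self):
        rec = _rec("c1", 0, 900, qlen=1000, q_start=0, q_end=900)
        assert filter_mito_alignments([rec]) == [rec]

    def test_evalue_above_cutoff_dropped(self):
        rec = _rec("c1", 0, 1000, ev=1e-5, q_end=1000)
        assert filter_mito_alignments([rec]) == []

    def test_per_contig_accumulated_coverage(self):
        # two half-coverage records on one contig jointly reach 90%
        a = _rec("c1", 0, 500, qlen=1000, q_start=0, q_end=500)
        b = _rec("c1", 600, 1100, qlen=1000, q_start=450, q_end=950)
        assert set(map(id, filter_mito_alignments([a, b]))) == {id(a), id(b)}
        # alone, each fails the 90% accumulated-coverage gate
        assert filter_mito_alignments([a]) == []


class TestReferenceCoverage:
    def test_full_single_record(self):
        frac, n = reference_coverage([_rec("c1", 0, 16000, qlen=16000, q_end=16000)], 16000)
        assert frac == pytest.approx(1.0) and n == 1

    def test_union_of_overlapping_records(self):
        recs = [
            _rec("c1", 0, 8000, qlen=8000, q_end=8000),
            _rec("c2", 4000, 12000, qlen=8000, q_end=8000),
        ]
        frac, n = reference_coverage(recs, 16000)
        assert frac == pytest.approx(0.75) and n == 2

    def test_empty(self):
        assert reference_coverage([], 16000) == (0.0, 0)


class TestTiling:
    def test_fragmented_reference_is_tiled_once_per_contig(self, rng):
        # staircase of ~1.6-kb pieces with ~10% overlaps covering the circle once
        recs, start = [], 0
        i = 0
        while start < 15_000:
            end = min(16_000, start + 1600)
            recs.append(_rec(f"c{i}", start, end, qlen=end - start, q_end=end - start))
            start = end - 160
            i += 1
        path = build_tiling(recs, 16_000)
        assert path.covered_fraction >= 0.99
        used = [s.record.query_id for s in path.segments]
        assert len(used) == len(set(used))

    def test_identical_records_tie(self):
        a = _rec("c1", 100, 900, qlen=800, q_end=800)
        b = _rec("c2", 100, 900, qlen=800, q_end=800)
        path = build_tiling([a, b], 16_000)
        assert len(path.segments) == 1

    def test_hole_reported_as_gap(self):
        recs = [
            _rec("c1", 0, 5000, qlen=5000, q_end=5000),
            _rec("c2", 6000, 12000, qlen=6000, q_end=6000),
        ]
        path = build_tiling(recs, 16_000)
        assert path.gaps == [(5000, 6000)]
        assert len(path.segments) == 2

    def test_covered_fraction_matches_reference_coverage_when_all_used(self):
        recs = [
            _rec("c1", 0, 4000, qlen=4000, q_end=4000),
            _rec("c2", 3500, 8000, qlen=4500, q_end=4500),
            _rec("c3", 7500, 12000, qlen=4500, q_end=4500),
        ]
        path = build_tiling(recs, 16_000)
        frac, _ = reference_coverage(recs, 16_000)
        assert len(path.segments) == 3
        assert path.covered_fraction == pytest.approx(frac)

    def test_short_records_excluded(self):
        path = build_tiling([_rec("c1", 0, 50, qlen=50, q_end=50)], 16_000)
        assert path.segments == []


class TestMapping:
    def test_error_free_reads_map_to_true_origin(self):
        f, _, reads, labels = simulate_mito_pair(4_000, 0.1, 1, 20, seed=41)
        f_reads = [(rid, s) for rid, s in reads if labels.mito_sources[rid] == "F"]
        placements, unmapped = map_reads_minimal(f_reads, f)
        assert unmapped == []
        by_id = {p.read_id: p for p in placements}
        for rid, _ in f_reads:
            pos, rev = labels.read_origins[rid]
            assert by_id[rid].pos == pos
            assert by_id[rid].reverse == rev
            assert by_id[rid].mismatches == 0

    def test_unrelated_read_is_unmapped(self, rng):
        f, _, _, _ = simulate_mito_pair(4_000, 0.1, 1, 0, seed=42)
        alien = "".join(rng.choice(list("ACGT"), 100))
        placements, unmapped = map_reads_minimal([("alien", alien)], f)
        assert unmapped == ["alien"] and placements == []

    def test_origin_spanning_read_gets_modular_coordinates(self):
        f, _, _, _ = simulate_mito_pair(2_000, 0.1, 1, 0, seed=43)
        read = f[1950:] + f[:50]
        placements, _ = map_reads_minimal([("wrap", read)], f)
        assert len(placements) == 1
        assert placements[0].pos == 1950

    def test_read_longer_than_reference_rejected(self):
        with pytest.raises(ValueError):
            map_reads_minimal([("big", "A" * 200)], "ACGT" * 30)


class TestDepthProfile:
    def test_uniform_reads_mean_near_nominal(self):
        f, _, reads, labels = simulate_mito_pair(8_000, 0.1, 1, 50, seed=44)
        reads = [(rid, s) for rid, s in reads if labels.mito_sources[rid] == "F"]
        placements, _ = map_reads_minimal(reads, f)
        prof = depth_profile(placements, 8_000)
        assert prof.mean_depth == pytest.approx(50, rel=0.05)
        assert prof.min_window_depth > 0
        # coverage-depth conservation: sum of depth == sum of placed lengths
        assert int(prof.depth.sum()) == sum(p.length for p in placements)

    def test_no_reads_all_zero(self):
        prof = depth_profile([], 1000)
        assert prof.depth.sum() == 0 and prof.mean_depth == 0.0

    def test_planted_coverage_hole_is_found(self):
        f, _, reads, labels = simulate_mito_pair(8_000, 0.1, 1, 40, seed=45)
        hole = (3000, 3500)
        kept = []
        for rid, seq in reads:
            if labels.mito_sources[rid] != "F":
                continue
            pos, _ = labels.read_origins[rid]
            end = pos + len(seq)
            if not (pos < hole[1] and end > hole[0]) and end <= 8_000:
                kept.append((rid, seq))
        placements, _ = map_reads_minimal(kept, f)
        prof = depth_profile(placements, 8_000)
        # excluding overlapping reads also shadows up to a read length
        # left of the hole, so the minimum window must overlap the hole
        assert hole[0] - 100 <= prof.min_window_start < hole[1]
        assert prof.min_window_depth == 0.0


class TestSnvCalling:
    def test_recall_and_precision_on_planted_variants(self):
        recalls, precisions = [], []
        for seed in range(20):
            f, m, reads, labels = simulate_mito_pair(
                8_000, 20 / 8_000, 1.0, 50, seed=500 + seed, error_rate=0.001
            )
            m_reads = [(rid, s) for rid, s in reads if labels.mito_sources[rid] == "M"]
            placements, _ = map_reads_minimal(m_reads, f)
            called = {v.pos for v in call_snvs(placements, f)}
            planted = set(labels.snv_alleles)
            recalls.append(len(called & planted) / len(planted))
            precisions.append(len(called & planted) / max(1, len(called)))
        assert np.mean(recalls) >= 0.95
        assert np.mean(precisions) >= 0.95

    def test_reference_reads_give_zero_variants(self):
        f, _, reads, labels = simulate_mito_pair(4_000, 0.1, 1, 30, seed=46)
        f_reads = [(rid, s) for rid, s in reads if labels.mito_sources[rid] == "F"]
        placements, _ = map_reads_minimal(f_reads, f)
        assert call_snvs(placements, f) == []

    def test_depth_gate_boundary(self):
        rng = np.random.default_rng(99)
        ref = "".join(rng.choice(list("ACGT"), 200))
        # nine perfect-alt reads at one site: below the depth-10 gate
        alt_ref = ref[:100] + ("A" if ref[100] != "A" else "C") + ref[101:]
        reads = [(f"r{i}", alt_ref[60:140]) for i in range(9)]
        placements, _ = map_reads_minimal(reads, ref)
        assert call_snvs(placements, ref) == []
        reads = [(f"r{i}", alt_ref[60:140]) for i in range(10)]
        placements, _ = map_reads_minimal(reads, ref)
        called = call_snvs(placements, ref)
        assert [v.pos for v in called] == [100]


class TestVariantDensity:
    @staticmethod
    def _variants(positions, ref="A" * 2000):
        from genomesurvey.mito import Variant

        return [Variant(pos=p, ref="A", alt="G", depth=50, alt_count=25) for p in positions]

    def test_gene_with_planted_variants_ranks_first(self):
        genes = [Gene("quiet", 0, 500), Gene("hot", 600, 800), Gene("trna", 900, 950, coding=False)]
        table = variant_density_by_gene(self._variants([650, 700, 750]), genes, 2000)
        assert table.rows.iloc[0]["gene"] == "hot"
        assert table.coding_variants == 3 and table.intergenic_variants == 0

    def test_empty_variant_list(self):
        table = variant_density_by_gene([], [Gene("g", 0, 100)], 2000)
        assert table.rows["variants"].sum() == 0

    def test_density_closed_form(self):
        genes = [Gene("small", 0, 100), Gene("big", 100, 1100)]
        table = variant_density_by_gene(self._variants([50, 600]), genes, 2000)
        rows = table.rows.set_index("gene")
        assert rows.loc["small", "pct_variants_per_bp"] == pytest.approx(1.0)
        assert rows.loc["big", "pct_variants_per_bp"] == pytest.approx(0.1)

    def test_overlapping_genes_both_credited_but_totals_count_once(self):
        genes = [Gene("a", 0, 200), Gene("b", 100, 300)]
        table = variant_density_by_gene(self._variants([150]), genes, 2000)
        assert table.rows["variants"].sum() == 2
        assert table.coding_variants == 1


class TestSamIngestion:
    def test_placements_from_text_sam(self, tmp_path):
        ref = "ACGTACGTAA" * 20
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:mt\tLN:200\n"
            f"r1\t0\tmt\t11\t60\t20M\t*\t0\t0\t{ref[10:30]}\t*\tNM:i:0\n"
            f"r2\t16\tmt\t51\t60\t20M\t*\t0\t0\t{ref[50:70]}\t*\tNM:i:1\n"
        )
        placements = placements_from_sam(str(sam), 200)
        assert [p.pos for p in placements] == [10, 50]
        assert [p.reverse for p in placements] == [False, True]
        prof = depth_profile(placements, 200)
        assert int(prof.depth.sum()) == 40
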