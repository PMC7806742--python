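"""Interval algebra and regulatory taxonomy, checked against a per-base
bitmap oracle (and bedtools as an independent implementation)."""
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bitmap, bitmap_to_spans, peakset_to_spans, random_peakset
from tscepi.regions import (
    PromoterParams,
    annotate_region_class,
    derive_enhancers,
    gene_body,
    intersects,
    merge,
    overlap_any,
    pairwise_intersection,
    promoter_window,
    subtract,
    top_n_peaks,
)
from tscepi.types import ChromSizes, GeneModel, Interval, PeakSet


class TestPromoterWindow:
    def test_plus_strand(self, toy_sizes):
        g = GeneModel("g", "chr1", "+", 10_000, 30_000)
        w = promoter_window(g, toy_sizes, PromoterParams())
        assert (w.start, w.end) == (7_000, 10_500)

    def test_minus_strand_mirrored(self, toy_sizes):
        g = GeneModel("g", "chr1", "-", 2_000, 10_000)
        w = promoter_window(g, toy_sizes, PromoterParams())
        assert (w.start, w.end) == (9_500, 13_000)

    def test_clipped_at_chromosome_start(self, toy_sizes):
        g = GeneModel("g", "chr1", "+", 1_000, 5_000)
        w = promoter_window(g, toy_sizes, PromoterParams())
        assert (w.start, w.end) == (0, 1_500)

    def test_fully_outside_is_error(self):
        # TSS at position 0 with no downstream extension: [-3000, 0) is empty
        # after clipping, so no promoter window can be derived.
        g = GeneModel("g", "chr1", "+", 0, 100)
        with pytest.raises(ValueError, match="outside"):
            promoter_window(
                g, ChromSizes([("chr1", 600)]), PromoterParams(upstream=3000, downstream=0)
            )

    def test_gene_body_ignores_strand(self):
        for strand in "+-":
            g = GeneModel("g", "chr1", strand, 5_000, 9_000)
            b = gene_body(g)
            assert (b.start, b.end) == (5_000, 9_000)


class TestIntersects:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (Interval("chr1", 0, 100), Interval("chr1", 99, 200), True),  # 1 bp
            (Interval("chr1", 0, 100), Interval("chr1", 100, 200), False),  # adjacency
            (Interval("chr1", 0, 100), Interval("chr1", 0, 100), True),
            (Interval("chr1", 0, 100), Interval("chr2", 0, 100), False),
        ],
    )
    def test_one_bp_rule(self, a, b, expected):
        assert intersects(a, b) is expected
        assert intersects(b, a) is expected


class TestSetAlgebraExamples:
    def test_merge_overlapping(self):
        ps = PeakSet("X", None, [Interval("chr1", 0, 10), Interval("chr1", 5, 20)])
        assert peakset_to_spans(merge(ps)) == [("chr1", 0, 20)]

    def test_subtract_splits(self):
        a = PeakSet("A", None, [Interval("chr1", 0, 20)])
        b = PeakSet("B", None, [Interval("chr1", 5, 10)])
        assert peakset_to_spans(subtract(a, b)) == [("chr1", 0, 5), ("chr1", 10, 20)]

    def test_enhancer_example(self):
        k4 = PeakSet("H3K4me1", None, [Interval("chr1", 0, 1000)])
        k27 = PeakSet("H3K27ac", None, [Interval("chr1", 500, 1500)])
        prom = PeakSet("promoter", None, [Interval("chr1", 900, 1200)])
        enh = derive_enhancers(k4, k27, prom)
        assert peakset_to_spans(enh) == [("chr1", 500, 900)]

    def test_disjoint_marks_give_no_enhancers(self):
        k4 = PeakSet("H3K4me1", None, [Interval("chr1", 0, 100)])
        k27 = PeakSet("H3K27ac", None, [Interval("chr1", 200, 300)])
        assert len(derive_enhancers(k4, k27, PeakSet("p", None, []))) == 0

    def test_overlap_any_counts(self):
        q = PeakSet("Q", None, [Interval("chr1", 0, 10), Interval("chr1", 20, 30), Interval("chr1", 40, 50)])
        t = PeakSet("T", None, [Interval("chr1", 5, 8), Interval("chr1", 45, 60)])
        flags, count = overlap_any(q, t)
        assert flags.tolist() == [True, False, True]
        assert count == 2

    def test_overlap_any_empty_targets(self):
        q = PeakSet("Q", None, [Interval("chr1", 0, 10)])
        flags, count = overlap_any(q, PeakSet("T", None, []))
        assert flags.tolist() == [False] and count == 0


class TestSetAlgebraOracle:
    """Randomised base-level agreement with the bitmap oracle."""

    CHROMS = {"chr1": 10_000, "chr2": 4_000}

    @pytest.mark.parametrize("seed", range(25))
    def test_merge_subtract_intersect_match_bitmap(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peakset(rng, int(rng.integers(0, 200)), self.CHROMS)
        b = random_peakset(rng, int(rng.integers(0, 200)), self.CHROMS)
        bm_a, bm_b = bitmap(a, self.CHROMS), bitmap(b, self.CHROMS)
        assert peakset_to_spans(merge(a)) == bitmap_to_spans(bm_a)
        assert peakset_to_spans(subtract(a, b)) == bitmap_to_spans(
            {c: bm_a[c] & ~bm_b[c] for c in bm_a}
        )
        assert peakset_to_spans(pairwise_intersection(a, b)) == bitmap_to_spans(
            {c: bm_a[c] & bm_b[c] for c in bm_a}
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_overlap_any_matches_bitmap(self, seed):
        rng = np.random.default_rng(1000 + seed)
        q = random_peakset(rng, 200, self.CHROMS)
        t = random_peakset(rng, 200, self.CHROMS)
        bm_t = bitmap(t, self.CHROMS)
        flags, count = overlap_any(q, t)
        expected = [bool(bm_t[iv.chrom][iv.start : iv.end].any()) for iv in q]
        assert flags.tolist() == expected
        assert count == sum(expected)

    def test_pairwise_intersection_symmetric(self):
        rng = np.random.default_rng(5)
        a = random_peakset(rng, 100, self.CHROMS)
        b = random_peakset(rng, 100, self.CHROMS)
        assert peakset_to_spans(pairwise_intersection(a, b)) == peakset_to_spans(
            pairwise_intersection(b, a)
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_merge_idempotent_and_subtract_empty(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peakset(rng, int(rng.integers(1, 60)), {"chr1": 5_000})
        merged = merge(a)
        assert peakset_to_spans(merge(merged)) == peakset_to_spans(merged)
        assert peakset_to_spans(subtract(a, PeakSet("E", None, []))) == peakset_to_spans(merged)


class TestBedtoolsCrossCheck:
    """Independent oracle: the field-standard interval tool."""

    def test_merge_and_intersect_agree_with_bedtools(self, tmp_path):
        assert shutil.which("bedtools"), "bedtools expected on PATH"
        rng = np.random.default_rng(42)
        chroms = {"chr1": 50_000}
        a = random_peakset(rng, 150, chroms)
        b = random_peakset(rng, 150, chroms)

        def to_bed(ps, path):
            with open(path, "w") as fh:
                for c, s, e in sorted((iv.chrom, iv.start, iv.end) for iv in ps):
                    fh.write(f"{c}\t{s}\t{e}\n")

        to_bed(a, tmp_path / "a.bed")
        to_bed(b, tmp_path / "b.bed")

        def run(args):
            out = subprocess.run(args, capture_output=True, text=True, check=True, cwd=tmp_path)
            spans = []
            for line in out.stdout.strip().splitlines():
                c, s, e = line.split("\t")[:3]
                spans.append((c, int(s), int(e)))
            return sorted(spans)

        assert peakset_to_spans(merge(a)) == run(["bedtools", "merge", "-i", "a.bed"])
        got = peakset_to_spans(pairwise_intersection(a, b))
        want = run(["bedtools", "intersect", "-a", "a.bed", "-b", "b.bed"])
        # bedtools reports one row per a/b pair; reduce to the merged base set
        want_ps = PeakSet("w", None, [Interval(c, s, e) for c, s, e in want])
        assert got == peakset_to_spans(merge(want_ps))
        got_sub = peakset_to_spans(subtract(a, b))
        want_sub = run(["bedtools", "subtract", "-a", "a.bed", "-b", "b.bed"])
        want_sub_ps = PeakSet("w", None, [Interval(c, s, e) for c, s, e in want_sub])
        assert got_sub == peakset_to_spans(merge(want_sub_ps))


class TestTopN:
    def _peaks(self, qs, scores=None):
        scores = scores or [1.0] * len(qs)
        return PeakSet(
            "X",
            None,
            [
                Interval("chr1", 10 * i, 10 * i + 5, score=s, qvalue=q)
                for i, (q, s) in enumerate(zip(qs, scores))
            ],
        )

    def test_small_set_returned_whole(self):
        ps = self._peaks([0.1] * 10)
        assert len(top_n_peaks(ps, 65_000)) == 10

    def test_tie_break_prefers_higher_score(self):
        ps = self._peaks([1e-3, 1e-3], scores=[5.0, 8.0])
        best = top_n_peaks(ps, 1).intervals[0]
        assert best.score == 8.0

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        qs = rng.uniform(0, 1, 100).tolist()
        ps = self._peaks(qs)
        got = top_n_peaks(ps, 30)
        expected = sorted(qs)[:30]
        assert sorted(iv.qvalue for iv in got) == pytest.approx(expected)

    def test_missing_qvalue_is_error(self):
        ps = PeakSet("X", None, [Interval("chr1", 0, 5, qvalue=None)])
        with pytest.raises(ValueError, match="q-value"):
            top_n_peaks(ps, 1)


class TestAnnotateRegionClass:
    def test_precedence_promoter_over_enhancer(self):
        peaks = PeakSet("X", None, [Interval("chr1", 100, 200)])
        prom = PeakSet("p", None, [Interval("chr1", 150, 300)])
        enh = PeakSet("e", None, [Interval("chr1", 100, 160)])
        classes, tallies = annotate_region_class(peaks, prom, enh, PeakSet("b", None, []))
        assert classes == ["promoter"]

    def test_orphan_peak_is_other(self):
        peaks = PeakSet("X", None, [Interval("chr1", 100, 200)])
        empty = PeakSet("e", None, [])
        classes, tallies = annotate_region_class(peaks, empty, empty, empty)
        assert classes == ["other"]
        assert tallies["other"] == 1

    def test_tallies_partition_peaks(self):
        rng = np.random.default_rng(8)
        chroms = {"chr1": 20_000}
        peaks = random_peakset(rng, 120, chroms)
        prom = random_peakset(rng, 10, chroms)
        enh = random_peakset(rng, 10, chroms)
        body = random_peakset(rng, 10, chroms)
        classes, tallies = annotate_region_class(peaks, prom, enh, body)
        assert sum(tallies.values()) == len(peaks) == len(classes)

    def test_planted_classes_recovered_exactly(self, small_study):
        """The generator records each peak's region class; annotation must agree."""
        from tscepi.regions import promoter_peakset, gene_body_peakset

        truth = small_study.truth
        prom = promoter_peakset(small_study.genes, small_study.sizes)
        bodies = gene_body_peakset(small_study.genes)
        enh = PeakSet("enh", None, truth.enhancers)
        for (factor, tp), ps in small_study.peaks.items():
            if len(ps) == 0:
                continue
            sub = truth.peak_classes[
                (truth.peak_classes["factor"] == factor)
                & (truth.peak_classes["timepoint"] == (tp if tp is not None else "NA"))
            ]
            classes, _ = annotate_region_class(ps, prom, enh, bodies)
            assert classes == sub["planted_class"].tolist(), (factor, tp)
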