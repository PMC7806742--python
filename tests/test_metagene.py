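"""Scaled-region matrices, profiles, and promoter-signal correlation."""
import numpy as np
import pytest

from tscepi.metagene import (
    MetageneParams,
    mean_profile,
    promoter_signal_correlation,
    scaled_region_matrix,
)
from tscepi.types import ChromSizes, GeneModel, Interval, PeakSet, SignalTrack

PARAMS = MetageneParams(upstream_flank=300, downstream_flank=300, body_bins=10, flank_bins=3)


def constant_track(chroms: dict[str, int], value: float) -> SignalTrack:
    return SignalTrack.from_steps([(c, 0, L, value) for c, L in chroms.items()])


def random_track(rng, chrom: str, length: int, step: int = 25) -> SignalTrack:
    edges = np.arange(0, length + step, step)
    edges[-1] = length
    edges = np.unique(edges)
    values = rng.uniform(0, 10, len(edges) - 1)
    return SignalTrack(
        {chrom: (edges[:-1].astype(np.int64), edges[1:].astype(np.int64), values)}
    )


def per_base_values(track: SignalTrack, chrom: str, length: int) -> np.ndarray:
    out = np.zeros(length)
    for c, s, e, v in track.iter_steps():
        if c == chrom:
            out[s:e] = v
    return out


class TestScaledRegionMatrix:
    def test_constant_track_gives_constant_matrix(self):
        sizes = ChromSizes([("chr1", 10_000)])
        track = constant_track({"chr1": 10_000}, 2.5)
        genes = [GeneModel("g1", "chr1", "+", 2_000, 4_000)]
        m = scaled_region_matrix(track, genes, sizes, PARAMS)
        assert m.values.shape == (1, 16)
        np.testing.assert_allclose(m.values, 2.5)

    def test_minus_strand_row_is_reversed_plus_computation(self):
        rng = np.random.default_rng(4)
        sizes = ChromSizes([("chr1", 10_000)])
        track = random_track(rng, "chr1", 10_000)
        plus = GeneModel("gp", "chr1", "+", 3_000, 5_000)
        minus = GeneModel("gm", "chr1", "-", 3_000, 5_000)
        m = scaled_region_matrix(track, [plus, minus], sizes, PARAMS)
        # mirrored gene on a mirrored track must equal the forward row
        mirror_steps = []
        for c, s, e, v in track.iter_steps():
            mirror_steps.append((c, 10_000 - e, 10_000 - s, v))
        mirrored = SignalTrack.from_steps(mirror_steps)
        minus_m = GeneModel("gm2", "chr1", "-", 10_000 - 5_000, 10_000 - 3_000)
        m2 = scaled_region_matrix(mirrored, [minus_m], sizes, PARAMS)
        np.testing.assert_allclose(m2.values[0], m.row("gp"), atol=1e-9)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_bins_match_per_base_oracle(self, strand):
        rng = np.random.default_rng(11)
        L = 8_000
        sizes = ChromSizes([("chr1", L)])
        track = random_track(rng, "chr1", L)
        gene = GeneModel("g", "chr1", strand, 2_500, 4_777)  # body not divisible by 10
        m = scaled_region_matrix(track, [gene], sizes, PARAMS)
        base = per_base_values(track, "chr1", L)
        body = gene.end - gene.start
        fb, bb = PARAMS.flank_bins, PARAMS.body_bins
        # oriented per-base vector: upstream flank, body, downstream flank
        if strand == "+":
            span = np.concatenate(
                [base[gene.start - 300 : gene.start], base[gene.start : gene.end], base[gene.end : gene.end + 300]]
            )
        else:
            span = np.concatenate(
                [base[gene.end : gene.end + 300][::-1], base[gene.start : gene.end][::-1], base[gene.start - 300 : gene.start][::-1]]
            )
        expected = []
        cursor = 0
        for total, bins in ((300, fb), (body, bb), (300, fb)):
            sizes_, rem = divmod(total, bins)
            for i in range(bins):
                w = sizes_ + (1 if i < rem else 0)
                expected.append(span[cursor : cursor + w].mean())
                cursor += w
        np.testing.assert_allclose(m.values[0], expected, atol=1e-9)

    def test_short_gene_skipped_with_warning(self, caplog):
        sizes = ChromSizes([("chr1", 10_000)])
        track = constant_track({"chr1": 10_000}, 1.0)
        short = GeneModel("tiny", "chr1", "+", 2_000, 2_005)
        ok = GeneModel("ok", "chr1", "+", 4_000, 6_000)
        with caplog.at_level("WARNING"):
            m = scaled_region_matrix(track, [short, ok], sizes, PARAMS)
        assert m.gene_ids == ["ok"]
        assert "tiny" in caplog.text

    def test_clipped_flank_contributes_zero(self):
        sizes = ChromSizes([("chr1", 10_000)])
        track = constant_track({"chr1": 10_000}, 4.0)
        gene = GeneModel("g", "chr1", "+", 100, 2_100)  # upstream flank clipped at 0
        m = scaled_region_matrix(track, [gene], sizes, PARAMS)
        # first flank bin covers [-200, -100): entirely off-chromosome -> 0
        assert m.values[0, 0] == 0.0
        # body bins untouched
        np.testing.assert_allclose(m.values[0, 3:13], 4.0)


class TestMeanProfile:
    def _matrix(self):
        sizes = ChromSizes([("chr1", 50_000)])
        track = constant_track({"chr1": 50_000}, 1.0)
        genes = [
            GeneModel("g1", "chr1", "+", 2_000, 4_000),
            GeneModel("g2", "chr1", "+", 10_000, 12_000),
        ]
        m = scaled_region_matrix(track, genes, sizes, PARAMS)
        m.values[0] = 1.0
        m.values[1] = 3.0
        return m

    def test_single_gene_subset_is_that_row(self):
        m = self._matrix()
        np.testing.assert_allclose(mean_profile(m, {"g2"}), 3.0)

    def test_two_gene_mean(self):
        m = self._matrix()
        np.testing.assert_allclose(mean_profile(m, {"g1", "g2"}), 2.0)

    def test_empty_subset_rejected(self):
        m = self._matrix()
        with pytest.raises(ValueError):
            mean_profile(m, set())

    def test_planted_promoter_peak_shapes(self, small_study):
        """Active genes show a promoter-proximal JMJD2B maximum; fully
        unmarked silent genes are flat within track noise."""
        track = small_study.tracks["JMJD2B_D0"]
        params = MetageneParams()
        matrix = scaled_region_matrix(track, small_study.genes, small_study.sizes, params)
        truth = small_study.truth
        j0 = truth.mark_status[("JMJD2B", "promoter", "D0")]
        active_j = set(truth.genes.index[(truth.genes["active_D0"]) & j0]) & set(matrix.gene_ids)
        unmarked = (
            ~truth.mark_status.any(axis=1)
        )
        silent_clean = set(truth.genes.index[(~truth.genes["active_D0"]) & unmarked]) & set(
            matrix.gene_ids
        )
        prof_active = mean_profile(matrix, active_j)
        prof_silent = mean_profile(matrix, silent_clean)
        fb, bb = params.flank_bins, params.body_bins
        # the promoter window spans the upstream flank plus the TSS-proximal
        # body, so the active profile must peak there and tower over the
        # distal gene body
        peak_bin = int(np.argmax(prof_active))
        assert peak_bin <= fb + 5
        promoter_mean = prof_active[:fb].mean()
        distal_body_mean = prof_active[fb + bb // 2 : fb + bb].mean()
        assert promoter_mean > 3 * distal_body_mean
        noise_ceiling = small_study.config.track_noise_max
        assert prof_silent.max() - prof_silent.min() < noise_ceiling


class TestPromoterCorrelation:
    def _promoters(self, n=500, width=100, spacing=150, chrom="chr1"):
        ivs = [
            Interval(chrom, i * spacing, i * spacing + width, name=f"p{i}")
            for i in range(n)
        ]
        return PeakSet("promoter", None, ivs)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        track = random_track(rng, "chr1", 100_000)
        proms = self._promoters()
        coef, _ = promoter_signal_correlation(track, track, proms)
        assert coef == pytest.approx(1.0)

    def test_monotone_negative_transform_gives_minus_one(self):
        rng = np.random.default_rng(1)
        track = random_track(rng, "chr1", 100_000)
        steps = [("chr1", s, e, 1000.0 - v) for _, s, e, v in track.iter_steps()]
        anti = SignalTrack.from_steps(steps)
        proms = self._promoters()
        coef, _ = promoter_signal_correlation(track, anti, proms, method="spearman")
        assert coef == pytest.approx(-1.0)

    def test_independent_tracks_weakly_correlated(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = random_track(rng, "chr1", 100_000)
            b = random_track(rng, "chr1", 100_000)
            coef, _ = promoter_signal_correlation(a, b, self._promoters())
            hits += abs(coef) < 0.15
        assert hits >= 19  # |rho| < 0.15 in ~95% of seeds under independence

    def test_zero_variance_rejected(self):
        flat = constant_track({"chr1": 100_000}, 1.0)
        rng = np.random.default_rng(2)
        other = random_track(rng, "chr1", 100_000)
        with pytest.raises(ValueError, match="variance"):
            promoter_signal_correlation(flat, other, self._promoters())

    def test_too_few_promoters_rejected(self):
        rng = np.random.default_rng(3)
        track = random_track(rng, "chr1", 10_000)
        with pytest.raises(ValueError):
            promoter_signal_correlation(track, track, self._promoters(n=2))
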