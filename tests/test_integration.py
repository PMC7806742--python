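"""Mark status, occupancy states, dynamics, cross-tabs and complex calls."""
import itertools

import numpy as np
import pandas as pd
import pytest

from tscepi.integration import (
    ALL_STATES,
    COMPLEX_CATEGORIES,
    DEFAULT_MARK_REGIONS,
    MarkStatusTable,
    assign_complex,
    build_mark_status,
    classify_dynamics,
    classify_state,
    complex_category,
    deg_dynamics_crosstab,
    dynamics_from_presence,
    dynamics_table,
    phase_label,
    state_code,
    state_table,
    summarize_fractions,
)
from tscepi.regions import gene_body, promoter_window
from tscepi.types import ChromSizes, GeneModel, Interval, PeakSet

TPS = ("D0", "D2", "D6")


def make_status(rows: dict[str, dict]) -> MarkStatusTable:
    """rows: gene_id -> {(mark, region, tp): bool}; missing cells filled False."""
    cols = [
        (m, r, tp)
        for m, r in (("JMJD2B", "promoter"), ("H3K9me3", "promoter"), ("H3K36me3", "gene_body"))
        for tp in TPS
    ]
    frame = pd.DataFrame(
        {c: [rows[g].get(c, False) for g in rows] for c in cols},
        index=list(rows),
    )
    frame.columns = pd.MultiIndex.from_tuples(cols, names=["mark", "region", "timepoint"])
    return MarkStatusTable(frame)


class TestBuildMarkStatus:
    def test_presence_from_peak_overlap(self):
        sizes = ChromSizes([("chr1", 100_000)])
        gene = GeneModel("g1", "chr1", "+", 10_000, 30_000)
        prom = {"g1": promoter_window(gene, sizes)}
        body = {"g1": gene_body(gene)}
        peaks = {
            ("JMJD2B", tp): PeakSet("JMJD2B", tp, [Interval("chr1", 7_100, 7_200)])
            for tp in TPS
        }
        peaks.update({("H3K9me3", tp): PeakSet("H3K9me3", tp, []) for tp in TPS})
        peaks.update(
            {
                ("H3K36me3", tp): PeakSet("H3K36me3", tp, [Interval("chr1", 20_000, 20_400)])
                for tp in TPS
            }
        )
        status = build_mark_status([gene], prom, body, peaks)
        assert status.present("g1", "JMJD2B", "promoter", "D0")
        assert not status.present("g1", "H3K9me3", "promoter", "D0")
        assert status.present("g1", "H3K36me3", "gene_body", "D6")

    def test_empty_peakset_means_all_absent(self):
        sizes = ChromSizes([("chr1", 100_000)])
        gene = GeneModel("g1", "chr1", "+", 10_000, 30_000)
        peaks = {
            (m, tp): PeakSet(m, tp, [])
            for m in ("JMJD2B", "H3K9me3", "H3K36me3")
            for tp in TPS
        }
        status = build_mark_status(
            [gene], {"g1": promoter_window(gene, sizes)}, {"g1": gene_body(gene)}, peaks
        )
        assert not status.frame.to_numpy().any()

    def test_missing_peakset_is_error(self):
        sizes = ChromSizes([("chr1", 100_000)])
        gene = GeneModel("g1", "chr1", "+", 10_000, 30_000)
        with pytest.raises(ValueError, match="missing peak set"):
            build_mark_status(
                [gene], {"g1": promoter_window(gene, sizes)}, {"g1": gene_body(gene)}, {}
            )

    def test_planted_occupancy_recovered_exactly(self, small_study):
        from tscepi.regions import PromoterParams

        sizes = small_study.sizes
        prom = {
            g.gene_id: promoter_window(g, sizes, PromoterParams())
            for g in small_study.genes
        }
        body = {g.gene_id: gene_body(g) for g in small_study.genes}
        status = build_mark_status(small_study.genes, prom, body, small_study.peaks)
        truth = small_study.truth.mark_status
        assert status.frame[truth.columns].equals(truth)


class TestStates:
    def test_state_code_naming_convention(self):
        assert state_code(True, True, False) == "J+K9+K36-"
        assert state_code(False, False, False) == "J-K9-K36-"

    def test_all_eight_states_distinct(self):
        codes = {
            state_code(j, k9, k36)
            for j, k9, k36 in itertools.product([True, False], repeat=3)
        }
        assert len(codes) == 8
        assert codes == set(ALL_STATES)

    def test_classify_state_reads_correct_compartments(self):
        status = make_status(
            {"g1": {("JMJD2B", "promoter", "D0"): True, ("H3K9me3", "promoter", "D0"): True}}
        )
        assert classify_state(status, "g1", "D0") == "J+K9+K36-"

    def test_state_tallies_partition_universe(self, small_study):
        status = MarkStatusTable(small_study.truth.mark_status)
        states = state_table(status, "D0")
        assert states.value_counts().sum() == len(small_study.genes)
        assert set(states.unique()) <= set(ALL_STATES)


class TestDynamics:
    def test_gain_loss_definitions(self):
        assert phase_label(False, True) == "gain"
        assert phase_label(True, False) == "loss"
        assert phase_label(True, True) == "persistent_present"
        assert phase_label(False, False) == "persistent_absent"

    def test_all_eight_trajectories_enumerate_consistently(self):
        """Exhaustive oracle: recompute each phase label from the definition."""
        for presence in itertools.product([False, True], repeat=3):
            lab = dynamics_from_presence(presence)
            assert lab.trajectory == "".join("P" if p else "A" for p in presence)
            for k in range(2):
                before, after = presence[k], presence[k + 1]
                expected = (
                    "gain"
                    if (not before and after)
                    else "loss"
                    if (before and not after)
                    else "persistent_present"
                    if before
                    else "persistent_absent"
                )
                assert lab.phases[k] == expected

    def test_classify_dynamics_from_status(self):
        status = make_status(
            {
                "g1": {
                    ("H3K9me3", "promoter", "D2"): True,
                    ("H3K9me3", "promoter", "D6"): True,
                }
            }
        )
        lab = classify_dynamics(status, "g1", "H3K9me3", "promoter")
        assert lab.trajectory == "APP"
        assert lab.phases == ("gain", "persistent_present")


class TestDegDynamicsCrosstab:
    def _degs(self, directions):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(directions))],
                "comparison": "D0->D2",
                "fold": 2.0,
                "direction": directions,
            }
        )

    def _dyn(self, phase1_labels):
        trajs = {"gain": "AP", "loss": "PA", "persistent_present": "PP", "persistent_absent": "AA"}
        return pd.DataFrame(
            {
                "trajectory": [trajs[l] + "P" for l in phase1_labels],
                "phase1": phase1_labels,
                "phase2": ["persistent_present"] * len(phase1_labels),
            },
            index=[f"g{i}" for i in range(len(phase1_labels))],
        )

    def test_negative_correlation_definition(self):
        degs = self._degs(["up", "down", "down", "up"])
        dyn = self._dyn(["loss", "loss", "gain", "gain"])
        ct = deg_dynamics_crosstab(degs, dyn, phase=1)
        # up&loss and down&gain are negative correlation; the others are not
        assert set(ct.negative_correlation) == {"g0", "g2"}
        assert ct.counts.at["up", "loss"] == 1
        assert ct.counts.at["down", "gain"] == 1
        assert ct.counts.to_numpy().sum() == 4

    def test_reverse_second_mark_subset(self):
        degs = self._degs(["up", "up"])
        dyn = self._dyn(["loss", "loss"])
        second = self._dyn(["gain", "persistent_present"])
        ct = deg_dynamics_crosstab(degs, dyn, phase=1, second_dynamics=second)
        assert ct.reversed_second_mark == ["g0"]

    def test_missing_gene_in_dynamics_is_error(self):
        degs = self._degs(["up"])
        dyn = self._dyn(["loss"]).drop(index="g0")
        with pytest.raises(ValueError, match="missing"):
            deg_dynamics_crosstab(degs, dyn, phase=1)

    def test_planted_crosstab_matches_truth(self, small_study):
        """Crosstab over planted dynamics equals direct truth counting."""
        truth = small_study.truth
        status = MarkStatusTable(truth.mark_status)
        dyn = dynamics_table(status, "H3K9me3", "promoter")
        degs = pd.DataFrame(
            {
                "gene_id": truth.genes.index,
                "comparison": "D0->D2",
                "fold": 2.0,
                "direction": truth.genes["deg_early"],
            }
        )
        ct = deg_dynamics_crosstab(degs, dyn, phase=1)
        expected_neg = {
            gid
            for gid, row in truth.genes.iterrows()
            if (row["deg_early"] == "up" and dyn.at[gid, "phase1"] == "loss")
            or (row["deg_early"] == "down" and dyn.at[gid, "phase1"] == "gain")
        }
        assert set(ct.negative_correlation) == expected_neg


class TestAssignComplex:
    def _sets(self):
        loci = PeakSet("prom", None, [Interval("chr1", 0, 1000), Interval("chr1", 2000, 3000), Interval("chr1", 4000, 5000)])
        j = PeakSet("JMJD2B", None, [Interval("chr1", 100, 200)])
        t = PeakSet("TFAP2C", None, [Interval("chr1", 150, 250), Interval("chr1", 2100, 2200)])
        l = PeakSet("LSD1", None, [Interval("chr1", 120, 260), Interval("chr1", 2150, 2250)])
        return loci, j, t, l

    def test_categories(self):
        loci, j, t, l = self._sets()
        cats, tallies = assign_complex(loci, j, t, l)
        assert cats == ["JMJD2B-TFAP2C-LSD1", "TFAP2C-LSD1", "unbound"]
        assert sum(tallies.values()) == len(loci)

    def test_category_mapping_exhaustive(self):
        seen = {
            complex_category(j, t, l)
            for j, t, l in itertools.product([True, False], repeat=3)
        }
        assert seen == set(COMPLEX_CATEGORIES)


class TestSummarizeFractions:
    @pytest.mark.parametrize(
        "num,den,pct",
        [
            (334, 10_655, 3),
            (10_446, 14_000, 75),
            (0, 50, 0),
            (1, 8, 13),  # 12.5 rounds half away from zero
            (8_068, 13_275, 61),
            (3_192, 8_068, 40),
        ],
    )
    def test_rounding(self, num, den, pct):
        s = summarize_fractions(num, den)
        assert s.percent == pct
        assert s.ratio == pytest.approx(num / den)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            summarize_fractions(1, 0)

    def test_numerator_bounds(self):
        with pytest.raises(ValueError):
            summarize_fractions(5, 4)


class TestConservation:
    def test_fig4a_style_cascade_is_nested(self, small_study):
        """|silent & J+| = |silent & J+ & K9+| + |silent & J+ & K9-| and the
        persistent co-enriched subset is contained in the D0 subset."""
        truth = small_study.truth
        status = MarkStatusTable(truth.mark_status)
        silent = ~truth.genes["active_D0"]
        j0 = status.column("JMJD2B", "promoter", "D0")
        k90 = status.column("H3K9me3", "promoter", "D0")
        sj = silent & j0
        assert sj.sum() == (sj & k90).sum() + (sj & ~k90).sum()
        persistent = sj & k90
        for tp in TPS:
            persistent &= status.column("JMJD2B", "promoter", tp) & status.column(
                "H3K9me3", "promoter", tp
            )
        assert (persistent & ~(sj & k90)).sum() == 0
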