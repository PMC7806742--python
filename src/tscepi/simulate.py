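"""Generator of a complete toy differentiation study with planted truth.

The simulator emits everything the pipeline consumes — chromosome sizes, a
gene annotation, a 3-timepoint x 2-replicate FPKM table, per-mark/timepoint
peak sets, enhancer-mark peaks, and signal tracks — together with a
:class:`TruthTable` recording every planted label (activity, DEG direction,
mark presence, occupancy state, dynamics, complex category, per-peak region
class), so every downstream classification can be scored against ground
truth.

Planting is deterministic given the truth labels: a planted "present" cell
always yields exactly one peak fully inside the corresponding window, and
windows of distinct genes/loci never collide (gene spacing and intergenic
safe zones guarantee it). Statistical fuzziness enters only through decoy
peaks (weak q-values), replicate noise in FPKM space, and track noise — so
interval logic can be tested exactly while the zFPKM path is tested
statistically.

The study design mirrors a differentiating stem-cell culture: a bimodal
log2-FPKM mixture (an expressed mode near 2^5 FPKM and a leaky-silent mode
near 2^-4, plus an exact-zero mass of undetected genes), promoter-bound
JMJD2B/H3K9me3, gene-body H3K36me3 tracking activity, a silent-gene
JMJD2B/H3K9me3 co-enrichment cascade with a persistent core, a small
negatively-correlated DEG subset, and TFAP2C/LSD1 co-binding at active
promoters and at intergenic enhancers.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .integration import complex_category, state_code
from .regions import PromoterParams, promoter_window
from .types import (
    ChromSizes,
    ExpressionTable,
    GeneModel,
    Interval,
    PeakSet,
    SampleInfo,
    SignalTrack,
)

TIMEPOINTS = ("D0", "D2", "D6")

#: activity trajectory per scenario, as active/silent flags over (D0, D2, D6)
SCENARIO_ACTIVITY: dict[str, tuple[bool, bool, bool]] = {
    "active_stable": (True, True, True),
    "silent_stable": (False, False, False),
    "up_early": (False, True, True),
    "down_early": (True, False, False),
    "up_late": (False, False, True),
    "down_late": (True, True, False),
}


@dataclass
class SimulationConfig:
    """Study-design knobs; the defaults ARE the simulated study conditions."""

    seed: int = 0
    n_chroms: int = 2
    # large enough for n_genes at the stated length/spacing contract
    chrom_length: int = 36_000_000
    n_genes: int = 1500

    # gene placement: alternating strands, >=10 kb spacing, log-normal lengths
    gene_length_median: int = 20_000
    gene_length_log_sd: float = 0.45  # sd of ln(length)
    gene_length_min: int = 2_500
    spacing_min: int = 12_000
    spacing_max: int = 20_000
    noncoding_fraction: float = 0.15

    # expression mixture (log2-FPKM space)
    active_mean: float = 5.0
    active_sd: float = 1.5
    silent_mean: float = -4.0
    silent_sd: float = 1.0
    silent_zero_fraction: float = 0.85  # undetected (exact-0 FPKM) silent genes
    replicate_noise_sd: float = 0.25

    # activity/DEG scenario mix (fractions sum to 1; active at D0 = 0.28)
    scenario_fractions: dict = field(
        default_factory=lambda: {
            "active_stable": 0.18,
            "silent_stable": 0.62,
            "up_early": 0.06,
            "down_early": 0.06,
            "up_late": 0.04,
            "down_late": 0.04,
        }
    )

    # mark-planting proportions (echoing the co-enrichment cascade shape)
    frac_j_silent: float = 0.36  # silent genes with promoter JMJD2B at D0
    frac_k9_given_j_silent: float = 0.61  # of those, also H3K9me3+
    frac_persistent_given_co: float = 0.40  # of co-enriched, persistent D0->D6
    frac_k9_only_silent: float = 0.08  # H3K9me3+ among JMJD2B- silent genes
    frac_k36_active: float = 0.97  # gene-body H3K36me3 when active
    frac_k36_leak_silent: float = 0.05  # background H3K36me3 at silent genes
    frac_j_gain_on_activation: float = 0.9

    # negative expression/H3K9me3 correlation planting
    frac_negcorr_deg: float = 0.03  # DEGs with opposite-sign H3K9me3 transition
    frac_reverse_j_given_negcorr: float = 0.08  # of those, JMJD2B also reversed

    # co-factor complexes at D0 promoters
    active_complex_probs: dict = field(
        default_factory=lambda: {
            "JMJD2B-TFAP2C-LSD1": 0.75,
            "TFAP2C-LSD1": 0.02,
            "JMJD2B_only": 0.04,
            "TFAP2C_only": 0.02,
            "LSD1_only": 0.02,
            "unbound": 0.15,
        }
    )
    silent_j_complex_probs: dict = field(
        default_factory=lambda: {"JMJD2B-TFAP2C-LSD1": 0.25, "JMJD2B_only": 0.75}
    )
    silent_noj_tl_fraction: float = 0.08  # TFAP2C-LSD1 at JMJD2B-free silent promoters

    # enhancers and intergenic co-binding
    n_enhancers: int = 400
    enhancer_width: int = 700
    enhancer_jtl_fraction: float = 0.20  # triple-bound enhancers
    enhancer_tl_fraction: float = 0.46  # TFAP2C-LSD1-bound enhancers
    n_cobound_intergenic: int = 130  # TFAP2C-LSD1 sites in plain intergenic space

    # peaks and tracks
    peak_width_mean: float = 400.0
    peak_width_sd: float = 100.0
    peak_width_min: int = 50
    planted_q_exp_range: tuple[float, float] = (-8.0, -4.0)  # q ~ 10^U(range)
    decoy_q_exp_range: tuple[float, float] = (-4.0, -1.0)
    decoy_fraction: float = 0.3  # decoys per planted peak
    track_noise_bin: int = 1000
    track_noise_max: float = 0.3
    track_peak_height: tuple[float, float] = (3.0, 6.0)

    promoter: PromoterParams = field(default_factory=PromoterParams)

    def __post_init__(self) -> None:
        total = sum(self.scenario_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scenario fractions sum to {total}, expected 1")
        unknown = set(self.scenario_fractions) - set(SCENARIO_ACTIVITY)
        if unknown:
            raise ValueError(f"unknown scenario(s): {sorted(unknown)}")
        for name, frac in self.scenario_fractions.items():
            if not (0 <= frac <= 1):
                raise ValueError(f"scenario fraction {name}={frac} outside [0,1]")

    @property
    def frac_active_d0(self) -> float:
        return sum(
            f
            for name, f in self.scenario_fractions.items()
            if SCENARIO_ACTIVITY[name][0]
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["promoter"] = {"upstream": self.promoter.upstream, "downstream": self.promoter.downstream}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "promoter" in d and isinstance(d["promoter"], dict):
            d["promoter"] = PromoterParams(**d["promoter"])
        if "planted_q_exp_range" in d:
            d["planted_q_exp_range"] = tuple(d["planted_q_exp_range"])
        if "decoy_q_exp_range" in d:
            d["decoy_q_exp_range"] = tuple(d["decoy_q_exp_range"])
        if "track_peak_height" in d:
            d["track_peak_height"] = tuple(d["track_peak_height"])
        return cls(**d)


@dataclass
class TruthTable:
    """Planted ground truth for every downstream classification."""

    genes: pd.DataFrame  # per-gene labels (activity, DEG, complex, scenario...)
    mark_status: pd.DataFrame  # genes x (mark, region, timepoint) booleans
    peak_classes: pd.DataFrame  # per emitted peak: factor/timepoint/span/class
    enhancers: list[Interval]

    def activity(self) -> pd.DataFrame:
        return self.genes[[f"active_{tp}" for tp in TIMEPOINTS]].rename(
            columns={f"active_{tp}": tp for tp in TIMEPOINTS}
        )

    def state(self, timepoint: str) -> pd.Series:
        j = self.mark_status[("JMJD2B", "promoter", timepoint)]
        k9 = self.mark_status[("H3K9me3", "promoter", timepoint)]
        k36 = self.mark_status[("H3K36me3", "gene_body", timepoint)]
        return pd.Series(
            [state_code(a, b, c) for a, b, c in zip(j, k9, k36)],
            index=self.genes.index,
        )

    def validate(self) -> None:
        """Internal-consistency checks (complex category vs planted presence;
        boolean frames complete)."""
        if self.mark_status.isna().any().any():
            raise AssertionError("truth mark status has missing cells")
        j0 = self.mark_status[("JMJD2B", "promoter", "D0")]
        for gene_id, row in self.genes.iterrows():
            cat = row["complex_category"]
            want_j = "JMJD2B" in cat
            if bool(j0[gene_id]) != want_j:
                raise AssertionError(
                    f"{gene_id}: complex {cat} inconsistent with planted JMJD2B@D0"
                )
            if (row["tfap2c_bound"] != ("TFAP2C" in cat)) or (
                row["lsd1_bound"] != ("LSD1" in cat)
            ):
                raise AssertionError(f"{gene_id}: complex {cat} inconsistent with T/L")


@dataclass
class Study:
    """A complete simulated study, in memory."""

    config: SimulationConfig
    sizes: ChromSizes
    genes: list[GeneModel]
    expression: ExpressionTable
    peaks: dict[tuple[str, str | None], PeakSet]
    tracks: dict[str, SignalTrack]
    truth: TruthTable


# ------------------------------------------------------------------- genome

def simulate_genome(config: SimulationConfig) -> tuple[ChromSizes, list[GeneModel]]:
    """Place genes sequentially with >=10 kb spacing on alternating strands.

    Gene lengths are log-normal (median ``gene_length_median``); chromosomes
    are filled left to right with an equal per-chromosome quota. Raises if
    the genome cannot hold the requested gene count.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sizes = ChromSizes(
        (f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)
    )
    quota = -(-config.n_genes // config.n_chroms)  # ceil
    margin = config.promoter.upstream + 1000  # promoter + flank headroom
    genes: list[GeneModel] = []
    g = 0
    for chrom in sizes:
        pos = 10_000
        placed = 0
        while placed < quota and g < config.n_genes:
            length = int(
                np.exp(rng.normal(np.log(config.gene_length_median), config.gene_length_log_sd))
            )
            length = max(length, config.gene_length_min)
            if pos + length + margin > config.chrom_length:
                break
            strand = "+" if g % 2 == 0 else "-"
            biotype = (
                "noncoding" if rng.random() < config.noncoding_fraction else "coding"
            )
            genes.append(
                GeneModel(
                    gene_id=f"G{g + 1:04d}",
                    chrom=chrom,
                    strand=strand,
                    start=pos,
                    end=pos + length,
                    biotype=biotype,
                )
            )
            pos += length + int(rng.integers(config.spacing_min, config.spacing_max + 1))
            placed += 1
            g += 1
    if g < config.n_genes:
        raise ValueError(
            f"genome too small: placed {g}/{config.n_genes} genes "
            f"(chrom_length={config.chrom_length}, n_chroms={config.n_chroms})"
        )
    return sizes, genes


# ------------------------------------------------------------- truth planting

def _sample_category(rng: np.random.Generator, probs: dict[str, float]) -> str:
    # sorted so planting is invariant to dict key order (config round-trips
    # through YAML, which sorts keys)
    names = sorted(probs)
    p = np.array([probs[n] for n in names], dtype=float)
    p = p / p.sum()
    return names[int(rng.choice(len(names), p=p))]


def _traj_with_loss(rng: np.random.Generator) -> tuple[bool, bool, bool]:
    """Present at D0, lost at D2 or D6 (equal odds)."""
    return (True, False, False) if rng.random() < 0.5 else (True, True, False)


def plant_truth(config: SimulationConfig, genes: list[GeneModel]) -> TruthTable:
    """Sample per-gene scenario labels and derive a fully consistent truth
    table of activity, DEG directions, mark trajectories and complex calls."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    names = sorted(config.scenario_fractions)
    probs = np.array([config.scenario_fractions[n] for n in names])
    gene_ids = [g.gene_id for g in genes]
    n = len(genes)
    scen = [names[i] for i in rng.choice(len(names), size=n, p=probs / probs.sum())]

    rows = []
    mark_cols: dict[tuple[str, str, str], list[bool]] = {
        (m, r, tp): []
        for m, r in (("JMJD2B", "promoter"), ("H3K9me3", "promoter"), ("H3K36me3", "gene_body"))
        for tp in TIMEPOINTS
    }

    for gid, scenario in zip(gene_ids, scen):
        act = SCENARIO_ACTIVITY[scenario]
        deg_early = (
            "up" if (not act[0] and act[1]) else "down" if (act[0] and not act[1]) else "unchanged"
        )
        deg_late = (
            "up" if (not act[1] and act[2]) else "down" if (act[1] and not act[2]) else "unchanged"
        )
        is_deg = scenario not in ("active_stable", "silent_stable")
        negcorr = bool(is_deg and rng.random() < config.frac_negcorr_deg)
        reverse_j = bool(negcorr and rng.random() < config.frac_reverse_j_given_negcorr)

        # ---- JMJD2B promoter trajectory + D0 complex category
        if act[0]:  # active at D0: category drawn from the active mix
            cat = _sample_category(rng, config.active_complex_probs)
            j0 = "JMJD2B" in cat
        else:  # silent at D0: the co-enrichment cascade decides JMJD2B
            j0 = rng.random() < config.frac_j_silent
            if j0:
                cat = _sample_category(rng, config.silent_j_complex_probs)
            else:
                cat = (
                    "TFAP2C-LSD1"
                    if rng.random() < config.silent_noj_tl_fraction
                    else "unbound"
                )

        k9_0 = False
        persistent_co = False
        if scenario == "silent_stable":
            if j0:
                k9_0 = rng.random() < config.frac_k9_given_j_silent
                if k9_0:
                    persistent_co = rng.random() < config.frac_persistent_given_co
                    j_traj = (True, True, True) if persistent_co else _traj_with_loss(rng)
                    k9_traj = (True, True, True)
                else:
                    j_traj = (True, True, True) if rng.random() < 0.5 else _traj_with_loss(rng)
                    k9_traj = (False, False, False)
            else:
                j_traj = (False, False, False)
                k9_traj = (
                    (True, True, True)
                    if rng.random() < config.frac_k9_only_silent
                    else (False, False, False)
                )
        elif scenario == "active_stable":
            j_traj = (j0, j0, j0)
            k9_traj = (False, False, False)
        else:  # DEG scenarios: marks follow (or, for negcorr, oppose) activity
            if negcorr:
                # H3K9me3 transitions opposite to expression in the DEG phase
                k9_traj = tuple(not a for a in act)  # loss on activation, gain on silencing
            else:
                k9_traj = (False, False, False)
            if reverse_j:
                j_traj = act  # JMJD2B transitions with expression, opposite to K9
            elif act[0]:
                if j0:
                    stays = rng.random() >= 0.7  # most down-DEGs lose promoter JMJD2B
                    j_traj = (True, True, True) if stays else act
                else:
                    j_traj = (False, False, False)
            else:
                gains = rng.random() < config.frac_j_gain_on_activation
                j_traj = act if gains else (False, False, False)
                j_traj = (j0, j_traj[1], j_traj[2])

        # ---- H3K36me3 follows transcription over gene bodies
        if rng.random() < config.frac_k36_active:
            k36_traj = act
        else:
            k36_traj = (False, False, False)
        if scenario == "silent_stable" and rng.random() < config.frac_k36_leak_silent:
            k36_traj = (True, True, True)

        # category string must match planted D0 presence for J (and defines T/L)
        if ("JMJD2B" in cat) != j_traj[0]:
            # J trajectory may start absent for reverse-J up-DEGs; fix category
            cat = complex_category(j_traj[0], "TFAP2C" in cat, "LSD1" in cat)

        for tp_i, tp in enumerate(TIMEPOINTS):
            mark_cols[("JMJD2B", "promoter", tp)].append(bool(j_traj[tp_i]))
            mark_cols[("H3K9me3", "promoter", tp)].append(bool(k9_traj[tp_i]))
            mark_cols[("H3K36me3", "gene_body", tp)].append(bool(k36_traj[tp_i]))

        rows.append(
            {
                "gene_id": gid,
                "scenario": scenario,
                "active_D0": act[0],
                "active_D2": act[1],
                "active_D6": act[2],
                "deg_early": deg_early,
                "deg_late": deg_late,
                "negcorr": negcorr,
                "reverse_j": reverse_j,
                "persistent_co": persistent_co,
                "complex_category": cat,
                "tfap2c_bound": "TFAP2C" in cat,
                "lsd1_bound": "LSD1" in cat,
                "undetected_when_silent": bool(rng.random() < config.silent_zero_fraction),
            }
        )

    genes_df = pd.DataFrame(rows).set_index("gene_id")
    mark_df = pd.DataFrame(mark_cols, index=genes_df.index)
    mark_df.columns = pd.MultiIndex.from_tuples(
        mark_df.columns, names=["mark", "region", "timepoint"]
    )
    return TruthTable(
        genes=genes_df, mark_status=mark_df, peak_classes=pd.DataFrame(), enhancers=[]
    )


# --------------------------------------------------------------- expression

def simulate_expression(
    truth: TruthTable, config: SimulationConfig
) -> ExpressionTable:
    """Draw the FPKM table from the planted activity states.

    Each gene keeps one expressed level and one leaky-silent level across the
    course, so planted DEG fold changes come from the activity switch itself
    (shift >> log2(1.5) + 3*replicate_noise_sd by construction) while stable
    genes only wobble by replicate noise. Undetected silent genes are exact 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    gene_ids = list(truth.genes.index)
    n = len(gene_ids)
    lvl_active = rng.normal(config.active_mean, config.active_sd, size=n)
    lvl_silent = rng.normal(config.silent_mean, config.silent_sd, size=n)
    # enforce the DEG recoverability margin between the two per-gene levels
    margin = np.log2(1.5) + 3 * config.replicate_noise_sd
    lvl_silent = np.minimum(lvl_silent, lvl_active - margin)

    samples = [
        SampleInfo(f"{tp}_r{rep}", tp, rep) for tp in TIMEPOINTS for rep in (1, 2)
    ]
    values = np.zeros((n, len(samples)))
    activity = truth.activity().to_numpy()
    undetected = truth.genes["undetected_when_silent"].to_numpy()
    for j, s in enumerate(samples):
        tp_i = TIMEPOINTS.index(s.timepoint)
        active = activity[:, tp_i]
        base = np.where(active, lvl_active, lvl_silent)
        noise = rng.normal(0.0, config.replicate_noise_sd, size=n)
        fpkm = np.power(2.0, base + noise)
        fpkm = np.where(~active & undetected, 0.0, fpkm)
        values[:, j] = fpkm
    frame = pd.DataFrame(
        values, index=pd.Index(gene_ids, name="gene_id"), columns=[s.label for s in samples]
    )
    return ExpressionTable(frame, samples)


# ----------------------------------------------------------- peaks & tracks

def _body_safe_window(gene: GeneModel, prom: Interval) -> tuple[int, int]:
    """Gene-body span minus the promoter window (plus a 100 bp buffer), so a
    body peak can never be classed as promoter."""
    if gene.strand == "+":
        lo = max(gene.start, prom.end + 100)
        hi = gene.end
    else:
        lo = gene.start
        hi = min(gene.end, prom.start - 100)
    return lo, hi


def _place_peak(
    rng: np.random.Generator, lo: int, hi: int, config: SimulationConfig
) -> tuple[int, int]:
    """One peak uniformly inside [lo, hi), width ~ N(mean, sd) truncated to
    the window (truncation logged by the caller when it matters)."""
    span = hi - lo
    width = int(round(rng.normal(config.peak_width_mean, config.peak_width_sd)))
    width = max(config.peak_width_min, min(width, span))
    start = int(rng.integers(lo, hi - width + 1))
    return start, start + width


def _place_cobound_peak(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    anchor: tuple[int, int],
    config: SimulationConfig,
) -> tuple[int, int]:
    """A peak overlapping *anchor* by >=50 bp, kept inside [lo, hi).

    Co-bound factors share a footprint in vivo; placing partners anchored on
    each other (rather than independently in the same window) is what makes
    the planted co-binding visible to peak-to-peak overlap statistics."""
    span = hi - lo
    width = int(round(rng.normal(config.peak_width_mean, config.peak_width_sd)))
    width = max(config.peak_width_min, min(width, span))
    a_s, a_e = anchor
    pad = min(50, (a_e - a_s) // 2, width // 2)
    s_lo = max(lo, a_s - width + pad)
    s_hi = min(hi - width, a_e - pad)
    if s_hi < s_lo:  # window too tight to honour the overlap pad; sit on anchor
        start = min(max(lo, a_s), hi - width)
    else:
        start = int(rng.integers(s_lo, s_hi + 1))
    return start, start + width


def simulate_peaks_and_tracks(
    truth: TruthTable,
    genes: list[GeneModel],
    sizes: ChromSizes,
    config: SimulationConfig,
) -> tuple[dict[tuple[str, str | None], PeakSet], dict[str, SignalTrack]]:
    """Emit peak sets realising the planted mark status, enhancer loci with
    their H3K4me1/H3K27ac pairs, TFAP2C/LSD1 sets, decoy background peaks,
    and peak-shaped signal tracks. Fills ``truth.peak_classes`` and
    ``truth.enhancers`` in place."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    gene_by_id = {g.gene_id: g for g in genes}
    promoters = {
        g.gene_id: promoter_window(g, sizes, config.promoter) for g in genes
    }

    peak_rows: list[dict] = []
    peaks: dict[tuple[str, str | None], list[Interval]] = {}

    def emit(
        factor: str,
        timepoint: str | None,
        chrom: str,
        start: int,
        end: int,
        cls: str,
        decoy: bool,
    ) -> None:
        lo_e, hi_e = (
            config.decoy_q_exp_range if decoy else config.planted_q_exp_range
        )
        q = 10.0 ** rng.uniform(lo_e, hi_e)
        score = float(rng.uniform(*config.track_peak_height)) * 2.0
        key = (factor, timepoint)
        peaks.setdefault(key, [])
        name = f"{factor}_{timepoint or 'NA'}_{len(peaks[key]) + 1}"
        peaks[key].append(
            Interval(chrom, start, end, name=name, score=score, qvalue=q)
        )
        peak_rows.append(
            {
                "factor": factor,
                "timepoint": timepoint if timepoint is not None else "NA",
                "chrom": chrom,
                "start": start,
                "end": end,
                "planted_class": cls,
                "is_decoy": decoy,
            }
        )

    # ---- planted gene-anchored peaks (marks at promoters / gene bodies)
    j_d0_span: dict[str, tuple[int, int]] = {}
    for gid in truth.genes.index:
        gene = gene_by_id[gid]
        prom = promoters[gid]
        body_lo, body_hi = _body_safe_window(gene, prom)
        for (mark, region, tp), present in truth.mark_status.loc[gid].items():
            if not present:
                continue
            if region == "promoter":
                lo, hi = prom.start, prom.end
                cls = "promoter"
            else:
                lo, hi = body_lo, body_hi
                cls = "gene_body"
                if hi - lo < config.peak_width_min:  # degenerate short body
                    lo, hi = gene.start, gene.end
            s, e = _place_peak(rng, lo, hi, config)
            if mark == "JMJD2B" and region == "promoter" and tp == "D0":
                j_d0_span[gid] = (s, e)
            emit(mark, tp, gene.chrom, s, e, cls, decoy=False)

    # ---- TFAP2C / LSD1 at promoters per complex category (single datasets).
    # Co-bound partners are anchored on each other so planted complexes are
    # visible both at the promoter-window level and peak-to-peak.
    for gid, row in truth.genes.iterrows():
        prom = promoters[gid]
        anchor = j_d0_span.get(gid)
        t_span: tuple[int, int] | None = None
        if row["tfap2c_bound"]:
            if anchor is not None:
                s, e = _place_cobound_peak(rng, prom.start, prom.end, anchor, config)
            else:
                s, e = _place_peak(rng, prom.start, prom.end, config)
            t_span = (s, e)
            emit("TFAP2C", None, prom.chrom, s, e, "promoter", decoy=False)
        if row["lsd1_bound"]:
            l_anchor = anchor if anchor is not None else t_span
            if l_anchor is not None:
                s, e = _place_cobound_peak(rng, prom.start, prom.end, l_anchor, config)
            else:
                s, e = _place_peak(rng, prom.start, prom.end, config)
            emit("LSD1", None, prom.chrom, s, e, "promoter", decoy=False)

    # ---- intergenic safe zones: gaps between genes, clear of promoters/flanks
    zones: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    zone_margin = config.promoter.upstream + 500
    for chrom, glist in by_chrom.items():
        glist = sorted(glist, key=lambda g: g.start)
        bounds = [(0, glist[0].start)]
        bounds += [
            (glist[i].end, glist[i + 1].start) for i in range(len(glist) - 1)
        ]
        bounds.append((glist[-1].end, sizes[chrom]))
        for lo, hi in bounds:
            zlo, zhi = lo + zone_margin, hi - zone_margin
            if zhi - zlo >= config.enhancer_width + 400:
                zones.append((chrom, zlo, zhi))
    rng.shuffle(zones)
    if len(zones) < config.n_enhancers:
        raise ValueError(
            f"only {len(zones)} intergenic zones for {config.n_enhancers} enhancers"
        )

    # ---- enhancer loci: overlapping H3K4me1/H3K27ac pairs outside promoters
    enhancers: list[Interval] = []
    for i in range(config.n_enhancers):
        chrom, zlo, zhi = zones[i]
        s = zlo + 150
        e = s + config.enhancer_width
        enhancers.append(Interval(chrom, s, e, name=f"enh_{i + 1}"))
        emit("H3K4me1", None, chrom, s - 150, e, "enhancer", decoy=False)
        emit("H3K27ac", None, chrom, s, e + 150, "enhancer", decoy=False)
        u = rng.random()
        if u < config.enhancer_jtl_fraction:
            bound = ("JMJD2B", "TFAP2C", "LSD1")
        elif u < config.enhancer_jtl_fraction + config.enhancer_tl_fraction:
            bound = ("TFAP2C", "LSD1")
        else:
            bound = ()
        locus_anchor: tuple[int, int] | None = None
        for factor in bound:
            if locus_anchor is None:
                ps, pe = _place_peak(rng, s, e, config)
                locus_anchor = (ps, pe)
            else:
                ps, pe = _place_cobound_peak(rng, s, e, locus_anchor, config)
            tp = "D0" if factor == "JMJD2B" else None
            emit(factor, tp, chrom, ps, pe, "enhancer", decoy=False)

    # ---- decoy slot pool: deeper into the remaining zone space
    slots: list[tuple[str, int, int]] = []
    for zi, (chrom, zlo, zhi) in enumerate(zones):
        cursor = zlo + (config.enhancer_width + 1200 if zi < config.n_enhancers else 200)
        while cursor + 600 <= zhi:
            slots.append((chrom, cursor, cursor + 500))
            cursor += 800
    rng.shuffle(slots)
    slot_iter = iter(slots)

    # ---- TFAP2C-LSD1 co-bound sites in plain intergenic space ("other")
    for _ in range(config.n_cobound_intergenic):
        try:
            chrom, lo, hi = next(slot_iter)
        except StopIteration:
            break
        s1, e1 = _place_peak(rng, lo, hi, config)
        emit("TFAP2C", None, chrom, s1, e1, "other", decoy=False)
        # LSD1 peak forced to overlap the TFAP2C one
        s2 = max(lo, s1 - 100)
        e2 = min(hi, e1 + 100)
        emit("LSD1", None, chrom, s2, e2, "other", decoy=False)

    # ---- decoys: weak-q background peaks per factor/timepoint
    planted_counts = {
        key: len(ivs) for key, ivs in peaks.items()
    }
    for key in sorted(planted_counts, key=lambda k: (k[0], k[1] or "")):
        n_decoys = int(round(config.decoy_fraction * planted_counts[key]))
        for _ in range(n_decoys):
            try:
                chrom, lo, hi = next(slot_iter)
            except StopIteration:
                break
            s, e = _place_peak(rng, lo, hi, config)
            emit(key[0], key[1], chrom, s, e, "other", decoy=True)

    peaksets = {
        key: PeakSet(key[0], key[1], ivs) for key, ivs in peaks.items()
    }
    # guarantee every declared mark x timepoint exists, even if empty
    for mark in ("JMJD2B", "H3K9me3", "H3K36me3"):
        for tp in TIMEPOINTS:
            peaksets.setdefault((mark, tp), PeakSet(mark, tp, []))
    for factor in ("TFAP2C", "LSD1", "H3K4me1", "H3K27ac"):
        peaksets.setdefault((factor, None), PeakSet(factor, None, []))

    truth.peak_classes = pd.DataFrame(peak_rows)
    truth.enhancers = enhancers

    # ---- signal tracks: peak-shaped steps + low uniform per-bin noise
    tracks: dict[str, SignalTrack] = {}
    for mark in ("JMJD2B", "H3K9me3", "H3K36me3"):
        tracks[f"{mark}_D0"] = _build_track(
            peaksets[(mark, "D0")], sizes, config, rng
        )
    return peaksets, tracks


def _build_track(
    peaks: PeakSet,
    sizes: ChromSizes,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SignalTrack:
    """Step-function track: each peak adds a rectangular bump of height
    score/2 on top of U(0, noise_max) noise drawn per fixed-width bin."""
    steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    by_chrom = {}
    for iv in peaks:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, length in sizes.items():
        bin_edges = np.arange(0, length + config.track_noise_bin, config.track_noise_bin)
        bin_edges[-1] = length
        bin_edges = np.unique(bin_edges)
        noise = rng.uniform(0.0, config.track_noise_max, size=len(bin_edges) - 1)
        ivs = by_chrom.get(chrom, [])
        bumps = np.array(
            [[iv.start, iv.end, (iv.score or 6.0) / 2.0] for iv in ivs]
        ).reshape(-1, 3)
        cuts = np.unique(
            np.concatenate([bin_edges, bumps[:, 0], bumps[:, 1]])
        ).astype(np.int64)
        cuts = cuts[(cuts >= 0) & (cuts <= length)]
        seg_s = cuts[:-1]
        seg_e = cuts[1:]
        # peak contribution per segment via difference array over cut indices
        delta = np.zeros(len(cuts) + 1)
        left = np.searchsorted(cuts, bumps[:, 0].astype(np.int64))
        right = np.searchsorted(cuts, bumps[:, 1].astype(np.int64))
        np.add.at(delta, left, bumps[:, 2])
        np.add.at(delta, right, -bumps[:, 2])
        seg_peak = np.cumsum(delta)[: len(seg_s)]
        bin_idx = np.minimum(seg_s // config.track_noise_bin, len(noise) - 1)
        values = noise[bin_idx] + seg_peak
        steps[chrom] = (seg_s, seg_e, values)
    return SignalTrack(steps)


# -------------------------------------------------------------- orchestration

def simulate_study(config: SimulationConfig) -> Study:
    """Run the full generator; deterministic (byte-identical files) per seed."""
    sizes, genes = simulate_genome(config)
    truth = plant_truth(config, genes)
    expression = simulate_expression(truth, config)
    peaks, tracks = simulate_peaks_and_tracks(truth, genes, sizes, config)
    truth.validate()
    return Study(
        config=config,
        sizes=sizes,
        genes=genes,
        expression=expression,
        peaks=peaks,
        tracks=tracks,
        truth=truth,
    )


def write_study(study: Study, outdir: str | Path) -> None:
    """Write the self-contained study directory (all plain text)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_chrom_sizes(study.sizes, out / "chrom.sizes")
    tio.write_gene_models_bed12(study.genes, out / "genes.bed12")
    tio.write_fpkm_table(study.expression, out / "fpkm.tsv")
    for (factor, tp), ps in sorted(
        study.peaks.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")
    ):
        suffix = f"_{tp}" if tp is not None else ""
        tio.write_peaks(ps, out / f"{factor}{suffix}.narrowPeak", format="narrowPeak")
    for name, track in sorted(study.tracks.items()):
        tio.write_bedgraph(track, out / f"{name}.bedgraph")
    study.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    long = study.truth.mark_status.stack([0, 1, 2], future_stack=True).reset_index()
    long.columns = ["gene_id", "mark", "region", "timepoint", "present"]
    long.to_csv(out / "truth_marks.tsv", sep="\t", index=False)
    study.truth.peak_classes.to_csv(out / "truth_peaks.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(study.config.to_dict(), fh, sort_keys=True)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))
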