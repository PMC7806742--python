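"""Gene-level mark status, co-occupancy states, dynamics and complex calls.

This is the inferential core: every gene is scored for presence/absence of
each chromatin mark in its reading compartment (JMJD2B and H3K9me3 at the
promoter, H3K36me3 over the gene body) at each timepoint; the three booleans
define one of eight occupancy states (e.g. "J+K9+K36-"); presence across the
D0 -> D2 -> D6 course defines a trajectory whose consecutive-pair labels are
gain (absence -> presence), loss (presence -> absence), or persistence; and
promoter co-binding of JMJD2B/TFAP2C/LSD1 defines the co-factor complex
category of each locus.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import overlap_any
from .types import ChromSizes, GeneModel, Interval, PeakSet

#: Which compartment each mark is read in (Fig-style convention; configurable).
DEFAULT_MARK_REGIONS: dict[str, str] = {
    "JMJD2B": "promoter",
    "H3K9me3": "promoter",
    "H3K36me3": "gene_body",
}

PHASE_LABELS = ("gain", "loss", "persistent_present", "persistent_absent")

COMPLEX_CATEGORIES = (
    "JMJD2B-TFAP2C-LSD1",
    "TFAP2C-LSD1",
    "JMJD2B-TFAP2C",
    "JMJD2B-LSD1",
    "JMJD2B_only",
    "TFAP2C_only",
    "LSD1_only",
    "unbound",
)


class MarkStatusTable:
    """Per (gene, mark, region, timepoint) presence/absence.

    Backed by a genes x (mark, region, timepoint) boolean frame; complete by
    construction (every declared cell filled, no missing values).
    """

    def __init__(self, frame: pd.DataFrame):
        if not isinstance(frame.columns, pd.MultiIndex) or frame.columns.nlevels != 3:
            raise ValueError("expected (mark, region, timepoint) column MultiIndex")
        if frame.isna().any().any():
            raise ValueError("mark status table must be complete (no missing cells)")
        self.frame = frame.astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def timepoints(self) -> list[str]:
        seen: list[str] = []
        for _, _, tp in self.frame.columns:
            if tp not in seen:
                seen.append(tp)
        return seen

    def marks(self) -> list[tuple[str, str]]:
        seen: list[tuple[str, str]] = []
        for mark, region, _ in self.frame.columns:
            if (mark, region) not in seen:
                seen.append((mark, region))
        return seen

    def present(self, gene: str, mark: str, region: str, timepoint: str) -> bool:
        return bool(self.frame.at[gene, (mark, region, timepoint)])

    def column(self, mark: str, region: str, timepoint: str) -> pd.Series:
        return self.frame[(mark, region, timepoint)]

    def to_long_frame(self) -> pd.DataFrame:
        long = self.frame.stack([0, 1, 2], future_stack=True).reset_index()
        long.columns = ["gene_id", "mark", "region", "timepoint", "present"]
        return long


def build_mark_status(
    genes: Sequence[GeneModel],
    promoters: Mapping[str, Interval],
    bodies: Mapping[str, Interval],
    peaks: Mapping[tuple[str, str], PeakSet],
    mark_regions: Mapping[str, str] = DEFAULT_MARK_REGIONS,
    timepoints: Sequence[str] = ("D0", "D2", "D6"),
) -> MarkStatusTable:
    """Score every gene for >=1 bp overlap of its reading region with each
    mark's peak set at each timepoint.

    *peaks* is keyed by ``(mark, timepoint)``; every declared combination must
    be present (an empty PeakSet is a legitimate "no peaks" statement).
    """
    gene_ids = [g.gene_id for g in genes]
    for g in genes:
        if g.gene_id not in promoters:
            raise ValueError(f"gene {g.gene_id} has no derivable promoter window")
        if g.gene_id not in bodies:
            raise ValueError(f"gene {g.gene_id} has no gene-body interval")
    region_query = {
        "promoter": PeakSet("promoter", None, [promoters[g] for g in gene_ids]),
        "gene_body": PeakSet("gene_body", None, [bodies[g] for g in gene_ids]),
    }
    columns = {}
    for mark, region in mark_regions.items():
        if region not in region_query:
            raise ValueError(f"mark {mark!r}: unknown region {region!r}")
        for tp in timepoints:
            if (mark, tp) not in peaks:
                raise ValueError(f"missing peak set for ({mark!r}, {tp!r})")
            flags, _ = overlap_any(region_query[region], peaks[(mark, tp)])
            columns[(mark, region, tp)] = flags
    frame = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    frame.columns = pd.MultiIndex.from_tuples(
        frame.columns, names=["mark", "region", "timepoint"]
    )
    return MarkStatusTable(frame)


# ------------------------------------------------------------------- states

def state_code(j: bool, k9: bool, k36: bool) -> str:
    """3-bit occupancy code, e.g. (True, True, False) -> "J+K9+K36-"."""
    return (
        f"J{'+' if j else '-'}"
        f"K9{'+' if k9 else '-'}"
        f"K36{'+' if k36 else '-'}"
    )


ALL_STATES = tuple(
    state_code(j, k9, k36)
    for j in (True, False)
    for k9 in (True, False)
    for k36 in (True, False)
)


def classify_state(
    status: MarkStatusTable,
    gene: str,
    timepoint: str,
    mark_regions: Mapping[str, str] = DEFAULT_MARK_REGIONS,
) -> str:
    """Occupancy state of one gene at one timepoint."""
    j = status.present(gene, "JMJD2B", mark_regions["JMJD2B"], timepoint)
    k9 = status.present(gene, "H3K9me3", mark_regions["H3K9me3"], timepoint)
    k36 = status.present(gene, "H3K36me3", mark_regions["H3K36me3"], timepoint)
    return state_code(j, k9, k36)


def state_table(
    status: MarkStatusTable,
    timepoint: str,
    mark_regions: Mapping[str, str] = DEFAULT_MARK_REGIONS,
) -> pd.Series:
    """Occupancy state per gene (exhaustive, exclusive partition)."""
    j = status.column("JMJD2B", mark_regions["JMJD2B"], timepoint)
    k9 = status.column("H3K9me3", mark_regions["H3K9me3"], timepoint)
    k36 = status.column("H3K36me3", mark_regions["H3K36me3"], timepoint)
    codes = [
        state_code(a, b, c)
        for a, b, c in zip(j.to_numpy(), k9.to_numpy(), k36.to_numpy())
    ]
    return pd.Series(codes, index=status.frame.index, name=f"state_{timepoint}")


# ----------------------------------------------------------------- dynamics

@dataclass(frozen=True)
class DynamicsLabel:
    """Presence trajectory over the timecourse plus per-phase transition labels."""

    trajectory: str  # e.g. "PPA" over (D0, D2, D6)
    phases: tuple[str, ...]  # one label per consecutive timepoint pair


def phase_label(before: bool, after: bool) -> str:
    if before and after:
        return "persistent_present"
    if not before and not after:
        return "persistent_absent"
    if not before and after:
        return "gain"
    return "loss"


def dynamics_from_presence(presence: Sequence[bool]) -> DynamicsLabel:
    traj = "".join("P" if p else "A" for p in presence)
    phases = tuple(
        phase_label(presence[i], presence[i + 1]) for i in range(len(presence) - 1)
    )
    return DynamicsLabel(traj, phases)


def classify_dynamics(
    status: MarkStatusTable, gene: str, mark: str, region: str
) -> DynamicsLabel:
    """Gain/loss/persistence trajectory of one mark at one gene."""
    presence = [
        status.present(gene, mark, region, tp) for tp in status.timepoints
    ]
    return dynamics_from_presence(presence)


def dynamics_table(status: MarkStatusTable, mark: str, region: str) -> pd.DataFrame:
    """Trajectory + phase labels for every gene (columns: trajectory, phase1..)."""
    tps = status.timepoints
    presence = np.column_stack(
        [status.column(mark, region, tp).to_numpy() for tp in tps]
    )
    rows = [dynamics_from_presence(p) for p in presence]
    data = {"trajectory": [r.trajectory for r in rows]}
    for k in range(len(tps) - 1):
        data[f"phase{k + 1}"] = [r.phases[k] for r in rows]
    return pd.DataFrame(data, index=status.frame.index)


# ----------------------------------------------- DEG x dynamics cross-tab

@dataclass
class DegDynamicsCrosstab:
    """Contingency of DEG direction vs mark-phase label for one phase.

    ``negative_correlation`` is the (up & loss) | (down & gain) gene set;
    ``reversed_second_mark`` (when a second mark's dynamics are supplied) is
    the subset whose second-mark phase label is the opposite transition.
    """

    counts: pd.DataFrame
    negative_correlation: list[str]
    reversed_second_mark: list[str]


def deg_dynamics_crosstab(
    degs: pd.DataFrame,
    dynamics: pd.DataFrame,
    phase: int,
    second_dynamics: pd.DataFrame | None = None,
) -> DegDynamicsCrosstab:
    """Cross-tabulate up/down DEGs against the mark's phase labels.

    *degs* must be restricted to the comparison matching *phase* (1-based
    consecutive-pair index into the timecourse). Every DEG gene must be
    present in *dynamics* (else error).
    """
    col = f"phase{phase}"
    if col not in dynamics.columns:
        raise ValueError(f"dynamics table has no column {col!r}")
    updown = degs[degs["direction"].isin(["up", "down"])]
    missing = set(updown["gene_id"]) - set(dynamics.index)
    if missing:
        raise ValueError(f"DEG gene(s) missing from dynamics: {sorted(missing)[:5]}")
    counts = pd.DataFrame(0, index=["up", "down"], columns=list(PHASE_LABELS))
    neg: list[str] = []
    rev: list[str] = []
    for row in updown.itertuples(index=False):
        label = dynamics.at[row.gene_id, col]
        counts.at[row.direction, label] += 1
        negcorr = (row.direction == "up" and label == "loss") or (
            row.direction == "down" and label == "gain"
        )
        if negcorr:
            neg.append(row.gene_id)
            if second_dynamics is not None and row.gene_id in second_dynamics.index:
                second = second_dynamics.at[row.gene_id, col]
                opposite = "gain" if label == "loss" else "loss"
                if second == opposite:
                    rev.append(row.gene_id)
    return DegDynamicsCrosstab(counts, neg, rev)


# ------------------------------------------------------------ complex calls

def complex_category(j: bool, t: bool, l: bool) -> str:
    if j and t and l:
        return "JMJD2B-TFAP2C-LSD1"
    if t and l:
        return "TFAP2C-LSD1"
    if j and t:
        return "JMJD2B-TFAP2C"
    if j and l:
        return "JMJD2B-LSD1"
    if j:
        return "JMJD2B_only"
    if t:
        return "TFAP2C_only"
    if l:
        return "LSD1_only"
    return "unbound"


def assign_complex(
    loci: PeakSet, jmjd2b: PeakSet, tfap2c: PeakSet, lsd1: PeakSet
) -> tuple[list[str], Counter]:
    """Co-factor complex category per locus from the three >=1 bp-overlap
    booleans; tallies partition the locus set."""
    j_hit, _ = overlap_any(loci, jmjd2b)
    t_hit, _ = overlap_any(loci, tfap2c)
    l_hit, _ = overlap_any(loci, lsd1)
    cats = [
        complex_category(j, t, l)
        for j, t, l in zip(j_hit.tolist(), t_hit.tolist(), l_hit.tolist())
    ]
    tallies = Counter(cats)
    for cat in COMPLEX_CATEGORIES:
        tallies.setdefault(cat, 0)
    return cats, tallies


# ---------------------------------------------------------------- reporting

@dataclass(frozen=True)
class FractionSummary:
    numerator: int
    denominator: int
    percent: int  # nearest integer, half away from zero
    ratio: float

    def __str__(self) -> str:
        return f"{self.percent}% ({self.numerator}/{self.denominator})"


def summarize_fractions(numerator: int, denominator: int) -> FractionSummary:
    """Publication-style rounding: nearest-integer percentage (half away from zero),
    with the exact ratio retained."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must lie in [0, denominator]")
    # exact integer arithmetic: round(100*n/d) half away from zero (n, d >= 0)
    percent = (200 * numerator + denominator) // (2 * denominator)
    return FractionSummary(
        numerator=numerator,
        denominator=denominator,
        percent=int(percent),
        ratio=float(Fraction(numerator, denominator)),
    )
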