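"""Chromosome-constrained randomisation control for peak-set overlap.

Each factor peak is re-placed uniformly at random on its own chromosome with
its own length (overlaps among shuffled peaks are permitted, matching the
default behaviour of bedtools shuffle without exclusion flags). For the null,
the factor set is shuffled many times and the number of target regions
intersected is counted each time; the summary reports the maximum across
shuffles next to the observed (unshuffled) count — the familiar
"randomised control" bar of overlap figures.

Reproducibility: one parent seed; shuffle i draws from spawned substream i,
so results do not depend on execution order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ChromSizes, Interval, PeakSet


@dataclass(frozen=True)
class ShuffleParams:
    n_shuffles: int = 10_000
    seed: int = 0
    allow_self_overlap: bool = True  # uniform placement; no exclusion rule
    keep_per_shuffle_max: int = 1_000  # retain raw counts only up to this many

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not self.allow_self_overlap:
            raise NotImplementedError(
                "non-overlapping shuffle placement is not implemented"
            )


@dataclass
class ShuffleNullResult:
    factor: str
    target: str
    n_shuffles: int
    seed: int
    observed_count: int
    observed_percent: float
    null_max_count: int
    null_max_percent: float
    null_mean_percent: float
    null_p95_percent: float
    n_target: int
    per_shuffle_counts: np.ndarray | None = field(default=None, repr=False)


def _validate_for_shuffle(peaks: PeakSet, sizes: ChromSizes) -> None:
    for iv in peaks:
        if iv.chrom not in sizes:
            raise ValueError(f"peak chromosome {iv.chrom!r} not in chrom sizes")
        if len(iv) > sizes[iv.chrom]:
            raise ValueError(
                f"peak {iv.chrom}:{iv.start}-{iv.end} longer than its chromosome"
            )


def shuffle_peaks(peaks: PeakSet, sizes: ChromSizes, seed: int) -> PeakSet:
    """Uniform within-chromosome re-placement preserving each peak's
    chromosome and length (and its name/score/q metadata)."""
    _validate_for_shuffle(peaks, sizes)
    rng = np.random.default_rng(seed)
    out: list[Interval] = []
    for iv in peaks:
        length = len(iv)
        start = int(rng.integers(0, sizes[iv.chrom] - length + 1))
        out.append(
            Interval(
                iv.chrom,
                start,
                start + length,
                name=iv.name,
                score=iv.score,
                qvalue=iv.qvalue,
            )
        )
    return PeakSet(peaks.factor, peaks.timepoint, out)


def _count_targets_hit(
    shuffled: dict[str, tuple[np.ndarray, np.ndarray]],
    targets: dict[str, tuple[np.ndarray, np.ndarray]],
) -> int:
    """Number of target intervals intersected by >=1 (possibly overlapping)
    factor interval. Factor arrays need not be disjoint: sort by start and
    take the running max of ends, then a target [s, e) is hit iff some factor
    start < e has running-max end > s."""
    total = 0
    for chrom, (t_s, t_e) in targets.items():
        if chrom not in shuffled:
            continue
        f_s, f_e = shuffled[chrom]
        order = np.argsort(f_s, kind="stable")
        f_s = f_s[order]
        f_end_max = np.maximum.accumulate(f_e[order])
        idx = np.searchsorted(f_s, t_e, side="left") - 1
        idxc = np.clip(idx, 0, len(f_s) - 1)
        hit = (idx >= 0) & (f_end_max[idxc] > t_s)
        total += int(hit.sum())
    return total


def overlap_percent(
    factor: PeakSet, target: PeakSet, denominator: str = "factor"
) -> float:
    """Percentage of the denominator set's intervals intersected (>=1 bp) by
    the other set. ``denominator`` is "factor" or "target"."""
    if denominator not in ("factor", "target"):
        raise ValueError(f"denominator must be 'factor' or 'target', got {denominator!r}")
    denom, other = (factor, target) if denominator == "factor" else (target, factor)
    if len(denom) == 0:
        raise ValueError("denominator peak set is empty")
    hit = _count_targets_hit(other.by_chrom(), denom.by_chrom())
    return 100.0 * hit / len(denom)


def null_max_overlap(
    factor: PeakSet,
    target: PeakSet,
    sizes: ChromSizes,
    params: ShuffleParams = ShuffleParams(),
) -> ShuffleNullResult:
    """Observed vs maximum-over-shuffles count of target regions intersected
    by the factor set, with the factor set shuffled within chromosomes."""
    _validate_for_shuffle(factor, sizes)
    target_arrays = target.by_chrom()
    n_target = len(target)

    observed = _count_targets_hit(factor.by_chrom(), target_arrays)

    # group factor peaks by chromosome once; lengths stay fixed across shuffles
    lengths: dict[str, np.ndarray] = {}
    for iv in factor:
        lengths.setdefault(iv.chrom, [])
    per_chrom_lengths: dict[str, list[int]] = {c: [] for c in lengths}
    for iv in factor:
        per_chrom_lengths[iv.chrom].append(len(iv))
    lens = {c: np.array(v, dtype=np.int64) for c, v in per_chrom_lengths.items()}
    highs = {c: sizes[c] - lens[c] + 1 for c in lens}

    seeds = np.random.SeedSequence(params.seed).spawn(params.n_shuffles)
    counts = np.zeros(params.n_shuffles, dtype=np.int64)
    for i in range(params.n_shuffles):
        rng = np.random.default_rng(seeds[i])
        shuffled = {}
        for chrom in lens:
            starts = rng.integers(0, highs[chrom])
            shuffled[chrom] = (starts, starts + lens[chrom])
        counts[i] = _count_targets_hit(shuffled, target_arrays)

    def pct(x: float) -> float:
        return 100.0 * x / n_target if n_target else 0.0

    return ShuffleNullResult(
        factor=factor.factor,
        target=target.factor,
        n_shuffles=params.n_shuffles,
        seed=params.seed,
        observed_count=observed,
        observed_percent=pct(observed),
        null_max_count=int(counts.max()),
        null_max_percent=pct(float(counts.max())),
        null_mean_percent=pct(float(counts.mean())),
        null_p95_percent=pct(float(np.percentile(counts, 95))),
        n_target=n_target,
        per_shuffle_counts=(
            counts if params.n_shuffles <= params.keep_per_shuffle_max else None
        ),
    )
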