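"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open (BED convention). Formats that
use 1-based inclusive coordinates (GTF) are converted at the parsing boundary;
nothing downstream ever sees a 1-based coordinate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TIMEPOINTS = ("D0", "D2", "D6")

#: Factor / mark vocabulary used by the study design. Peak sets may carry other
#: labels, but the integration layer only knows how to place these.
FACTORS = (
    "JMJD2B",
    "H3K9me3",
    "H3K36me3",
    "TFAP2C",
    "LSD1",
    "H3K4me1",
    "H3K27ac",
)


class FormatError(ValueError):
    """A text input violated its declared format (raised with line context)."""


@dataclass(frozen=True)
class Interval:
    """A half-open genomic span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    qvalue: float | None = None  # linear-scale FDR q, in [0, 1]

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"qvalue {self.qvalue} outside [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start

    def intersects(self, other: "Interval") -> bool:
        """>=1 bp overlap on the same chromosome (half-open adjacency is not overlap)."""
        return self.chrom == other.chrom and max(self.start, other.start) < min(
            self.end, other.end
        )


class ChromSizes:
    """Ordered chromosome-name -> length (bp) map."""

    def __init__(self, entries: Iterable[tuple[str, int]] = ()) -> None:
        self._sizes: dict[str, int] = {}
        for name, length in entries:
            self.add(name, length)

    def add(self, name: str, length: int) -> None:
        if name in self._sizes:
            raise ValueError(f"duplicate chromosome name {name!r}")
        if not isinstance(length, (int, np.integer)) or length < 1:
            raise ValueError(f"chromosome {name!r} has non-positive length {length!r}")
        self._sizes[name] = int(length)

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __len__(self) -> int:
        return len(self._sizes)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def items(self) -> Iterable[tuple[str, int]]:
        return self._sizes.items()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ChromSizes) and list(self.items()) == list(other.items())

    def require_nonempty(self) -> "ChromSizes":
        if not self._sizes:
            raise ValueError("operation requires at least one chromosome")
        return self

    def validate_interval(self, iv: Interval) -> None:
        if iv.chrom not in self._sizes:
            raise ValueError(f"chromosome {iv.chrom!r} not in chrom sizes")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self._sizes[iv.chrom]}"
            )


@dataclass
class PeakSet:
    """A collection of intervals for one factor/mark (optionally one timepoint)."""

    factor: str
    timepoint: str | None
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.timepoint is not None and self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"timepoint {self.timepoint!r} not in declared vocabulary {TIMEPOINTS}"
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def filter_to_chroms(self, sizes: ChromSizes) -> "PeakSet":
        """Drop intervals on contigs absent from *sizes*, with a logged warning."""
        kept = [iv for iv in self.intervals if iv.chrom in sizes]
        dropped = len(self.intervals) - len(kept)
        if dropped:
            log.warning(
                "%s/%s: dropped %d interval(s) on contigs absent from chrom sizes",
                self.factor,
                self.timepoint,
                dropped,
            )
        return PeakSet(self.factor, self.timepoint, kept)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays sorted by start (ties by end)."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        chroms: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            chroms.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, spans in chroms.items():
            arr = np.array(sorted(spans), dtype=np.int64).reshape(-1, 2)
            out[chrom] = (arr[:, 0], arr[:, 1])
        return out

    def total_bases(self) -> int:
        """Bases covered, counting overlaps once (i.e. after merging)."""
        total = 0
        for starts, ends in self.by_chrom().values():
            cover_end = -1
            for s, e in zip(starts.tolist(), ends.tolist()):
                if s > cover_end:
                    total += e - s
                    cover_end = e
                elif e > cover_end:
                    total += e - cover_end
                    cover_end = e
        return total


class SignalTrack:
    """Step-function coverage: per chromosome sorted, non-overlapping
    ``(start, end, value)`` steps; uncovered positions have implicit value 0."""

    def __init__(self, steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (starts, ends, values) in steps.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise FormatError(f"{chrom}: step with non-positive span")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"{chrom}: overlapping steps")
            self._steps[chrom] = (starts, ends, values)
            # cumulative integral up to the start of each step
            self._cum[chrom] = np.concatenate(
                [[0.0], np.cumsum(values * (ends - starts))]
            )

    @classmethod
    def from_steps(
        cls, steps: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in steps:
            per.setdefault(chrom, []).append((s, e, v))
        return cls(
            {
                c: (
                    np.array([t[0] for t in lst]),
                    np.array([t[1] for t in lst]),
                    np.array([t[2] for t in lst]),
                )
                for c, lst in per.items()
            }
        )

    def chroms(self) -> list[str]:
        return list(self._steps)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._steps[chrom]

    def iter_steps(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self._steps:
            starts, ends, values = self._steps[chrom]
            for s, e, v in zip(starts.tolist(), ends.tolist(), values.tolist()):
                yield chrom, s, e, v

    def _integral_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, pos) for an array of positions."""
        if chrom not in self._steps:
            return np.zeros(len(pos), dtype=np.float64)
        starts, ends, values = self._steps[chrom]
        cum = self._cum[chrom]
        k = np.searchsorted(starts, pos, side="right") - 1
        kc = np.clip(k, 0, len(starts) - 1)
        base = np.where(k >= 0, cum[kc], 0.0)
        inside = np.clip(pos - starts[kc], 0, ends[kc] - starts[kc])
        partial = np.where(k >= 0, values[kc] * inside, 0.0)
        return base + partial

    def mean_over(self, chrom: str, starts, ends) -> np.ndarray:
        """Mean per-base signal over each span ``[start, end)`` (vectorised).

        Spans are clipped to [0, inf); bases outside any step contribute 0 but
        still count in the denominator (the nominal span length).
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(ends <= starts):
            raise ValueError("mean_over requires start < end for every span")
        lo = np.clip(starts, 0, None)
        hi = np.maximum(np.clip(ends, 0, None), lo)
        totals = self._integral_at(chrom, hi) - self._integral_at(chrom, lo)
        return totals / (ends - starts)

    def value_at(self, chrom: str, pos: int) -> float:
        """Point value (implicit 0 off-step)."""
        if chrom not in self._steps:
            return 0.0
        starts, ends, values = self._steps[chrom]
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        if k >= 0 and pos < ends[k]:
            return float(values[k])
        return 0.0


@dataclass(frozen=True)
class GeneModel:
    """Gene identity plus strand-aware TSS/TES over a half-open genomic span."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: invalid span {self.start}-{self.end}")
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, name=self.gene_id)


@dataclass(frozen=True)
class SampleInfo:
    label: str
    timepoint: str
    replicate: int


class ExpressionTable:
    """Gene x sample FPKM matrix with (timepoint, replicate) sample metadata."""

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleInfo]):
        if list(values.columns) != [s.label for s in samples]:
            raise ValueError("value columns must match sample metadata order")
        if (values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if values.index.duplicated().any():
            raise ValueError("duplicate gene_id in expression table")
        tp_counts: dict[str, int] = {}
        for s in samples:
            tp_counts[s.timepoint] = tp_counts.get(s.timepoint, 0) + 1
        if any(n < 1 for n in tp_counts.values()) or not tp_counts:
            raise ValueError("each timepoint needs at least one replicate")
        self.values = values.astype(float)
        self.samples = list(samples)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.timepoint not in seen:
                seen.append(s.timepoint)
        return seen

    def samples_for(self, timepoint: str) -> list[SampleInfo]:
        out = [s for s in self.samples if s.timepoint == timepoint]
        if not out:
            raise ValueError(f"no samples for timepoint {timepoint!r}")
        return out

    def mean_fpkm(self, timepoint: str) -> pd.Series:
        labels = [s.label for s in self.samples_for(timepoint)]
        return self.values[labels].mean(axis=1)
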