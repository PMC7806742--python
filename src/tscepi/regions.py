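"""Interval algebra and the regulatory-element taxonomy.

Promoters are the strand-aware window [-3 kb, +500 bp) around the TSS, the
gene body is the annotated span, and putative enhancers are the base-level
intersection of H3K4me1 and H3K27ac peaks lying outside promoters. Overlap
everywhere means >=1 bp intersection of half-open intervals; book-ended
intervals do not overlap, but merge() unions them (base-cover semantics,
matching bedtools merge defaults).

The set operations are implemented as sorted sweeps over per-chromosome
numpy arrays; they are property-tested against a per-base bitmap oracle.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .types import ChromSizes, GeneModel, Interval, PeakSet

log = logging.getLogger(__name__)

REGION_CLASSES = ("promoter", "enhancer", "gene_body", "other")


@dataclass(frozen=True)
class PromoterParams:
    """Strand-aware promoter window size around the TSS (bp)."""

    upstream: int = 3000
    downstream: int = 500

    def __post_init__(self) -> None:
        if self.upstream + self.downstream < 1:
            raise ValueError("promoter window must cover at least 1 bp")


def promoter_window(
    gene: GeneModel, sizes: ChromSizes, params: PromoterParams = PromoterParams()
) -> Interval:
    """The promoter window of *gene*, clipped to the chromosome.

    Plus strand: [TSS-upstream, TSS+downstream); minus strand mirrored.
    A window that falls entirely off-chromosome is an error.
    """
    if gene.chrom not in sizes:
        raise ValueError(f"{gene.gene_id}: chromosome {gene.chrom!r} not in sizes")
    if gene.strand == "+":
        start, end = gene.tss - params.upstream, gene.tss + params.downstream
    else:
        start, end = gene.tss - params.downstream, gene.tss + params.upstream
    chrom_len = sizes[gene.chrom]
    start_c, end_c = max(start, 0), min(end, chrom_len)
    if start_c >= end_c:
        raise ValueError(
            f"{gene.gene_id}: promoter window [{start}, {end}) lies entirely "
            f"outside chromosome {gene.chrom} (length {chrom_len})"
        )
    return Interval(gene.chrom, start_c, end_c, name=gene.gene_id)


def gene_body(gene: GeneModel) -> Interval:
    """The full annotated genomic span (strand does not affect the result)."""
    return Interval(gene.chrom, gene.start, gene.end, name=gene.gene_id)


def intersects(a: Interval, b: Interval) -> bool:
    """>=1 bp intersection; half-open adjacency is not overlap."""
    return a.intersects(b)


# --------------------------------------------------------- array-level sweeps

def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals, merging overlapping and book-ended spans.

    Inputs must be sorted by start. Returns sorted, disjoint spans.
    """
    if len(starts) == 0:
        return starts, ends
    out_s: list[int] = [int(starts[0])]
    out_e: list[int] = [int(ends[0])]
    for s, e in zip(starts[1:].tolist(), ends[1:].tolist()):
        if s <= out_e[-1]:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def _subtract_arrays(
    a_s: np.ndarray, a_e: np.ndarray, b_s: np.ndarray, b_e: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Bases of merged A not covered by merged B. Both inputs merged/sorted."""
    out_s: list[int] = []
    out_e: list[int] = []
    j = 0
    nb = len(b_s)
    for s, e in zip(a_s.tolist(), a_e.tolist()):
        cur = s
        while j < nb and b_e[j] <= cur:
            j += 1
        k = j
        while k < nb and b_s[k] < e:
            if b_s[k] > cur:
                out_s.append(cur)
                out_e.append(int(b_s[k]))
            cur = max(cur, int(b_e[k]))
            if cur >= e:
                break
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def _intersect_arrays(
    a_s: np.ndarray, a_e: np.ndarray, b_s: np.ndarray, b_e: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Base-level intersection of two merged/sorted interval lists."""
    out_s: list[int] = []
    out_e: list[int] = []
    i = j = 0
    na, nb = len(a_s), len(b_s)
    while i < na and j < nb:
        s = max(a_s[i], b_s[j])
        e = min(a_e[i], b_e[j])
        if s < e:
            out_s.append(int(s))
            out_e.append(int(e))
        if a_e[i] <= b_e[j]:
            i += 1
        else:
            j += 1
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def _any_overlap_mask(
    q_s: np.ndarray, q_e: np.ndarray, t_s: np.ndarray, t_e: np.ndarray
) -> np.ndarray:
    """For each query span, whether any merged target span overlaps it.

    Targets must be merged (disjoint, sorted): then the only candidate is the
    last target starting before the query end.
    """
    if len(t_s) == 0:
        return np.zeros(len(q_s), dtype=bool)
    idx = np.searchsorted(t_s, q_e, side="left") - 1
    idxc = np.clip(idx, 0, len(t_s) - 1)
    return (idx >= 0) & (t_e[idxc] > q_s)


def _chrom_order(*sets: PeakSet) -> list[str]:
    chroms: set[str] = set()
    for ps in sets:
        for iv in ps:
            chroms.add(iv.chrom)
    return sorted(chroms)


def _as_plain_peakset(
    factor: str,
    timepoint: str | None,
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
) -> PeakSet:
    intervals = [
        Interval(chrom, int(s), int(e))
        for chrom in sorted(per_chrom)
        for s, e in zip(*[a.tolist() for a in per_chrom[chrom]])
    ]
    return PeakSet(factor, timepoint, intervals)


# ----------------------------------------------------------- public set ops

def merge(peaks: PeakSet) -> PeakSet:
    """Union of the peak set's intervals (overlapping/book-ended spans fused)."""
    per = {
        chrom: _merge_arrays(*arrays) for chrom, arrays in peaks.by_chrom().items()
    }
    return _as_plain_peakset(peaks.factor, peaks.timepoint, per)


def subtract(a: PeakSet, b: PeakSet) -> PeakSet:
    """Bases of *a* not covered by *b* (both sides treated as base sets)."""
    bc = {c: _merge_arrays(*arr) for c, arr in b.by_chrom().items()}
    per: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, arrays in a.by_chrom().items():
        a_s, a_e = _merge_arrays(*arrays)
        b_s, b_e = bc.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        per[chrom] = _subtract_arrays(a_s, a_e, b_s, b_e)
    return _as_plain_peakset(a.factor, a.timepoint, per)


def pairwise_intersection(a: PeakSet, b: PeakSet) -> PeakSet:
    """Base-level intersection of the two base sets (symmetric)."""
    bc = {c: _merge_arrays(*arr) for c, arr in b.by_chrom().items()}
    per: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, arrays in a.by_chrom().items():
        if chrom not in bc:
            continue
        a_s, a_e = _merge_arrays(*arrays)
        per[chrom] = _intersect_arrays(a_s, a_e, *bc[chrom])
    return _as_plain_peakset(f"{a.factor}&{b.factor}", a.timepoint, per)


def overlap_any(query: PeakSet, targets: PeakSet) -> tuple[np.ndarray, int]:
    """Per-query-interval boolean (>=1 bp overlap with any target) and the
    total count of query intervals overlapped. Order follows ``query.intervals``."""
    tc = {c: _merge_arrays(*arr) for c, arr in targets.by_chrom().items()}
    flags = np.zeros(len(query), dtype=bool)
    by_chrom_idx: dict[str, list[int]] = {}
    for i, iv in enumerate(query):
        by_chrom_idx.setdefault(iv.chrom, []).append(i)
    for chrom, idxs in by_chrom_idx.items():
        if chrom not in tc:
            continue
        q_s = np.array([query.intervals[i].start for i in idxs], dtype=np.int64)
        q_e = np.array([query.intervals[i].end for i in idxs], dtype=np.int64)
        hit = _any_overlap_mask(q_s, q_e, *tc[chrom])
        flags[np.array(idxs)] = hit
    return flags, int(flags.sum())


def top_n_peaks(peaks: PeakSet, n: int = 65_000) -> PeakSet:
    """The *n* most significant peaks by ascending linear q-value.

    Deterministic tie-break: (q asc, score desc, chrom, start). Missing
    q-values are an error; if the set has <= n peaks it is returned whole
    (re-sorted by the same key).
    """
    for iv in peaks:
        if iv.qvalue is None:
            raise ValueError(
                f"{peaks.factor}: peak {iv.chrom}:{iv.start}-{iv.end} has no q-value"
            )
    key = lambda iv: (
        iv.qvalue,
        -(iv.score if iv.score is not None else float("-inf")),
        iv.chrom,
        iv.start,
    )
    ranked = sorted(peaks.intervals, key=key)
    return PeakSet(peaks.factor, peaks.timepoint, ranked[:n])


def derive_enhancers(
    h3k4me1: PeakSet, h3k27ac: PeakSet, promoters: PeakSet
) -> PeakSet:
    """Putative enhancers: H3K4me1 n H3K27ac base-intersection outside promoters."""
    enh = subtract(pairwise_intersection(h3k4me1, h3k27ac), promoters)
    intervals = [
        Interval(iv.chrom, iv.start, iv.end, name=f"enh_{i + 1}")
        for i, iv in enumerate(enh)
    ]
    return PeakSet("enhancer", None, intervals)


def annotate_region_class(
    peaks: PeakSet,
    promoters: PeakSet,
    enhancers: PeakSet,
    gene_bodies: PeakSet,
) -> tuple[list[str], Counter]:
    """Assign each peak its highest-precedence overlapping class.

    Precedence: promoter > enhancer > gene_body > other. Tallies partition
    the peak set exactly.
    """
    prom_hit, _ = overlap_any(peaks, promoters)
    enh_hit, _ = overlap_any(peaks, enhancers)
    body_hit, _ = overlap_any(peaks, gene_bodies)
    classes: list[str] = []
    for p, e, b in zip(prom_hit.tolist(), enh_hit.tolist(), body_hit.tolist()):
        if p:
            classes.append("promoter")
        elif e:
            classes.append("enhancer")
        elif b:
            classes.append("gene_body")
        else:
            classes.append("other")
    tallies = Counter(classes)
    for cls in REGION_CLASSES:
        tallies.setdefault(cls, 0)
    return classes, tallies


def promoter_peakset(
    genes: list[GeneModel],
    sizes: ChromSizes,
    params: PromoterParams = PromoterParams(),
) -> PeakSet:
    """All promoter windows as one PeakSet (name = gene_id, gene order kept)."""
    return PeakSet(
        "promoter", None, [promoter_window(g, sizes, params) for g in genes]
    )


def gene_body_peakset(genes: list[GeneModel]) -> PeakSet:
    return PeakSet("gene_body", None, [gene_body(g) for g in genes])
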