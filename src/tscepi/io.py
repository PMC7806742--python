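"""Readers and writers for the plain-text genomics formats the pipeline touches.

Formats: UCSC chrom.sizes, BED6, ENCODE narrowPeak (10 columns, col 9 is a
-log10 q-value), BED12, minimal GTF (gene features only), bedGraph, and TSV
expression matrices. Parsing is strict: malformed input raises
:class:`~tscepi.types.FormatError` naming the offending line; there is no
silent coercion. Output tables are tab-separated; header lines begin ``#``.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    ChromSizes,
    ExpressionTable,
    FormatError,
    GeneModel,
    Interval,
    PeakSet,
    SampleInfo,
    SignalTrack,
)


def _lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


# ---------------------------------------------------------------- chrom sizes

def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Parse a two-column ``name<TAB>length`` file, preserving file order."""
    sizes = ChromSizes()
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        name, raw_len = fields
        if not re.fullmatch(r"[+-]?\d+", raw_len):
            raise FormatError(f"{path}:{lineno}: non-integer length {raw_len!r}")
        try:
            sizes.add(name, int(raw_len))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------- peaks

def _parse_int(raw: str, what: str, ctx: str) -> int:
    try:
        return int(raw)
    except ValueError as exc:
        raise FormatError(f"{ctx}: non-integer {what} {raw!r}") from exc


def read_peaks(
    path: str | Path,
    format: str,
    factor: str,
    timepoint: str | None = None,
) -> PeakSet:
    """Read a BED6 or ENCODE narrowPeak file into a :class:`PeakSet`.

    narrowPeak q-values (column 9, -log10 scale per ENCODE convention) are
    converted to linear scale ``10**(-col9)`` so that "sorted by q" always
    means ascending linear q. Input order is preserved.
    """
    if format not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    need = 6 if format == "bed6" else 10
    intervals: list[Interval] = []
    for lineno, line in _lines(path):
        ctx = f"{path}:{lineno}"
        fields = line.split("\t")
        if len(fields) < need:
            raise FormatError(f"{ctx}: {format} needs {need} columns, got {len(fields)}")
        chrom = fields[0]
        start = _parse_int(fields[1], "start", ctx)
        end = _parse_int(fields[2], "end", ctx)
        name = fields[3] if fields[3] != "." else None
        score = float(fields[4]) if fields[4] != "." else None
        qvalue = None
        if format == "narrowPeak":
            score = float(fields[6])  # signalValue
            neglog_q = float(fields[8])
            if neglog_q >= 0:
                qvalue = min(10.0 ** (-neglog_q), 1.0)
            elif neglog_q == -1:  # ENCODE sentinel for "not available"
                qvalue = None
            else:
                raise FormatError(f"{ctx}: invalid -log10 q-value {neglog_q}")
        try:
            intervals.append(
                Interval(chrom, start, end, name=name, score=score, qvalue=qvalue)
            )
        except ValueError as exc:
            raise FormatError(f"{ctx}: {exc}") from exc
    return PeakSet(factor=factor, timepoint=timepoint, intervals=intervals)


def write_peaks(peaks: PeakSet, path: str | Path, format: str = "narrowPeak") -> None:
    """Write a PeakSet as BED6 or narrowPeak (round-trips with :func:`read_peaks`)."""
    if format not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks):
            name = iv.name if iv.name is not None else f"{peaks.factor}_{i + 1}"
            if format == "bed6":
                score = iv.score if iv.score is not None else 0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t.\n")
            else:
                signal = iv.score if iv.score is not None else 0.0
                if iv.qvalue is None:
                    neglog_q = -1.0
                elif iv.qvalue <= 0:
                    raise ValueError("cannot encode q-value 0 as -log10")
                else:
                    import math

                    neglog_q = -math.log10(iv.qvalue)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\t"
                    f"{signal:.17g}\t-1\t{neglog_q:.17g}\t-1\n"
                )


def write_bed6(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = iv.name if iv.name is not None else f"region_{i + 1}"
            score = iv.score if iv.score is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t.\n")


# ---------------------------------------------------------------- gene models

def read_gene_models(path: str | Path, format: str) -> list[GeneModel]:
    """Read gene models from BED12 (coordinates as-is, 0-based) or minimal GTF
    (gene features only; start converted from 1-based inclusive to 0-based)."""
    if format not in ("bed12", "gtf-minimal"):
        raise ValueError(f"unknown gene-model format {format!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()

    def _add(gene: GeneModel, ctx: str) -> None:
        if gene.gene_id in seen:
            raise FormatError(f"{ctx}: duplicate gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
        genes.append(gene)

    for lineno, line in _lines(path):
        ctx = f"{path}:{lineno}"
        fields = line.split("\t")
        if format == "bed12":
            if len(fields) < 12:
                raise FormatError(f"{ctx}: BED12 needs 12 columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise FormatError(f"{ctx}: unknown strand {strand!r}")
            try:
                gene = GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    start=_parse_int(start, "start", ctx),
                    end=_parse_int(end, "end", ctx),
                )
            except ValueError as exc:
                raise FormatError(f"{ctx}: {exc}") from exc
            _add(gene, ctx)
        else:
            if len(fields) < 9:
                raise FormatError(f"{ctx}: GTF needs 9 columns, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "gene":
                continue
            if strand not in ("+", "-"):
                raise FormatError(f"{ctx}: unknown strand {strand!r}")
            m = re.search(r'gene_id "([^"]+)"', attrs)
            if not m:
                raise FormatError(f"{ctx}: missing gene_id attribute")
            bm = re.search(r'gene_biotype "([^"]+)"', attrs)
            biotype = "coding"
            if bm and bm.group(1) != "protein_coding":
                biotype = "noncoding"
            try:
                gene = GeneModel(
                    gene_id=m.group(1),
                    chrom=chrom,
                    strand=strand,
                    start=_parse_int(start, "start", ctx) - 1,  # 1-based -> 0-based
                    end=_parse_int(end, "end", ctx),
                    biotype=biotype,
                )
            except ValueError as exc:
                raise FormatError(f"{ctx}: {exc}") from exc
            _add(gene, ctx)
    return genes


def write_gene_models_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write genes as single-block BED12 records (round-trips the span/strand)."""
    with open(path, "w") as fh:
        for g in genes:
            length = g.end - g.start
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{length},\t0,\n"
            )


# ------------------------------------------------------------------- bedGraph

def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Steps may arrive unsorted; overlapping steps are an error (no silent
    averaging). Uncovered positions have implicit value 0.
    """
    steps: list[tuple[str, int, int, float]] = []
    for lineno, line in _lines(path):
        ctx = f"{path}:{lineno}"
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{ctx}: bedGraph needs 4 columns, got {len(fields)}")
        chrom = fields[0]
        start = _parse_int(fields[1], "start", ctx)
        end = _parse_int(fields[2], "end", ctx)
        if end <= start:
            raise FormatError(f"{ctx}: non-positive span {start}-{end}")
        try:
            value = float(fields[3])
        except ValueError as exc:
            raise FormatError(f"{ctx}: non-numeric value {fields[3]!r}") from exc
        steps.append((chrom, start, end, value))
    try:
        return SignalTrack.from_steps(steps)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in track.iter_steps():
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")


# ----------------------------------------------------------- expression table

def read_fpkm_table(
    path: str | Path, sample_meta: Sequence[tuple[str, str, int]]
) -> ExpressionTable:
    """Read a TSV FPKM matrix (first column gene_id; one column per sample).

    *sample_meta* is an ordered list of ``(label, timepoint, replicate)``
    matching the data columns left to right.
    """
    df = pd.read_csv(path, sep="\t", comment=None, float_precision="round_trip")
    if df.columns[0].startswith("#"):
        df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected gene_id column plus >=1 sample column")
    data_cols = list(df.columns[1:])
    labels = [m[0] for m in sample_meta]
    if data_cols != labels:
        raise FormatError(
            f"{path}: sample columns {data_cols} do not match metadata {labels}"
        )
    values = df.set_index(df.columns[0])[labels]
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric FPKM value ({exc})") from exc
    if values.isna().any().any():
        raise FormatError(f"{path}: missing FPKM value")
    samples = [SampleInfo(label, tp, rep) for label, tp, rep in sample_meta]
    try:
        return ExpressionTable(values, samples)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fpkm_table(table: ExpressionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(s.label for s in table.samples) + "\n")
        for gene_id, row in table.values.iterrows():
            fh.write(gene_id + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
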