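"""Scaled-region signal matrices, average profiles, and promoter-signal
correlation between marks.

Every gene contributes one row oriented 5' -> 3': an upstream flank, the
TSS -> TES body rescaled to a fixed number of bins, and a downstream flank.
Bin values are mean per-base signal; flank bases clipped off the chromosome
contribute 0 (the nominal bin length stays in the denominator). Minus-strand
genes are computed on mirrored genomic bins so that reversing the genome
leaves the matrix unchanged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ChromSizes, GeneModel, PeakSet, SignalTrack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetageneParams:
    upstream_flank: int = 3000
    downstream_flank: int = 3000
    body_bins: int = 100
    flank_bins: int = 30

    def __post_init__(self) -> None:
        if min(
            self.upstream_flank, self.downstream_flank, self.body_bins, self.flank_bins
        ) < 1:
            raise ValueError("all metagene parameters must be >= 1")


@dataclass
class SignalMatrix:
    """Genes x bins mean-signal matrix; columns ordered upstream flank,
    scaled body (TSS -> TES), downstream flank."""

    gene_ids: list[str]
    values: np.ndarray  # shape (n_genes, 2*flank_bins + body_bins)
    params: MetageneParams

    @property
    def n_bins(self) -> int:
        return 2 * self.params.flank_bins + self.params.body_bins

    def to_frame(self) -> pd.DataFrame:
        fb, bb = self.params.flank_bins, self.params.body_bins
        cols = (
            [f"up{i + 1}" for i in range(fb)]
            + [f"body{i + 1}" for i in range(bb)]
            + [f"down{i + 1}" for i in range(fb)]
        )
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def _oriented_sizes(total: int, n_bins: int) -> np.ndarray:
    """Split *total* bases into *n_bins* spans; the remainder goes to the
    bins nearest the 5' end (oriented leftmost)."""
    base, rem = divmod(total, n_bins)
    sizes = np.full(n_bins, base, dtype=np.int64)
    sizes[:rem] += 1
    return sizes


def _gene_bin_edges(gene: GeneModel, params: MetageneParams) -> np.ndarray:
    """Genomic (unclipped) bin edges for one gene, in row (5'->3') order.

    Returns an array of shape (n_bins, 2) of [start, end) spans; for minus
    strand genes the spans run right-to-left along the genome.
    """
    sizes = np.concatenate(
        [
            _oriented_sizes(params.upstream_flank, params.flank_bins),
            _oriented_sizes(gene.end - gene.start, params.body_bins),
            _oriented_sizes(params.downstream_flank, params.flank_bins),
        ]
    )
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    if gene.strand == "+":
        origin = gene.start - params.upstream_flank
        starts = origin + offsets[:-1]
        ends = origin + offsets[1:]
    else:
        origin = gene.end + params.upstream_flank
        starts = origin - offsets[1:]
        ends = origin - offsets[:-1]
    return np.column_stack([starts, ends])


def scaled_region_matrix(
    track: SignalTrack,
    genes: list[GeneModel],
    sizes: ChromSizes,
    params: MetageneParams = MetageneParams(),
) -> SignalMatrix:
    """Per-gene scaled-region bin means (genes with bodies shorter than
    ``body_bins`` are skipped with a logged warning)."""
    kept: list[str] = []
    rows: list[np.ndarray] = []
    for gene in genes:
        if gene.end - gene.start < params.body_bins:
            log.warning(
                "%s: gene body (%d bp) shorter than body_bins=%d; skipped",
                gene.gene_id,
                gene.end - gene.start,
                params.body_bins,
            )
            continue
        edges = _gene_bin_edges(gene, params)
        row = track.mean_over(gene.chrom, edges[:, 0], edges[:, 1])
        rows.append(row)
        kept.append(gene.gene_id)
    values = np.array(rows) if rows else np.empty((0, 2 * params.flank_bins + params.body_bins))
    return SignalMatrix(gene_ids=kept, values=values, params=params)


def mean_profile(matrix: SignalMatrix, subset: set[str] | None = None) -> np.ndarray:
    """Column-wise mean over the given gene subset (all rows if None)."""
    if subset is None:
        idx = np.arange(len(matrix.gene_ids))
    else:
        unknown = set(subset) - set(matrix.gene_ids)
        if unknown:
            raise ValueError(f"subset gene(s) not in matrix: {sorted(unknown)[:5]}")
        lookup = {g: i for i, g in enumerate(matrix.gene_ids)}
        idx = np.array(sorted(lookup[g] for g in subset))
    if len(idx) == 0:
        raise ValueError("empty gene subset")
    return matrix.values[idx].mean(axis=0)


def promoter_signal_correlation(
    track_a: SignalTrack,
    track_b: SignalTrack,
    promoters: PeakSet,
    method: str = "spearman",
) -> tuple[float, float]:
    """Correlation of per-promoter mean signal between two tracks.

    Returns (coefficient, two-sided p-value). Zero variance in either
    per-promoter vector makes the correlation undefined (error).
    """
    if len(promoters) < 3:
        raise ValueError("need >= 3 promoters for a correlation")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    means_a: list[float] = []
    means_b: list[float] = []
    for iv in promoters:
        means_a.append(float(track_a.mean_over(iv.chrom, [iv.start], [iv.end])[0]))
        means_b.append(float(track_b.mean_over(iv.chrom, [iv.start], [iv.end])[0]))
    a = np.array(means_a)
    b = np.array(means_b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in promoter signal; correlation undefined")
    if method == "spearman":
        res = stats.spearmanr(a, b)
    else:
        res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------------ plotting

def plot_profile(profile: np.ndarray, params: MetageneParams, path: str, label: str = "") -> None:
    """Average-profile line plot (flank/body boundaries marked)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fb, bb = params.flank_bins, params.body_bins
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(np.arange(len(profile)), profile, lw=1.5, label=label or None)
    for x in (fb - 0.5, fb + bb - 0.5):
        ax.axvline(x, color="grey", lw=0.7, ls="--")
    ax.set_xticks([0, fb, fb + bb, 2 * fb + bb - 1])
    ax.set_xticklabels(
        [f"-{params.upstream_flank / 1000:g}kb", "TSS", "TES",
         f"+{params.downstream_flank / 1000:g}kb"]
    )
    ax.set_ylabel("mean signal")
    if label:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: SignalMatrix, path: str, order_by_mean: bool = True) -> None:
    """Genes x bins heatmap, rows ordered by descending row mean."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.values
    if order_by_mean and len(values):
        values = values[np.argsort(-values.mean(axis=1))]
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(values, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_xlabel("bins (5' flank | body | 3' flank)")
    ax.set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
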