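"""Transcriptional-state calling from FPKM tables.

The zFPKM transform (Hart et al. style) standardises each sample's log2 FPKM
distribution against its main (expressed) density mode: with x = log2(FPKM)
over genes with FPKM > 0,

    mu    = argmax of a Gaussian-kernel density of x,
    U     = mean of {x : x > mu},
    sigma = (U - mu) * sqrt(pi / 2)      (half-normal relation),
    z     = (x - mu) / sigma.

Genes with zFPKM strictly greater than -3 in at least one replicate of a
timepoint are called transcriptionally active there; zero-FPKM genes are
excluded from the density fit and flagged silent outright.

Differentially expressed genes (DEGs) between two timepoints are genes whose
replicate-mean FPKM ratio (with a small pseudocount) exceeds 1.5-fold in
either direction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .types import ExpressionTable

DIRECTIONS = ("up", "down", "unchanged")


@dataclass(frozen=True)
class ZFpkmParams:
    active_threshold: float = -3.0
    density_bandwidth: str = "silverman"
    grid_points: int = 512
    grid_pad: float = 3.0  # grid spans [min(x)-pad, max(x)+pad]
    min_nonzero: int = 100  # density fit unreliable below this
    mode_refine_frac: float = 0.5  # log-quadratic fit over the >=frac*peak region

    def __post_init__(self) -> None:
        if not math.isfinite(self.active_threshold):
            raise ValueError("active_threshold must be finite")


@dataclass
class ZFpkmResult:
    """Per-sample zFPKM values plus the fitted (mu, U, sigma) parameters.

    ``zfpkm`` and ``log2_fpkm`` are genes x samples frames with NaN for
    zero-FPKM genes; ``zero`` flags those genes (auto-silent, excluded from
    the fit); ``fits`` is indexed by sample label with columns mu, U, sigma.
    """

    zfpkm: pd.DataFrame
    log2_fpkm: pd.DataFrame
    zero: pd.DataFrame
    fits: pd.DataFrame
    params: ZFpkmParams
    samples: list = field(default_factory=list)


def _density_mode(x: np.ndarray, params: ZFpkmParams) -> float:
    """Mode of the Gaussian-KDE of *x*, evaluated on a fixed grid.

    The raw grid argmax is refined by a quadratic fit to log-density over the
    contiguous region around the peak with density >= mode_refine_frac * max
    (a Gaussian peak is exactly parabolic in log space), which suppresses the
    flat-top sampling noise of the argmax.
    """
    kde = gaussian_kde(x, bw_method=params.density_bandwidth)
    grid = np.linspace(
        x.min() - params.grid_pad, x.max() + params.grid_pad, params.grid_points
    )
    dens = kde(grid)
    i = int(np.argmax(dens))
    lo = i
    while lo > 0 and dens[lo - 1] >= params.mode_refine_frac * dens[i]:
        lo -= 1
    hi = i
    while hi < len(grid) - 1 and dens[hi + 1] >= params.mode_refine_frac * dens[i]:
        hi += 1
    if hi - lo >= 4:
        coef = np.polyfit(grid[lo : hi + 1], np.log(dens[lo : hi + 1]), 2)
        if coef[0] < 0:
            vertex = float(-coef[1] / (2 * coef[0]))
            if grid[lo] <= vertex <= grid[hi]:
                return vertex
    return float(grid[i])


def zfpkm_transform(
    table: ExpressionTable, params: ZFpkmParams = ZFpkmParams()
) -> ZFpkmResult:
    """Fit the zFPKM transform per sample (never pooled across samples)."""
    values = table.values
    zero = values <= 0
    log2 = values.where(~zero).apply(np.log2)
    zf = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
    fits = {}
    for sample in values.columns:
        x = log2[sample].dropna().to_numpy()
        if len(x) == 0:
            raise ValueError(f"sample {sample!r}: all FPKM values are zero")
        if len(x) < params.min_nonzero:
            raise ValueError(
                f"sample {sample!r}: only {len(x)} non-zero genes "
                f"(need >= {params.min_nonzero} for a reliable density fit)"
            )
        mu = _density_mode(x, params)
        upper = x[x > mu]
        if len(upper) == 0:
            raise ValueError(f"sample {sample!r}: no mass right of the fitted mode")
        U = float(upper.mean())
        sigma = (U - mu) * math.sqrt(math.pi / 2)
        if sigma <= 0:
            raise ValueError(f"sample {sample!r}: degenerate fit (sigma <= 0)")
        zf[sample] = (log2[sample] - mu) / sigma
        fits[sample] = {"mu": mu, "U": U, "sigma": sigma}
    return ZFpkmResult(
        zfpkm=zf,
        log2_fpkm=log2,
        zero=zero,
        fits=pd.DataFrame(fits).T[["mu", "U", "sigma"]],
        params=params,
        samples=list(table.samples),
    )


def call_active(
    result: ZFpkmResult,
    params: ZFpkmParams | None = None,
    rule: str = "any",
) -> pd.DataFrame:
    """Per-gene, per-timepoint activity calls.

    A gene is active at a timepoint iff zFPKM > threshold in at least one
    replicate (``rule="any"``, the default) or in every replicate
    (``rule="all"``). "Over -3" is strict: z == threshold exactly is silent.
    Zero-FPKM replicates never vote active.
    """
    params = params or result.params
    if rule not in ("any", "all"):
        raise ValueError(f"unknown replicate rule {rule!r}")
    timepoints: list[str] = []
    for s in result.samples:
        if s.timepoint not in timepoints:
            timepoints.append(s.timepoint)
    out = {}
    for tp in timepoints:
        labels = [s.label for s in result.samples if s.timepoint == tp]
        if not labels:
            raise ValueError(f"missing timepoint {tp!r}")
        over = result.zfpkm[labels] > params.active_threshold  # NaN -> False
        out[tp] = over.any(axis=1) if rule == "any" else over.all(axis=1)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class DEGParams:
    fold_threshold: float = 1.5
    pseudocount: float = 0.1  # FPKM units, avoids division by zero

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    comparison: tuple[str, str]  # (earlier, later)
    fold: float
    direction: str


def call_degs(
    table: ExpressionTable,
    pair: tuple[str, str],
    params: DEGParams = DEGParams(),
) -> pd.DataFrame:
    """Fold-change DEG classification between an ordered timepoint pair.

    fold = (mean FPKM at later + pc) / (mean FPKM at earlier + pc);
    direction is "up" if fold > threshold, "down" if fold < 1/threshold,
    else "unchanged". Returns a frame with columns gene_id, comparison,
    fold, direction (one row per gene, table order).
    """
    earlier, later = pair
    m0 = table.mean_fpkm(earlier) + params.pseudocount
    m1 = table.mean_fpkm(later) + params.pseudocount
    fold = m1 / m0
    direction = np.where(
        fold > params.fold_threshold,
        "up",
        np.where(fold < 1.0 / params.fold_threshold, "down", "unchanged"),
    )
    return pd.DataFrame(
        {
            "gene_id": table.genes,
            "comparison": f"{earlier}->{later}",
            "fold": fold.to_numpy(),
            "direction": direction,
        }
    )


def deg_records(degs: pd.DataFrame) -> list[DEGRecord]:
    """Frame rows as typed records (up/down only)."""
    out = []
    for row in degs.itertuples(index=False):
        if row.direction in ("up", "down"):
            earlier, later = row.comparison.split("->")
            out.append(DEGRecord(row.gene_id, (earlier, later), row.fold, row.direction))
    return out
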