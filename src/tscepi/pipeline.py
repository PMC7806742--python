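"""End-to-end orchestration: study directory in, summary report out.

Stages run in a fixed order — expression state -> regulatory regions ->
mark integration -> shuffle null -> metagene/correlation — and every number
in the report is recomputable from the intermediate tables written next to
it. A provenance block (config, seed, package version, config hash) is
embedded in the JSON report, and the run is deterministic for a fixed
configuration.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as tio
from .expression import DEGParams, ZFpkmParams, call_active, call_degs, zfpkm_transform
from .integration import (
    DEFAULT_MARK_REGIONS,
    assign_complex,
    build_mark_status,
    deg_dynamics_crosstab,
    dynamics_table,
    state_table,
    summarize_fractions,
)
from .metagene import MetageneParams, promoter_signal_correlation
from .regions import (
    PromoterParams,
    annotate_region_class,
    derive_enhancers,
    gene_body,
    overlap_any,
    promoter_window,
    top_n_peaks,
)
from .shuffle import ShuffleParams, null_max_overlap
from .types import PeakSet

log = logging.getLogger(__name__)

TIMEPOINTS = ("D0", "D2", "D6")


@dataclass
class AnalysisConfig:
    """Every numeric constant the pipeline uses, in one place.

    Defaults are the study constants: zFPKM > -3 activity, 1.5-fold DEGs,
    -3 kb/+500 bp promoters, top-65,000 peak selection, 10,000 shuffles.
    """

    study_dir: str = "study"
    out_dir: str = "out"
    timepoints: tuple[str, ...] = TIMEPOINTS
    zfpkm_threshold: float = -3.0
    replicate_rule: str = "any"
    deg_fold: float = 1.5
    deg_pseudocount: float = 0.1
    promoter_upstream: int = 3000
    promoter_downstream: int = 500
    top_n: int = 65_000
    n_shuffles: int = 10_000
    seed: int = 0
    shuffle_denominator: str = "factor"
    metagene: MetageneParams = field(default_factory=MetageneParams)
    compute_metagene: bool = True
    min_nonzero: int = 100

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints"] = list(self.timepoints)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        if "metagene" in d and isinstance(d["metagene"], dict):
            d["metagene"] = MetageneParams(**d["metagene"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def provenance(self) -> dict:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return {
            "tool": "tscepi",
            "version": __version__,
            "seed": self.seed,
            "config": self.to_dict(),
            "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        }


@dataclass
class SummaryReport:
    """Machine-readable tallies mirroring the usual summary figures (cascade
    pies, complex tallies, overlap bars, cross-tabs)."""

    provenance: dict
    expression: dict
    deg_dynamics: dict
    cascade: dict
    complexes: dict
    region_distribution: dict
    overlap_null: dict
    correlation: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_markdown(self, path: str | Path) -> None:
        d = self.to_dict()
        lines = ["# Summary report", ""]
        for section in (
            "expression",
            "deg_dynamics",
            "cascade",
            "complexes",
            "region_distribution",
            "overlap_null",
            "correlation",
        ):
            lines.append(f"## {section}")
            lines.append("```json")
            lines.append(json.dumps(d[section], indent=2, sort_keys=True))
            lines.append("```")
            lines.append("")
        Path(path).write_text("\n".join(lines))


def _frac(n: int, d: int) -> dict:
    if d <= 0:
        return {"numerator": int(n), "denominator": int(d), "percent": None}
    s = summarize_fractions(int(n), int(d))
    return {
        "numerator": s.numerator,
        "denominator": s.denominator,
        "percent": s.percent,
        "ratio": s.ratio,
    }


def load_study_inputs(config: AnalysisConfig) -> dict:
    """Read a study directory laid out by :func:`tscepi.simulate.write_study`."""
    d = Path(config.study_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"study directory {d} not found")
    sizes = tio.read_chrom_sizes(d / "chrom.sizes")
    genes = tio.read_gene_models(d / "genes.bed12", format="bed12")
    sample_meta = [
        (f"{tp}_r{rep}", tp, rep) for tp in config.timepoints for rep in (1, 2)
    ]
    expression = tio.read_fpkm_table(d / "fpkm.tsv", sample_meta)
    peaks: dict[tuple[str, str | None], PeakSet] = {}
    for mark in ("JMJD2B", "H3K9me3", "H3K36me3"):
        for tp in config.timepoints:
            path = d / f"{mark}_{tp}.narrowPeak"
            if not path.exists():
                raise FileNotFoundError(f"missing peak file {path}")
            peaks[(mark, tp)] = tio.read_peaks(path, "narrowPeak", mark, tp)
    for factor in ("TFAP2C", "LSD1", "H3K4me1", "H3K27ac"):
        path = d / f"{factor}.narrowPeak"
        if not path.exists():
            raise FileNotFoundError(f"missing peak file {path}")
        peaks[(factor, None)] = tio.read_peaks(path, "narrowPeak", factor, None)
    tracks = {}
    for mark in ("JMJD2B", "H3K9me3", "H3K36me3"):
        path = d / f"{mark}_D0.bedgraph"
        if path.exists():
            tracks[f"{mark}_D0"] = tio.read_bedgraph(path)
    return {
        "sizes": sizes,
        "genes": genes,
        "expression": expression,
        "peaks": peaks,
        "tracks": tracks,
    }


def run_pipeline(config: AnalysisConfig) -> SummaryReport:
    """Run every stage on a study directory and write the report + tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_study_inputs(config)
    sizes, genes = inputs["sizes"], inputs["genes"]
    expression, peaks = inputs["expression"], inputs["peaks"]

    # ---- stage 1: expression state -------------------------------------
    log.info("stage expression: zFPKM transform and DEG calls")
    zparams = ZFpkmParams(
        active_threshold=config.zfpkm_threshold, min_nonzero=config.min_nonzero
    )
    zres = zfpkm_transform(expression, zparams)
    active = call_active(zres, zparams, rule=config.replicate_rule)
    dparams = DEGParams(fold_threshold=config.deg_fold, pseudocount=config.deg_pseudocount)
    tps = list(config.timepoints)
    degs_by_phase = {
        k + 1: call_degs(expression, (tps[k], tps[k + 1]), dparams)
        for k in range(len(tps) - 1)
    }
    active.to_csv(out / "active_calls.tsv", sep="\t")
    zres.fits.to_csv(out / "zfpkm_fits.tsv", sep="\t")
    pd.concat(degs_by_phase.values()).to_csv(out / "degs.tsv", sep="\t", index=False)

    # ---- stage 2: regulatory regions ------------------------------------
    log.info("stage regions: promoters, enhancers, top-N selection")
    pparams = PromoterParams(config.promoter_upstream, config.promoter_downstream)
    promoters = {g.gene_id: promoter_window(g, sizes, pparams) for g in genes}
    bodies = {g.gene_id: gene_body(g) for g in genes}
    prom_set = PeakSet("promoter", None, [promoters[g.gene_id] for g in genes])
    body_set = PeakSet("gene_body", None, [bodies[g.gene_id] for g in genes])
    selected = {key: top_n_peaks(ps, config.top_n) for key, ps in peaks.items()}
    enhancers = derive_enhancers(
        selected[("H3K4me1", None)], selected[("H3K27ac", None)], prom_set
    )
    tio.write_bed6(enhancers.intervals, out / "enhancers.bed")

    # ---- stage 3: integration -------------------------------------------
    log.info("stage integration: mark status, states, dynamics, complexes")
    status = build_mark_status(
        genes, promoters, bodies, selected, DEFAULT_MARK_REGIONS, tps
    )
    status.to_long_frame().to_csv(out / "mark_status.tsv", sep="\t", index=False)
    states = pd.DataFrame({tp: state_table(status, tp) for tp in tps})
    states.to_csv(out / "states.tsv", sep="\t")
    dyn = {
        mark: dynamics_table(status, mark, region)
        for mark, region in DEFAULT_MARK_REGIONS.items()
    }
    for mark, table in dyn.items():
        table.to_csv(out / f"dynamics_{mark}.tsv", sep="\t")

    # DEG x H3K9me3 dynamics (negative-correlation logic, both phases)
    crosstabs = {}
    neg_union: set[str] = set()
    rev_union: set[str] = set()
    n_deg_events = 0
    deg_union: set[str] = set()
    for phase, degs in degs_by_phase.items():
        ct = deg_dynamics_crosstab(
            degs, dyn["H3K9me3"], phase, second_dynamics=dyn["JMJD2B"]
        )
        crosstabs[phase] = ct
        neg_union |= set(ct.negative_correlation)
        rev_union |= set(ct.reversed_second_mark)
        updown = degs[degs["direction"].isin(["up", "down"])]
        n_deg_events += len(updown)
        deg_union |= set(updown["gene_id"])
        ct.counts.to_csv(out / f"crosstab_H3K9me3_phase{phase}.tsv", sep="\t")
    neg_events = sum(len(ct.negative_correlation) for ct in crosstabs.values())

    # Fig-4a-style cascade over silent genes at D0
    silent_d0 = set(active.index[~active[tps[0]]])
    j0 = status.column("JMJD2B", "promoter", tps[0])
    k90 = status.column("H3K9me3", "promoter", tps[0])
    silent_j = {g for g in silent_d0 if j0[g]}
    silent_j_k9 = {g for g in silent_j if k90[g]}
    persistent_co = {
        g
        for g in silent_j_k9
        if all(
            status.present(g, "JMJD2B", "promoter", tp)
            and status.present(g, "H3K9me3", "promoter", tp)
            for tp in tps
        )
        and not any(active.at[g, tp] for tp in tps)
    }
    cascade = {
        "n_genes": len(active.index),
        "n_silent_d0": len(silent_d0),
        "silent_jmjd2b": _frac(len(silent_j), len(silent_d0)),
        "co_enriched_h3k9me3": _frac(len(silent_j_k9), len(silent_j)),
        "persistent_co_enriched": _frac(len(persistent_co), len(silent_j_k9)),
    }

    # ---- stage 4: complexes at promoters & locus taxonomy ---------------
    j_d0 = selected[("JMJD2B", tps[0])]
    tfap2c = selected[("TFAP2C", None)]
    lsd1 = selected[("LSD1", None)]
    active_genes = [g for g in genes if active.at[g.gene_id, tps[0]]]
    active_prom_set = PeakSet(
        "promoter", None, [promoters[g.gene_id] for g in active_genes]
    )
    cats, tallies = assign_complex(active_prom_set, j_d0, tfap2c, lsd1)
    pd.DataFrame(
        {"gene_id": [g.gene_id for g in active_genes], "complex": cats}
    ).to_csv(out / "complex_active_promoters.tsv", sep="\t", index=False)
    n_active = len(active_genes)
    complexes = {
        "universe": "active-gene promoters at " + tps[0],
        "tallies": dict(sorted(tallies.items())),
        "triple_bound": _frac(tallies["JMJD2B-TFAP2C-LSD1"], n_active),
        "tfap2c_lsd1": _frac(tallies["TFAP2C-LSD1"], n_active),
        "jmjd2b_only": _frac(tallies["JMJD2B_only"], n_active),
    }

    # locus taxonomy: JMJD2B peaks as reference universe for the triple set;
    # TFAP2C peaks as reference for TFAP2C-LSD1-without-JMJD2B loci
    t_hits, _ = overlap_any(j_d0, tfap2c)
    l_hits, _ = overlap_any(j_d0, lsd1)
    jtl_loci = PeakSet(
        "JTL", None,
        [iv for iv, t, l in zip(j_d0, t_hits, l_hits) if t and l],
    )
    j_on_t, _ = overlap_any(tfap2c, j_d0)
    l_on_t, _ = overlap_any(tfap2c, lsd1)
    tl_loci = PeakSet(
        "TL", None,
        [iv for iv, j, l in zip(tfap2c, j_on_t, l_on_t) if l and not j],
    )
    region_distribution = {}
    for label, loci in (("JMJD2B-TFAP2C-LSD1", jtl_loci), ("TFAP2C-LSD1", tl_loci)):
        if len(loci) == 0:
            region_distribution[label] = {"n": 0}
            continue
        classes, class_tallies = annotate_region_class(
            loci, prom_set, enhancers, body_set
        )
        n = len(loci)
        region_distribution[label] = {
            "n": n,
            "promoter": _frac(class_tallies["promoter"], n),
            "enhancer": _frac(class_tallies["enhancer"], n),
            "gene_body": _frac(class_tallies["gene_body"], n),
            "other": _frac(class_tallies["other"], n),
            "other_incl_gene_body": _frac(
                class_tallies["other"] + class_tallies["gene_body"], n
            ),
        }

    # ---- stage 5: shuffle null ------------------------------------------
    log.info("stage shuffle: observed vs randomised-control overlap")
    sparams = ShuffleParams(n_shuffles=config.n_shuffles, seed=config.seed)
    overlap_null = {}
    shuffle_rows = []
    for factor_key in (("TFAP2C", None), ("LSD1", None)):
        factor_ps = selected[factor_key]
        res = null_max_overlap(factor_ps, j_d0, sizes, sparams)
        overlap_null[factor_key[0]] = {
            "target": "JMJD2B_" + tps[0],
            "n_shuffles": res.n_shuffles,
            "observed_count": res.observed_count,
            "observed_percent": res.observed_percent,
            "null_max_count": res.null_max_count,
            "null_max_percent": res.null_max_percent,
            "null_mean_percent": res.null_mean_percent,
        }
        shuffle_rows.append(
            {
                "factor": factor_ps.factor,
                "target": "JMJD2B_" + tps[0],
                "n_shuffles": res.n_shuffles,
                "seed": res.seed,
                "observed_count": res.observed_count,
                "observed_percent": res.observed_percent,
                "null_max_count": res.null_max_count,
                "null_max_percent": res.null_max_percent,
                "null_mean_percent": res.null_mean_percent,
            }
        )
    pd.DataFrame(shuffle_rows).to_csv(out / "shuffle_null.tsv", sep="\t", index=False)

    # ---- stage 6: promoter-signal correlation ---------------------------
    correlation = {}
    tracks = inputs["tracks"]
    if config.compute_metagene and {"JMJD2B_D0", "H3K9me3_D0"} <= set(tracks):
        coef, pval = promoter_signal_correlation(
            tracks["JMJD2B_D0"], tracks["H3K9me3_D0"], prom_set, method="spearman"
        )
        correlation = {
            "tracks": ["JMJD2B_D0", "H3K9me3_D0"],
            "method": "spearman",
            "coefficient": coef,
            "pvalue": pval,
        }

    n_genes = len(active.index)
    expression_summary = {
        "n_genes": n_genes,
        "active_per_timepoint": {
            tp: _frac(int(active[tp].sum()), n_genes) for tp in tps
        },
        "degs_per_phase": {
            f"{tps[k]}->{tps[k + 1]}": {
                "up": int((degs_by_phase[k + 1]["direction"] == "up").sum()),
                "down": int((degs_by_phase[k + 1]["direction"] == "down").sum()),
            }
            for k in range(len(tps) - 1)
        },
    }
    deg_dynamics = {
        "counts_per_phase": {
            phase: ct.counts.to_dict() for phase, ct in crosstabs.items()
        },
        "negative_correlation_genes": _frac(len(neg_union), len(deg_union) or 1),
        "negative_correlation_events": _frac(neg_events, n_deg_events or 1),
        "reverse_jmjd2b_genes": len(rev_union),
    }

    report = SummaryReport(
        provenance=config.provenance(),
        expression=expression_summary,
        deg_dynamics=deg_dynamics,
        cascade=cascade,
        complexes=complexes,
        region_distribution=region_distribution,
        overlap_null=overlap_null,
        correlation=correlation,
    )
    report.to_json(out / "report.json")
    report.to_markdown(out / "report.md")
    config.to_yaml(out / "config_used.yaml")
    return report
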