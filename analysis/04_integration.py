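#!/usr/bin/env python
"""Integrate marks with expression: states, dynamics, cascade, complexes.

Runs the full pipeline on the simulated study and prints the headline
summary: the silent-gene JMJD2B/H3K9me3 co-enrichment cascade, the DEG x
H3K9me3 dynamics cross-tab with the negative-correlation subset, complex
occupancy at active promoters, and the genome-wide locus taxonomy.
"""
import argparse
import json
from pathlib import Path

from tscepi.pipeline import AnalysisConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study-dir", type=Path, default=ROOT / "scratch" / "study")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-shuffles", type=int, default=2_000)
    args = ap.parse_args()

    cfg = AnalysisConfig(
        study_dir=str(args.study_dir),
        out_dir=str(ROOT / "scratch" / "pipeline_out"),
        seed=args.seed,
        n_shuffles=args.n_shuffles,
    )
    report = run_pipeline(cfg)

    (ROOT / "results").mkdir(exist_ok=True)
    summary = {
        "cascade": report.cascade,
        "deg_dynamics": report.deg_dynamics,
        "complexes_at_active_promoters": report.complexes,
        "locus_region_distribution": report.region_distribution,
        "overlap_vs_shuffle_null": report.overlap_null,
        "promoter_signal_correlation": report.correlation,
    }
    with open(ROOT / "results" / "04_integration_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    c = report.cascade
    print(
        f"Of {c['n_silent_d0']} silent genes at D0, "
        f"{c['silent_jmjd2b']['percent']}% carry promoter JMJD2B; "
        f"{c['co_enriched_h3k9me3']['percent']}% of those are H3K9me3 co-enriched; "
        f"{c['persistent_co_enriched']['percent']}% of the co-enriched stay so through D6."
    )
    neg = report.deg_dynamics["negative_correlation_genes"]
    print(
        f"{neg['percent']}% of DEGs ({neg['numerator']}/{neg['denominator']}) are "
        "negatively associated with H3K9me3 dynamics; "
        f"{report.deg_dynamics['reverse_jmjd2b_genes']} of them also reverse JMJD2B."
    )
    t = report.complexes["triple_bound"]
    print(
        f"{t['percent']}% of active genes ({t['numerator']}/{t['denominator']}) are "
        "JMJD2B-TFAP2C-LSD1 bound at their promoter."
    )
    for factor, row in report.overlap_null.items():
        print(
            f"{factor} vs JMJD2B: observed {row['observed_percent']:.1f}% of JMJD2B "
            f"peaks co-bound; randomized-control max {row['null_max_percent']:.1f}%."
        )


if __name__ == "__main__":
    main()
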