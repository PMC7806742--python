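#!/usr/bin/env python
"""Call transcriptional states: zFPKM activity and fold-change DEGs.

Fits the zFPKM transform per sample, calls genes active at z > -3 in any
replicate, classifies >1.5-fold DEGs for both differentiation phases, and
scores the calls against the generator's planted truth. Aggregates go to
results/, per-gene tables to scratch/.
"""
import argparse
from pathlib import Path

import pandas as pd

from tscepi.expression import call_active, call_degs, zfpkm_transform
from tscepi.pipeline import AnalysisConfig, load_study_inputs
from tscepi.simulate import load_config, simulate_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study-dir", type=Path, default=ROOT / "scratch" / "study")
    args = ap.parse_args()

    cfg = AnalysisConfig(study_dir=str(args.study_dir))
    inputs = load_study_inputs(cfg)
    truth = simulate_study(load_config(args.study_dir / "config.yaml")).truth

    res = zfpkm_transform(inputs["expression"])
    active = call_active(res)
    rows = []
    for tp in cfg.timepoints:
        t = truth.activity()[tp]
        p = active[tp]
        tpr = (p & t).sum() / t.sum()
        tnr = (~p & ~t).sum() / (~t).sum()
        rows.append(
            {
                "timepoint": tp,
                "n_active_called": int(p.sum()),
                "n_active_planted": int(t.sum()),
                "balanced_accuracy": (tpr + tnr) / 2,
                "fit_mu": res.fits.loc[f"{tp}_r1", "mu"],
                "fit_sigma": res.fits.loc[f"{tp}_r1", "sigma"],
            }
        )
    summary = pd.DataFrame(rows)

    deg_rows = []
    for col, pair in (("deg_early", ("D0", "D2")), ("deg_late", ("D2", "D6"))):
        degs = call_degs(inputs["expression"], pair).set_index("gene_id")
        planted = truth.genes[col]
        called = degs.loc[planted.index, "direction"]
        deg_rows.append(
            {
                "phase": f"{pair[0]}->{pair[1]}",
                "up_called": int((called == "up").sum()),
                "down_called": int((called == "down").sum()),
                "up_planted": int((planted == "up").sum()),
                "down_planted": int((planted == "down").sum()),
                "direction_accuracy": float((called == planted).mean()),
            }
        )
        degs.to_csv(ROOT / "scratch" / f"degs_{pair[0]}_{pair[1]}.tsv", sep="\t")
    deg_summary = pd.DataFrame(deg_rows)

    (ROOT / "results").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "02_activity_calls.tsv", sep="\t", index=False)
    deg_summary.to_csv(ROOT / "results" / "02_deg_calls.tsv", sep="\t", index=False)
    active.to_csv(ROOT / "scratch" / "active_calls.tsv", sep="\t")
    print(summary.to_string(index=False))
    print(deg_summary.to_string(index=False))
    print(
        "zFPKM recovered the planted active/silent split at "
        f">= {summary['balanced_accuracy'].min():.3f} balanced accuracy."
    )


if __name__ == "__main__":
    main()
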