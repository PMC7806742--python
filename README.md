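# tscepi — epigenome–transcriptome integration for differentiating trophoblast stem cells

Trophoblast stem cells (TSCs) differentiate over a D0 → D2 → D6 timecourse
while the histone demethylase JMJD2B/KDM4B, the repressive promoter mark
H3K9me3, and the elongation mark H3K36me3 redistribute over the genome, and
JMJD2B co-binds active promoters with the transcription factor TFAP2C and
the demethylase LSD1. `tscepi` implements the desk half of such a study as a
tested, reusable pipeline for anyone integrating ChIP-seq peak sets with an
FPKM expression table:

- **Active/silent gene calling (zFPKM).** Per sample, with
  `x = log2(FPKM)` over genes with FPKM > 0, the transform fits the main
  density mode `μ` (Gaussian KDE, Silverman bandwidth), takes
  `U = mean{x : x > μ}`, sets `σ = (U − μ)·√(π/2)` (half-normal relation),
  and standardises `z = (x − μ)/σ`. A gene is *active* at a timepoint iff
  `z > −3` in at least one replicate; zero-FPKM genes are auto-silent.
- **DEG classification.** `fold = (FPKM_later + 0.1)/(FPKM_earlier + 0.1)`
  on replicate means; up/down at >1.5-fold in either direction.
- **Regulatory taxonomy.** Promoters are the strand-aware
  `[TSS − 3 kb, TSS + 500 bp)` window; gene bodies are the annotated span;
  putative enhancers are the base-level H3K4me1 ∩ H3K27ac intersection
  outside promoters. Overlap always means ≥ 1 bp intersection of half-open
  intervals; peaks are ranked by linear q-value with a top-65,000 selector.
- **Co-occupancy states and dynamics.** Per gene and timepoint, promoter
  JMJD2B, promoter H3K9me3 and gene-body H3K36me3 presence define one of
  eight states (e.g. `J+K9+K36−`); presence across the timecourse yields
  gain (absence → presence), loss (presence → absence) or persistence per
  differentiation phase, cross-tabulated against DEG direction with the
  negative-correlation rule (up ∧ loss) ∨ (down ∧ gain).
- **Complex assignment.** Each promoter/locus gets one of eight co-factor
  categories (JMJD2B–TFAP2C–LSD1, TFAP2C–LSD1, singles, unbound) from the
  triple of ≥ 1 bp overlap booleans.
- **Shuffle null.** Peaks are re-placed uniformly within their own
  chromosome (length and per-chromosome multiplicity preserved); the
  maximum count of target regions intersected across N shuffles (default
  10,000) is the randomised control for the observed overlap.
- **Metagene profiles.** Scaled-region (flank/TSS→TES/flank) signal
  matrices from bedGraph tracks, strand-aware, plus promoter-signal
  correlation between marks.
- **Synthetic study generator.** `tscepi.simulate` emits a complete toy
  study — genome, BED12 annotation, FPKM table (3 timepoints × 2
  replicates, bimodal log-FPKM mixture), narrowPeak sets per mark and
  timepoint, bedGraph tracks — with a `TruthTable` of every planted label,
  so every classifier above is testable with no sequencing data.

## Worked example

```bash
tscepi simulate --seed 1 --out-dir scratch/study
tscepi run-all --study-dir scratch/study --out-dir scratch/out --n-shuffles 2000
```

prints (abridged; numbers from this exact run):

```
silent-gene cascade: 36% JMJD2B-bound, of which 50% H3K9me3 co-enriched, of which 46% persistent
report written to scratch/out/report.json
```

and the numbered drivers under `analysis/` narrate each stage on the same
study. `analysis/04_integration.py` ends with:

```
Of 1098 silent genes at D0, 36% carry promoter JMJD2B; 50% of those are
H3K9me3 co-enriched; 46% of the co-enriched stay so through D6.
2% of DEGs (5/324) are negatively associated with H3K9me3 dynamics; 2 of
them also reverse JMJD2B.
74% of active genes (299/402) are JMJD2B-TFAP2C-LSD1 bound at their promoter.
TFAP2C vs JMJD2B: observed 46.3% of JMJD2B peaks co-bound; randomized-control max 2.3%.
```

Reading: the simulated study plants a silent-gene cohort in which roughly a
third carry promoter JMJD2B, about half of those are co-marked by H3K9me3,
and a persistent core keeps both marks (and stays silent) through
differentiation; co-factor complexes dominate active promoters while the
TFAP2C–LSD1 pair without JMJD2B sits mostly at enhancers; and the real
co-binding towers over the within-chromosome shuffle control. The pipeline
recovers every planted occupancy state, dynamics label and complex category
exactly, and the planted active/silent split at >99% balanced accuracy
through the zFPKM path (see `results/` and the test suite).

Every percentage in the report is emitted alongside its exact
numerator/denominator, and every number is recomputable from the
intermediate TSVs written next to it.

## Layout

```
src/tscepi/        library: types, io, expression, regions, integration,
                   shuffle, metagene, simulate, pipeline, cli
analysis/          numbered narrative drivers over the library
scripts/           acceptance.py (from-scratch recomputation)
tests/             pytest suite incl. bitmap/bedtools oracles
docs/methods.md    model, parameters, numerical choices, limitations
```
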