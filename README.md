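# katharoseq

Control-based quality control for **low-biomass microbiome sequencing**.

Floors of cleanrooms, hospital surfaces, aquaculture facilities and other
low-biomass environments carry so little microbial material that reagent
contaminants ("kitome") and well-to-well leakage can dominate the reads of
an amplicon or shotgun run. This package implements the bioinformatic half
of the KatharoSeq approach: spiked titrations of positive controls and
co-processed negative controls are used to measure the pipeline's
background contamination, establish a per-study limit of detection, and
derive a read-count threshold below which samples are excluded as
indistinguishable from noise.

## The model

Positive controls carry known cell inputs (by default 5, 50, 500 and 5,000
cells of a single organism, e.g. *Bacillus subtilis*). The fraction *y* of a
control's reads that map to that organism follows the allosteric sigmoidal
(Hill) curve of the input *x*:

```
y(x) = Ymax · x^h / (K½^h + x^h)
```

* With *x* = **input cells**, `K½` is the background contamination load of
  the entire pipeline in cell equivalents: a sample starting with `K½`
  cells yields reads that are half signal, half contaminant.
* With *x* = **read depth**, `K½` (at `Ymax = 1`) is the read count at
  which half of a library is expected to be genuine — a natural
  sample-exclusion threshold.

Around the curve fit, the package provides:

* **Limit of detection** — each titration level is compared against the
  pooled negative controls with a Kruskal–Wallis rank test (exact
  permutation p-values at tiny n), with Benjamini–Hochberg FDR control at
  α = 0.05 across levels; the LOD is the smallest level from which every
  larger level is also distinguishable.
* **Sample exclusion** — thresholds from the Hill fit (`fit_half_max`) or,
  conservatively, the median read depth of the top titration level
  (`max_input_median`); exclusion is boundary-inclusive and recomputed per
  study/run, never reused globally.
* **Contamination reporting** — target-organism reads in negatives and
  true samples quantify well-to-well leakage.
* **A synthetic experiment generator** — seeded count-level simulations of
  the whole titration design, so every stage is testable without any
  sequencing data.

The curve fitting is exposed as a scikit-learn regressor
(`HillCurveModel`) and the exclusion step as a fit/transform estimator
(`ReadCountFilter`); plain functions wrap both.

## Worked example

```python
from katharoseq import (SimulationParams, generate_study, composition_points,
                        fit_hill, limit_of_detection, ReadCountFilter,
                        NEGATIVE_CLASSES)

params = SimulationParams(n_samples=50)          # 4×18 positives, 24 negatives
table, design = generate_study(params, seed=42)
positives, _ = composition_points(table, design, {"extraction_positive"})
negatives, _ = composition_points(table, design, NEGATIVE_CLASSES)

cells_fit = fit_hill([(p.input_cells, p.target_fraction) for p in positives])
print(f"background load K1/2 = {cells_fit.k_half:.1f} cell equivalents "
      f"(h = {cells_fit.h:.2f}, R^2 = {cells_fit.r_squared:.3f})")

reads_fit = fit_hill([(p.depth, p.target_fraction) for p in positives],
                     ymax_mode="fixed_1", x_variable="reads")
print(f"50%-composition read count = {reads_fit.k_half:.0f} reads")

lod = limit_of_detection(positives, negatives, metric="target_fraction")
print(f"limit of detection (composition) = {lod.lod_cells:g} cells")

filt = ReadCountFilter(strategy="max_input_median")
filtered = filt.fit_transform(table, design)
print(f"exclusion threshold = {filt.threshold_:.0f} reads; "
      f"retained {filtered.n_samples} of {table.n_samples} samples")
```

Output:

```
background load K1/2 = 97.9 cell equivalents (h = 1.39, R^2 = 0.999)
50%-composition read count = 726 reads
limit of detection (composition) = 5 cells
exclusion threshold = 2247 reads; retained 25 of 146 samples
```

The fitted `K½` of 97.9 cells recovers the generator's true background of
96.88 cell equivalents; the 2,247-read threshold is the median depth of
the 5,000-cell controls, and the 121 excluded columns are low-biomass
samples and controls whose libraries are mostly contaminant.

The same pipeline runs from the shell:

```bash
katharoseq simulate --seed 42 -o sim/
katharoseq run -t sim/table.tsv -m sim/metadata.tsv -o qc/
# qc/ -> decisions.tsv, summary.json, filtered_table.tsv, lod_*.tsv
```

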