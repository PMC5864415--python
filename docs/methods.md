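# Methods

## The QC procedure

Low-biomass sequencing runs mix three read sources: genuine sample
material, reagent/laboratory contaminants, and well-to-well leakage. The
package quantifies the first two and flags the third using only the
co-processed controls of a run:

1. **Composition points.** For every extraction positive control, the
   target fraction is the share of its reads assigned to features matching
   the expected organism (lineage substring, case-insensitive, or an
   explicit feature-id set), computed on raw integer counts with a single
   final division. Zero-depth controls are reported, never silently
   dropped — a composition is undefined without reads.
2. **Hill fits.** The target fraction is regressed on input cells and,
   separately, on read depth with `y = Ymax·x^h/(K½^h + x^h)`. The
   cells-variable `K½` is the background contamination load in cell
   equivalents; the reads-variable `K½` (at `Ymax = 1`) is the read count
   at which a library is half signal.
3. **Limit of detection.** Each titration level is tested against the
   pooled negatives (Kruskal–Wallis, two groups), BH step-up across the
   levels of one metric at α = 0.05. The LOD is the smallest level from
   which **all** larger levels are also significant, which forbids
   non-monotone detection claims.
4. **Exclusion.** A read-count threshold is derived per study/run and
   applied boundary-inclusively to every sample; retained counts are not
   renormalized. Success rates are retained/total within a sample class.
5. **Contamination report.** Target-organism fractions in negatives and
   true samples; samples above the 95th percentile (configurable) of the
   negatives' distribution are flagged as likely well-to-well leakage.

## Model assumptions

* The Hill form is fitted on linear x (not log x). Under this convention
  the closed-form inversion through the mean compositions at 50 and 500
  cells recovers a background load within 0.5% of the value the full
  titration fit converges to (see `scripts/acceptance.py`).
* The positive-control organism is assumed absent from the true samples'
  environment, so its reads in non-positive wells measure leakage.
* Composition is computed on raw deblurred/denoised counts; no
  rarefaction. Depth semantics stay exact — fractional counts are
  rejected, not rounded.

## Fitting details

* `ymax_mode="free"` (default) estimates the plateau with bound
  `Ymax ∈ (0, 1]` and needs ≥ 3 distinct dose levels; `"fixed_1"` pins
  `Ymax = 1` and needs ≥ 2. Bounds: `K½ > 0`, `h ∈ (0.1, 10]`.
* Initialization is deterministic: the closed-form two-point solution
  through the mean response at the smallest and largest positive dose
  (fallback: median dose, `h = 1`). No random restarts.
* Trust-region least squares with tolerance `1e-8` on parameters and
  objective; `converged` records the optimizer's status.
* With exactly two distinct doses and fixed plateau, the weighted
  least-squares solution interpolates the level means and is computed in
  closed form — no iteration, exact agreement with `solve_two_point`.
* A response with no variance refuses the fit (`converged=False`,
  `r_squared=NaN`) rather than returning an arbitrary curve.
* Weights are optional (`sample_weight`); default unweighted. `R²` is
  `1 − SSres/SStot` about the (weighted) mean.
* `invert_hill` is the closed form `x = K½·(y/(Ymax−y))^(1/h)`; inverting
  at `y = Ymax/2` returns `K½` exactly.

## Statistical details

* Kruskal–Wallis uses midranks with tie correction and the chi-square
  approximation (df = groups − 1). For two groups with total n < 8 the
  package switches to an exact permutation p-value over all
  `C(n, n₁)` assignments; at such sizes the exact test is conservative
  by construction (the attainable size at α = 0.05 with 5+5 observations
  is ≈ 0.032 because p-values move in steps of the rank-sum counts).
  Calibration at the design sizes actually used (18 replicates vs 24
  negatives) is ≈ 0.048.
* BH is the step-up rule, boundary inclusive: reject every ordered
  `p(i)` with `i ≤ max{i : p(i) ≤ i·α/m}`. The FDR family is the set of
  testable levels of one metric; levels with fewer than two usable points
  are excluded from the family and logged. Family choice across metrics
  or kits is intentionally not pooled — the minimal per-metric family is
  the least surprising reading of a per-level FDR.
* Identical observations across all groups give `(H, p) = (0, 1)`.

## Exclusion conventions

* `max_input_median` (default, conservative): median depth of positives
  at the top titration level; even counts take the lower central value so
  the threshold is always an observed depth and never excludes a sample
  that outperformed half the top controls. Invariant under duplicating
  the whole control set.
* `fit_half_max` (permissive): ceil of the reads-fit inversion at 50%
  composition; refused with a pointer to `max_input_median` when the
  fitted plateau never reaches 0.5 or the fit did not converge.
* Retention is `depth ≥ threshold` ("at least" semantics). Thresholds are
  derived from each run's own controls.

## The synthetic generator

`SimulationParams` defaults define the emulated study: titration levels
(5, 50, 500, 5,000 cells) × 18 replicates, 24 extraction negatives, true
background `K½ = 96.88` cell equivalents, `h = 1.377`, `Ymax = 1`, median
top-level depth 2,000 reads with log-normal noise `σ = 0.5`, 40 background
taxa under a symmetric Dirichlet (α = 0.5), 50 true samples with
log-uniform biomass over 5–5,000 cells, leakage rate 0.002.

* **Composition:** target reads are `Binomial(depth, hill(c))`; the rest
  is Dirichlet-multinomial over background taxa. At `c = K½` the expected
  target fraction is `Ymax/2` by construction.
* **Depth:** mean `D_neg + (D_max − D_neg)·hill(c; k_depth, h_depth)/
  hill(c_max)` with multiplicative log-normal noise. The additive floor
  `D_neg = 150` reads gives blank wells a realistic nonzero yield —
  DNA-free wells amplify reagent contaminants rather than producing empty
  libraries — and keeps negatives usable in the rank tests. The
  depth–cells coupling is an explicit, replaceable convention
  (`depth_k_half`, `depth_h`).
* **True samples** carry their own community taxa; the share of their
  reads that is genuine follows the same Hill curve of their latent
  biomass, and leakage injects `Binomial(depth, leakage_rate)` target
  reads, so an observed target fraction in a contaminated sample estimates
  the leakage rate directly.
* One `numpy` Generator per call; a fixed seed is bit-reproducible.

What the generator does **not** emulate: sequence-level error, chimeras,
taxon-specific amplification bias, batch/plate effects, cross-run depth
drift, and compositional correlation among contaminant taxa. Tests passing
on these simulations therefore validate the estimators' self-consistency
and calibration, not robustness to those real-data pathologies.

## Problem sizes

Simulation-backed tests use the default design (96 control wells) over
tens of seeds, and calibration checks use 2,000 null replicates at the
18-vs-24 design; the whole suite completes in a few seconds on one core.

## Known limitations

* The method excludes whole samples; it does not remove contaminant
  features from retained samples.
* Two-group exact permutation p-values only; k-group exact enumeration is
  not implemented (the asymptotic path handles k groups).
* BIOM support covers count tables with taxonomy observation metadata;
  other observation/sample metadata are ignored on read and not written.
* `fit_half_max` assumes the reads-vs-composition relationship is
  monotone within a run; heavily contaminated runs where no library
  reaches 50% target composition must fall back to `max_input_median`.
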