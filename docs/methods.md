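# Methods

## Scope

`lipotrace` covers the quantitative chain of a leukocyte lipid-trafficking
study: single-cell readout tables → per-well QC and standard-based
normalization → per-subject readouts → composite scores (UPT, LiM, LT,
polygenic integration) → within-group quintile stratification with odds
ratios, confidence intervals and exact tests. Because real data of this kind
live behind biobank access controls, the package ships a synthetic study
generator whose structure matches what the analysis assumes, plus small
rendered microscope fields with planted ground truth to validate the
cell-quantification step. Wet-lab and upstream imaging steps (staining,
confocal acquisition, deconvolution, production segmentation) are out of
scope; the image module's quantifier is a minimal, verifiable stand-in, not
a segmentation pipeline.

## Cell-level pipeline

Processing of the single-cell table follows high-content-screening
convention, with these fixed rules:

* **Outlier filter.** Within each well, cells whose area or mean LDL
  intensity deviates more than 5 SD from the well mean are dropped. Mean and
  sample SD are computed once on the unfiltered well (single pass, not
  iterated — no iteration count is defensible, and one pass is
  order-independent). Wells with fewer than two cells, or zero SD, pass
  through unchanged. The filter is applied per well; plate- or dataset-level
  pooling would let batch effects masquerade as outliers.
* **Cell-type gate.** Lymphocyte iff area < 115 µm², monocyte otherwise;
  the boundary value 115 µm² itself is a monocyte ("under" read strictly).
  The cutoff is taken as given from prior marker-based calibration.
* **Well summaries and QC.** Arithmetic means per well × cell type;
  LD-Pos summarizes to the positive-cell fraction. Wells with < 50 cells of
  a type fail QC and are excluded, never imputed.
* **Standard-based normalization.** Each well mean is divided by the mean
  of the QC-passing standard-sample well means of the same normalization
  batch, cell type, condition and readout. When both standard samples pass
  QC their well means are pooled into one divisor (they are replicate
  anchors of the same reference material). A batch with no valid standard
  yields missing values for all its wells.
* **Replicate averaging.** The subject readout is the unweighted mean of
  the QC-passing normalized wells (up to 4 wells × 2 experiments = 8); the
  number of contributing wells is recorded. Readouts are missing when all
  wells fail.

The pipeline output is invariant under permutation of input rows, and — by
construction of the normalization — independent of multiplicative batch
effects, exactly so at zero noise.

## Score construction

UPT, LiM and LT are defined in the README. Two compositions of LT are
genuinely defensible readings of the score hierarchy and both are
implemented behind `lt_composition`:

* `upt_composite` (default): LT averages the rescaled LiM with the two
  rescaled condition-level UPT composites (each weight 1/3).
* `raw_readouts`: the four raw uptake readouts are rescaled individually
  and averaged with LiM (weights 1/5 in LT).

Rescaling is literal min–max to [0, 1] over the entire dataset, applied
after forming the UPT composites (the composite, not its inputs, is the
quantity being placed on a common scale with LiM). Min–max rather than
quantile scaling: the target is range alignment, not distribution reshaping.
A constant vector has a degenerate range and is rejected rather than mapped
arbitrarily. Missing values stay missing, never enter the range, and
propagate through every mean. Fold-change denominators are guarded at
ε = 1e−12; a subject with a zero lipid-poor readout gets a missing LiM.

The polygenic score is min–max rescaled and inverted (1 − x*) so that, like
LT, higher values point toward lower circulating LDL-C; `LDL-PRS-LT` is the
unweighted mean of LT and the inverted-rescaled PRS (no weighting is
assumed; the weight is exposed as a parameter).

## Stratification statistics

* **Quintiles** are assigned within each subject group separately, by
  stable ascending sort; the lowest and highest focus quintiles contain
  exactly ⌈n/5⌉ subjects (the only rule consistent with all published focus
  sizes: 135→27, 134→27, 133→27, 131→27, 39→8). The middle ranks are split
  as evenly as possible over Q2–Q4.
* **Odds ratios** use OR = ad/bc on the focus-vs-rest × outcome table. Any
  zero cell triggers the Haldane–Anscombe correction (+0.5 to every cell;
  flagged `is_estimated`), and the Woolf CI
  exp(ln OR ± z·√(Σ 1/cell)) is then computed on the corrected cells too,
  for internal consistency. z defaults to the conventional 1.96 (this — not
  the exact 0.975 quantile — reproduces published CIs at printed precision).
* **Fisher exact p** (always on the raw integer table) is two-sided by the
  probability-mass criterion: the sum of hypergeometric probabilities of
  tables no more probable than the observed one.
* **Spearman** correlations use average ranks for ties with the asymptotic
  t-distribution p-value; **Mann–Whitney U** is two-sided, exact for small
  tie-free samples (both n ≤ 20) and tie-corrected normal approximation
  otherwise; completely tied data give p = 1. R² is the squared Pearson
  correlation ("coefficient of determination" in its standard sense).
* No multiple-testing correction is applied anywhere; all p-values are raw.

## Synthetic cohort generator

Defaults are the study conditions: 135 controls and 133 statin-monotherapy
recipients, 39 of them on a high-intensity statin (HIS: rosuvastatin
5–40 mg or atorvastatin 10–80 mg, the dose ranges with > 40% LDL-C-reduction
potential; HIS is drawn as a subset of the statin rows and the generated
doses re-derive the membership).

* **Latent traits.** Per-subject LDL-uptake and lipid-mobilization
  capacities are Beta(2, 2) on [0, 1] (bounded, centered, configurable)
  with a Gaussian-copula correlation (default 0.3 — related but distinct
  trafficking traits).
* **LDL-C.** Baseline is lognormal with control mean 3.48 mmol/L
  (σ = 0.25) plus a polygenic log-scale slope (0.08 per SD of the raw PRS,
  giving the positive PRS–LDL-C coupling). On statin:
  `LDL-C = baseline × (1 − effect × latent_uptake) × lognormal noise
  (σ = 0.15)` with effect 0.56 (statin) and 0.84 (HIS), so the arm-mean
  reductions are 28% and 42% — matching the observed statin-arm mean
  (≈ 2.5 mmol/L from 3.48) and the > 40% HIS reduction potential — and the
  within-arm uptake–LDL-C rank correlation is negative, more strongly in
  the HIS arm. Setting the effects to 0 is the null configuration.
* **CVD events.** Logistic in latent mobilization:
  `p = expit(logit(base) − slope·(latent_mob − 0.5))` with base rates
  0.06/0.12/0.13 and slopes 1.0/1.8/3.0 for control/statin/HIS. Event dates
  are uniform over the register period; diagnoses carry I21/I22/I63/I61
  codes (plus unrelated background codes), so the I2X/I6X prefix rule
  re-derives the planted flags.
* **Registers.** Statin subjects get ~6 purchases before sampling at
  ≈ 115 ± 12-day intervals of 100-tablet packages (adherence ≈ 0.87), plus
  one refill after sampling so the last-package adherence ratio is defined.
  The 6-month window is 183 days (calendar-month arithmetic is ambiguous);
  whether the sampling day itself counts is a config switch
  (`window_inclusive`, default off — not stated, not assumed). A single
  in-window purchase defines the type by itself. The I2X wildcard is a
  literal 2-character prefix match (so I20 angina would match; the printed
  wildcard is followed as written).
* **Plates.** Subjects are partitioned over plate batches; each
  (plate batch × experiment) is a normalization batch with a lognormal
  multiplicative effect (σ = 0.15) applied to intensities and count rates,
  plus per-well effects (σ = 0.05). Cell counts are Poisson (default mean
  1200/well, 80% lymphocytes — several hundred monocytes per well); areas
  are a two-component lognormal mixture (medians 70 and 180 µm², σ = 0.18)
  around the 115 µm² gate. Organelle counts are Poisson with rate
  ∝ (0.5 + latent_uptake), × 1.8 in lipid-poor medium; droplet counts are
  Poisson with a rich:poor rate ratio 1 + 2·latent_mobilization (ratio 2 at
  the latent midpoint). Standards have both latents fixed at 0.5 — a stable
  normalization anchor re-measured in every batch. `noise_scale = 0`
  replaces every draw by its expectation, giving the exact-cancellation
  regime the invariance tests use.

### What the generator does not emulate

Real NMR covariance structure (subclass concentrations are simple monotone
functions of the lipid panel with lognormal noise), population sampling
design, genotype-level PRS computation (the PRS enters as one number per
subject), informative missingness, cell-cycle or viability structure, and
any spatial plate-layout artifacts (row/column gradients). Passing tests
therefore demonstrate the correctness and invariances of the analysis
chain under the assumed generative structure — not that the biological
effect sizes would be recovered from real assay data.

## Image fixtures

Fields are 2-channel 16-bit images with non-overlapping disk cells (channel
0) and Gaussian organelle spots (amplitude 2000, σ = 1.5 px) planted on
integer pixels ≥ 7 px apart inside the cell (channel 1), over background
100 with optional Gaussian noise. Pixel size defaults to 0.3 µm/px so the
115 µm² gate corresponds to realistic pixel areas. The quantifier uses a
global Otsu threshold + connected components for cells and per-cell local
maxima for spots, with a cell-adaptive threshold
`bg + max(6·MAD-noise, 20% of the cell's dynamic range, 1)`. At zero noise
recovered counts equal planted counts exactly; at moderate noise (sd 100,
5% of spot amplitude ≥ 95% of cells recover exact counts. Degenerate
(constant or saturated) images produce zero records with a warning.

## Problem sizes

Replicate-heavy tests run scaled-down studies (e.g. statin arm n = 60 with
20 HIS, 2 wells × 2 experiments per condition, 80 cells/well, monocyte-only
wells) — large enough that per-subject readout error is ~2% and the
qualitative orderings are stable across 100 seeded replicates, small enough
to keep the whole suite fast. Generator defaults remain at study scale.

## Known limitations

* The LD-Pos readout is not multiplicative in batch effects (positivity is
  1 − exp(−λ)), so its normalization cancels batch effects only
  approximately at finite noise; exactly at `noise_scale = 0`.
* LT's affine invariance to raw-readout transforms is exact for readouts
  that are min–max rescaled directly (the `raw_readouts` composition, or
  joint transforms of a condition's two uptake readouts under the default);
  a transform of a single UPT constituent re-weights the composite and is
  not removed.
* The Fisher/Mann–Whitney implementations defer to scipy; their exactness
  is cross-checked against enumeration oracles only up to the instance
  sizes the tests cover (n ≤ 40 tables, n ≤ 12 rank configurations).
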