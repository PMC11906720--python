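# Methods

## The clock model

Age is modeled as a linear function of percent methylation (beta) at a
panel of CpG sites: `age = b0 + Σ w_j beta_j`. The bundled 25-CpG model
carries one coefficient per site in years per percent-methylation unit
(e.g. +0.2441 for the KLF14 site: a 10-point rise in beta adds ~2.4
years to the estimate). Coefficient magnitudes only span a plausible
human age range when betas are on a 0–100 scale, so the bundled model's
`beta_scale` is percent; `predict_age` converts automatically when a
model is expressed on the 0–1 fraction scale. The bundled model has no
intercept because its source does not publish one; rather than invent a
number, prediction with it refuses to run until
`calibrate_intercept(model, betas, known_ages)` sets
`b0 = median(age_i − Σ w_j beta_ij)` from at least one calibration
sample. The median is used for robustness to outlying calibration
samples and makes repeated calibration idempotent.

## Elastic-net solver

`enet_fit` minimizes `(1/2n)·RSS + λ(α‖w‖₁ + (1−α)/2‖w‖₂²)` by cyclic
coordinate descent with soft-thresholding. This is the objective
convention of the widely used R solver, so published (α, λ) values are
directly meaningful; λ is *not* rescaled by n. Numerical choices:

* predictors standardized to mean 0, sd 1 (population sd) on the data
  given to the fit; coefficients destandardized before return. Penalties
  are scale-sensitive and betas at different CpGs have very different
  variances, so standardization is the default (configurable);
* convergence when the largest per-sweep coefficient change (on the
  standardized scale) falls below 1e-7; hard failure with diagnostics
  after 10,000 sweeps;
* the penalized objective is evaluated every sweep and asserted
  non-increasing (coordinate descent on this convex objective can never
  increase it; a violation means a numerical bug);
* constant (zero-variance) columns get coefficient 0;
* warm starts are used inside cross-validation loops — they change
  iteration counts, not solutions, which is checked by a test comparing
  against cold-started refits.

Hyperparameters are tuned by grid search under leave-one-out
cross-validation: for each (α, λ) the model is refit n times, each time
predicting the held-out sample; the grid point with the smallest mean
squared LOO error wins, with ties broken toward larger λ then smaller α
(more regularization). Tiny default grids
(α ∈ {0.01, 0.1, 0.5, 1}, λ ∈ {0.01, 0.1, 1.2, 10}) keep n·|grid|
refits cheap at panel scale.

## Training protocol

`train_clock` reproduces the standard protocol end to end: an
age-stratified 70/30 split (decade strata `[20,30), [30,40), …` —
"balanced ages" is read as decade stratification; the exact bin edges
are a package choice), grid search by LOOCV on the training set, a
final fit at the chosen point, held-out test evaluation, and finally
LOOCV predictions over the *whole* cohort at the chosen hyperparameters
as the least-biased accuracy estimate. The split uses
largest-remainder allocation so the overall train count is the rounded
fraction of n while each stratum stays within one sample of the target
share. Headline accuracy is the **median** absolute error (MAE) in
years — deliberately the median, which is how this assay family reports
it — alongside the mean AE, Pearson r with its two-sided t-transform p
value, the fraction of predictions within ±5 years (boundary
inclusive), and per-decade MAE.

## Synthetic data generator

The generator emulates the study design this assay family uses, not any
particular cohort:

* **Cohort**: decade-stratified ages on [20, 80) with default weights
  (1, 1, 1, 1, 2, 1.5) — the ≥60 strata are deliberately over-weighted,
  mirroring the elderly-enriched recruitment that damps epigenetic-drift
  noise during training. Ages are uniform within a decade; sex is an
  independent coin flip.
* **Betas**: each site's mean beta is affine in age with slope
  `w_j / Σw²` (so the clock sum gains exactly one year per year) and
  baseline 50% at age 50. Two variance components are added: (i)
  between-individual variation (sd 3 percentage points) drawn in the
  null space of the coefficient vector — it decorrelates the sites, as
  in real cohorts, but cancels exactly in the clock sum, keeping the
  noise-free age relation exact and the generating coefficients
  identifiable; (ii) independent per-CpG Gaussian noise (default sd 3
  points), which does perturb predicted age. Betas are clipped to
  [0, 100]; with the default baselines clipping only engages at extreme
  ages or noise levels.
* **Reads**: per molecule, CpG states are Bernoulli(beta/100); both
  bisulfite strands (OT/OB) are simulated with equal probability (PCR
  amplifies both converted strands). Non-CpG cytosines are treated as
  unmethylated. Conversion failure (unmethylated C read as C, default
  0.005) and over-conversion (methylated C read as T, default 0.001)
  apply outside primer footprints; inside a footprint the synthetic
  primer oligo fixes every base, with degenerate Y/R positions resolved
  to match the molecule's methylation state — which is exactly why the
  assay's primers are degenerate. Inserts shorter than the 150 bp read
  length read through into the opposite adapter (beginning
  `AGATCGGAAGAGC`, then the full adapter sequence, then G — the
  two-color no-signal call). Substitution sequencing errors (default
  0.001/base) are uniform; there are no indels, PCR bias or chimeras.
  Qualities are constant Q37 by default, with an optional decaying-tail
  model to exercise quality trimming.

Because the simulator omits indels, context-dependent error, PCR
duplication and real between-CpG covariance structure, passing tests
demonstrate correctness of the pipeline's logic and statistics — not
performance on real instrument data. The default noise magnitudes are
stated assumptions typical of bisulfite assays, not fits to any
dataset.

The shipped amplicon reference is synthetic (random CG-free filler with
CG planted at the published site offsets and primer-compatible ends,
`data/amplicons.synthetic.fa`, fixed build seed); real GRCh38 sequence
can be substituted via the FASTA argument of `load_regions`.

## Read processing

Trimming follows the established two-step contract: two-color quality
trimming at Q30 (G bases are scored as quality cutoff−1 in the
running-sum trim, because a high-confidence G call is indistinguishable
from signal dropout on two-color chemistry), then semi-global
suffix/prefix adapter matching (min overlap 3, max error rate 0.1, ties
to the longest removal). The pass is iterated to a fixed point: adapter
removal can expose a fresh low-quality 3' end, and a single pass is
then not idempotent; on realistic reads one pass suffices. The length
filter keeps a pair only when **both** mates are strictly longer than
20 bp (the conventional paired-mode reading).

Alignment is ungapped sliding-window scoring (+1/−1) in bisulfite
converted space against both strands of every amplicon — amplicons are
fixed-length PCR products, so gaps buy nothing against this simulator;
this is a documented limitation for real data containing indels. A tie
in best score across regions, or a best score below 0.6× the total
trimmed read length, leaves the pair unassigned (conservative "unique
mapping"). Mate-overlap positions are called once, from mate 1, so each
molecule contributes a single count; primer-footprint CpGs are never
called. Zero-coverage cells are missing betas, never 0, and samples
with a missing beta at any model CpG are rejected at prediction time by
default (mean imputation is available but off).

## Problem sizes

The end-to-end checks run a 150-sample cohort at 400 read pairs per
region with per-CpG noise sd 3. The depth was chosen from the variance
budget: binomial sampling at depth 400 adds ≈5–6 percentage-points² of
beta variance on top of the 9 from the noise term, predicting an
age-error sd near 3.5 years and a median absolute error near 2.4 — the
observed LOOCV MAE. Calling-exactness checks use 2,000 pairs per region
(10,000 total) with all error processes disabled, where calls must
equal the simulator's molecule truth table exactly and betas of 0/100
must be recovered without tolerance; intermediate betas are checked
against a simultaneous (Šidák-adjusted) 99% binomial band across the
panel's CpGs.

## Known limitations

* No genome-wide alignment: reads are assigned to the five known
  amplicons only.
* Ungapped alignment; indel-containing real reads would be penalized or
  dropped.
* The published model's intercept is unknown; absolute predictions with
  the bundled coefficients are only as good as the calibration cohort.
* λ printed for the published fit is stored as metadata; whether it was
  on a standardized-response scale is not stated by its source, so it is
  never used to re-derive fits.
* The simulator's noise model is substitution-only and site-independent.
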