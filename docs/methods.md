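# Methods

`embryocnv` studies why human IVF embryos arrest before the blastocyst
stage, by combining three pieces: a mechanistic cohort simulator, a
copy-number displacement caller for bulk low-coverage sequencing of
multi-cell embryo samples, and the association/mixed-model statistics that
relate aneuploidy and cleavage behaviour to developmental outcome.

## The measurement model

Preimplantation genetic testing for aneuploidy (PGT-A) sequences a 5–10-cell
trophectoderm biopsy (or, here, the entire cell mass of an arrested embryo)
at low coverage and bins reads on a fixed genomic grid. Normalized read
depth is linear in the mean chromosome copy number of the sampled cells, so
a chromosome's *displacement*

> d = |ĉ − 2| × 100  (percent of a full single-copy change)

interpolates between disomy (d = 0) and a constitutional trisomy/monosomy
(d = 100). Because a meiotic error is present in every cell while a mitotic
(post-zygotic) error is confined to a clone, the displacement separates the
two origins in a bulk sample: d > 70 is called meiotic, 30 ≤ d ≤ 70 mitotic
(mosaic), d < 30 normal disomy. Both boundary values are assigned to the
mitotic range. Sex chromosomes (whose baseline depends on the inferred sex)
and arm-scale segmental events (lower signal-to-noise) are called but never
stratified by origin.

Numerical conventions in the caller:

- Bins are 0-based half-open, tiled per chromosome arm (no bin spans the
  centromere), on a packaged GRCh38-like karyotype table with centromeres
  rounded to whole Mb. Default bin size 1 Mb (the platform's true grid is
  proprietary; 1 Mb reproduces arm-level events comfortably).
- Per-bin ratio = count / median autosomal bin count; per-chromosome copy
  ĉ = 2 × 10%-trimmed mean of the chromosome's ratios (robust to single-bin
  CNV/breakpoint artifacts). No GC correction: simulated counts carry no GC
  bias; a hook exists at the normalization step.
- Displacements are rounded to 1e-6 before thresholding, so analytically
  exact fractions (3 trisomic cells in 10 → d = 30) land on the boundary
  rather than half an ulp away.
- A whole-chromosome call requires *both* arms displaced ≥ 30% in the same
  direction; a single displaced arm is a segmental call even when it drags
  the chromosome mean over 30%. Arms represented by fewer than 5 bins are
  not resolved separately (the chromosome mean decides). A one-changepoint
  binary-segmentation step confirms the within-chromosome split; sub-arm
  changepoints are merged up to arm scope — the minimum reportable segment
  is one full arm.
- Technical noise is summarized as the median absolute deviation between
  adjacent autosomal bins (MAPD); samples above 0.15 are QC-excluded, a
  distinguished result rather than an error.
- Profiles where fewer than half of the autosomes sit below d = 30 are
  flagged `baseline_unreliable`: median normalization is biased when most of
  the genome is displaced. Genome-wide ploidy changes (triploidy, balanced
  tetraploidy) are *invisible by construction* under median normalization —
  the simulator demonstrates this and such embryos are out of scope.

## The cohort simulator

The generator's defaults encode the study conditions rather than
convenience values: 125 patients (1 + Poisson(0.32) cycles each, ≈165
cycles), maternal age ~ N(38.9, 3.5²) truncated to [30, 45], Poisson(7.2)
normally fertilized zygotes per cycle.

**Meiotic errors.** P(≥1 whole-chromosome meiotic error) =
invlogit(0.80 + 0.261·(age − 38.9)); affected autosomes drawn without
replacement with 3× weight on chromosomes 15, 16, 19, 21 and 22; error
count 1 + Poisson(1); gain/loss equiprobable. The intercept is calibrated
to the study's implied *population* euploid fraction (~0.18) rather than
its tested-sample fraction (22.6%), because the study tested only half of
its arrested embryos while the simulator samples every embryo.

**Cleavage and mosaicism.** Three division rounds are simulated explicitly.
The first division is abnormal with probability 0.26 (multipolar 0.40 /
precocious 0.35 / reverse 0.12 / failed 0.13); an abnormal second division
occurs in a further 9.7% of embryos. A tripolar (multipolar) division
distributes each chromosome's four replicated chromatids over three
daughters — with probability 0.55 the homologs share one pole pair,
producing the (2,2,0) nullisomy pattern — so hypodiploid, partially
complementary clones arise mechanically and copy number is conserved (the
daughters' copies sum to 4 per chromosome). Precocious cleavage is a normal
division followed by a premature tripolar split of one daughter; failed and
reverse cleavage double the genome without cytokinesis, and such polyploid
cells undergo chaotic (tripolar) divisions with probability 0.9 at later
rounds. Normal divisions missegregate each chromosome reciprocally (one
daughter +1, the other −1) at 5 × 10⁻⁴ per chromosome, with a rarer
single-arm variant. The mitotic age trend (0.009 logits/year, i.e. flat)
acts on every mitotic channel so the generated marginal follows the
configured slope. Mosaic fractions are never drawn: the founders are
expanded multinomially with Dirichlet(1)-varied clone proportions (an
optional fitness penalty against aneuploid clones exists, default off), and
trophectoderm biopsies take a *contiguous* window of the lineage-ordered
cell sequence, so biopsy mosaic fractions emerge from clonal sampling.

**Outcome.** Arrest is Bernoulli with logit = −1.66 + 0.60·min(n, 5) +
1.6·[abnormal division] + patient effect, where n counts chromosomes hit by
meiotic or first/second-round mitotic events (third-round events touch only
~1/8 of cells and are excluded from the risk predictor; capping at 5
mirrors the ≥5 complexity bin and keeps chaotic embryos below certainty).
The patient random intercept is N(0, 0.5²), drawn once per patient. The
intercept gives the 16% euploid arrest baseline; b1 and b2 were calibrated
once so the category-wise marginal arrest rates reproduce the ~0.36
(meiotic-only) and 0.55–0.64 (mitotic-containing) pattern, then frozen.
Arrested embryos receive a stage (earlier for more abnormal lineages; early
≤ 10 cells); blastocysts grow to ~110 cells, receive correlated ICM/TE
grades from a shared latent score shifted one unit toward D under
aneuploidy (reproducing the ~20→90% aneuploidy gradient from best to worst
grades), and a biopsy day 5 + Binomial(2, 0.35 + 0.11·aneuploid), i.e. a
+0.22-day mean shift.

**Reads and QC.** Expected bin count = depth × (mean arm copy across
sampled cells)/2 + a small copy-independent background; counts are negative
binomial (depth 300/bin, overdispersion 0.005 → MAPD ≈ 0.09, comfortably
under the 0.15 QC threshold; ~1M reads per sample). QC failures corrupt the
profile with heavy multiplicative noise; the failure probability is 2% for
biopsies but 35% for whole-embryo samples of ≤ 5 cells, reflecting
amplification failure from minimal input DNA — overall exclusions land near
6%, skewed toward arrested embryos as in the motivating data (6.1% of
arrested vs 2.0% of biopsies).

**What the simulator does not emulate:** GC and mappability bias,
amplification artifacts beyond NB overdispersion, parent-of-origin
structure, triploidy as a detectable state, sub-arm segmental events,
cell-death dynamics beyond the optional fitness penalty, or time-lapse
imagery (division patterns are symbolic). Passing tests therefore show that
the calling thresholds and statistics behave correctly for data whose noise
is well modelled; they do not certify performance on real WGA sequencing.

## Statistics

- Pearson chi-squared without continuity correction; Fisher's exact test
  with two-sided probability-mass ordering, the conditional-MLE odds ratio
  and its exact conditional CI (the sample odds ratio is reported
  alongside; with a zero cell the OR is 0 or ∞ with a one-sided CI; with a
  degenerate margin it is undefined/NaN).
- Quasi-binomial and quasi-Poisson trend models: point estimates are the
  ordinary GLM estimates; the dispersion is the Pearson statistic over
  *rows* divided by residual df (for per-cycle successes/trials responses
  each cycle is one row, matching R's `quasibinomial` — note that treating
  each trial as a unit would understate the dispersion several-fold), and
  only rescales the standard errors. Slopes beyond |15| logits flag
  separation. No multiple-testing correction anywhere; p-values are
  reported unadjusted.
- The binomial GLMM (arrest ~ predictor + patient random intercept)
  maximizes the exact marginal likelihood by *adaptive* Gauss–Hermite
  quadrature: per-patient Newton search for the posterior mode and
  curvature, then a 15-node Hermite rule on the re-centred integrand;
  Laplace is the 1-node special case and is used automatically when more
  than 50 clusters exceed 200 observations. Optimization is BFGS on
  (β, log σ) with a Nelder–Mead polish; the covariance is the inverse
  numerical Hessian. Effects are reported as average marginal effects:
  population-averaged probabilities ∫ invlogit(xβ + b) φ(b; 0, σ̂) db per
  level, differenced against the Euploid reference (or the average
  derivative for numeric predictors), with delta-method CIs and an optional
  seeded parametric bootstrap. With σ = 0 the integral collapses exactly to
  the plain logistic probability.
- The biopsy-day model is a REML linear mixed model (statsmodels MixedLM);
  for a binary predictor its AME equals the fixed coefficient.

## Problem sizes

The test suite and the acceptance script run the full default cohort
(~1,200 embryos, ~3,100 one-megabase bins per sample) end to end; parameter
recovery uses 50 replicate truth-only cohorts for the quasi-binomial age
trends and 200 replicates of 30 patients × 8 embryos for GLMM coverage —
sizes at which the Monte-Carlo error of each checked quantity is well below
the width of its acceptance band.

## Known limitations

- Median normalization makes uniform genome-wide changes invisible and
  biases displacement when many chromosomes are affected (flagged, not
  corrected).
- Whole-chromosome mitotic events at a mosaic fraction near the 30%
  boundary can be split between segmental/whole scope by arm-level noise.
- GLMM CIs are Wald-type; coverage at very small cluster counts can dip a
  few points below nominal.
- The commercial platform's normalization internals are proprietary; this
  caller is an independent implementation of the displacement idea, not a
  re-implementation of that software.
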