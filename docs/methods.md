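# Methods

## The model

`panprog` ranks genes by their association with patient survival using
four omics layers measured on the same tumors: gene expression (GE),
somatic copy-number alteration (SCNA), DNA methylation (DM) and miRNA
expression mapped onto target genes (ME). All layers are gene × sample
matrices; survival is right-censored follow-up time with a death
indicator.

**Stage 1 — voting screen.** For every gene and every layer a univariate
Cox proportional-hazards model

    h(t | x) = h0(t) · exp(β x)

is fitted with the layer's (z-scored) value as the covariate. A layer
"votes" for the gene when the likelihood-ratio test p-value is below
α = 0.05; a positive β marks the gene a risk factor on that layer. Genes
voted in at least 2 of the 4 layers become candidates. No multiplicity
correction is applied in the screen (a Benjamini–Hochberg variant is
available but off by default); the vote threshold, not a per-gene error
rate, is the selection device.

**Stage 2 — multivariate integration.** Each candidate gets one
4-covariate Cox fit on its [GE, SCNA, DM, ME] values. The gene is
retained only when the fit converges and all three overall tests —
likelihood ratio, Wald, and score (log-rank) — are significant at 0.05.
With the coefficient vector B and a sample's omics vector V:

    RS_j  = B · V_j                    (per-sample risk score)
    GS    = (Σ_j RS_j) / m             (mean over the m samples)
    Score = A + B + C + D + GS

where A–D are the stage-1 vote flags (GE, SCNA, DM, ME order). Genes are
ranked by decreasing Score; ties break by vote sum (descending), then
multivariate LRT p (ascending), then gene id, so rankings are fully
deterministic. The top k (default 10) form the biomarker panel. GS is
used with its sign (the Score definition does not take absolute values);
an |GS| sensitivity variant exists behind a flag.

**Validation.** The panel's prognostic power is summarized by: (i) a
multivariate Cox fit over all 4·k panel covariates whose linear
predictor is each sample's risk; (ii) a median split into high/low risk
groups compared by Kaplan–Meier curves and the log-rank test; (iii) the
distribution of Harrell's concordance indexes over 100 random 90%
subsamples (fit and evaluated on the same subsample; an optional
train/test mode fits on 90% and scores the held-out 10%), with a
one-sided sign test for median C > 0.5; and (iv) decision-curve
analysis, net benefit = TP/n − FP/n · p_t/(1−p_t) over a threshold grid
(default 0.01–0.80, step 0.01) against treat-all and treat-none
policies. Because a Cox linear predictor is not a probability, the DCA
input is obtained by logistic regression of the observed event indicator
on the risk score — the simplest monotone mapping into [0, 1].

**Functional analysis.** Gene-set enrichment is the upper-tail
cumulative hypergeometric test P(X ≥ i) for an overlap of i between an
n-gene query and an M-gene term inside an N-gene universe, flagged at
p < 0.05 without correction (BH optional); GO collections can be
restricted to biological-process terms via a `|BP` namespace suffix.
Tumor-vs-normal differential expression follows the SAM scheme: a
moderated statistic d = (mean_a − mean_b)/(s + s0), with s0 fixed at the
5th percentile of gene-wise standard errors (a deterministic
simplification of the original coefficient-of-variation minimization),
permutation q-values (median false-call count over label permutations at
each |d| cutoff, monotonized), and calls at q < 0.05 and |log2 FC| > 1
with a pseudo-count of 1.

## Harmonization

Raw matrices pass through, in order: primary-tumor sample filter
(type code "01"); removal of genes missing in more than 5% of samples
(survivors are gene-row-mean imputed); support filters for expression
layers (GE: value > 0 in more than 50% of samples; ME: value > 1 in more
than 10%); per-gene averaging of duplicate probe rows; miRNA→gene
mapping through a curated interaction table (≥ 5 supporting experiments
and anti-correlation in ≥ 1 cancer; a gene's row is the mean over its
bound miRNAs); sample/gene intersection across layers and the clinical
table; and z-scoring. All threshold comparisons are strict (`>`).

Z-scoring standardizes by the mean and SD of the **entire matrix**
(global), with rounding half-to-even at the fourth decimal. A per-gene
mode exists but is discouraged as the default: forcing every gene's mean
to zero makes GS ≈ 0 for all genes and collapses the Score ranking to
the integer vote count. Z-scoring runs after sample intersection, so the
normalization describes the analyzed cohort.

## The synthetic cohort generator

Real multi-cohort tumor data are not bundled; the generator supplies
cohorts with a known answer so every stage can be tested against a
planted truth.

Per gene and sample a latent activity factor f ~ N(0,1) is mixed into
each layer as `offset + sign·√ρ·f + √(1−ρ)·ε`, with signs +1 for GE and
SCNA and −1 for the silencing layers DM and ME. This guarantees the
biologically expected correlation pattern — methylation and miRNA
anti-correlated with expression, copy number positively correlated —
with pairwise magnitude ρ, without committing to a full covariance.
Layer offsets (GE +5, ME +3, SCNA/DM 0) place expression layers on
positive raw scales so the support filters behave as on real data; the
offsets carry no survival information and vanish under the global
z-score.

Survival times are exponential proportional hazards,
T_i ~ Exp(h0 · exp(lp_i)), the simplest model satisfying the
proportional-hazards assumption (a Weibull baseline is a natural config
extension). The linear predictor sums, over planted drivers and their
designated layers, effect × centered layer value; a driver's effect
through each layer carries that layer's sign (its methylation is
protective-signed because methylation silences it), so all of a driver's
layers express one underlying risk direction. Censoring is an
independent exponential with rate h0·c/(1−c), giving a null subject
censoring probability c; it is independent of covariates (random
censoring), which keeps the C-index interpretation clean. Missing
entries are injected uniformly at random and duplicate probe rows are
noisy copies of existing genes — both exist purely to exercise the
harmonization filters.

Defaults are the reference study conditions used by the test battery:
500 genes × 300 samples, 5 drivers with two designated layers each,
effect 1.0 log-hazard units per SD, ρ = 0.5, baseline hazard 1/365
events per day (≈ 1-year median survival for a null subject), 30%
censoring. The generator does **not** model tumor purity, batch
effects, subtype mixtures or non-proportional hazards, so passing tests
demonstrate correctness of the procedure under its own assumptions, not
robustness to the full messiness of real tumor cohorts.

## Numerical choices

* **Cox solver.** Newton–Raphson on the Efron partial likelihood
  (Breslow available for cross-checks), gradient max-norm tolerance
  1e-8, at most 50 iterations, with step-halving whenever a step would
  decrease the log-likelihood. Covariates are centered internally (the
  partial likelihood is shift-invariant; conditioning improves), and the
  linear predictor is re-centered before exponentiation to prevent
  overflow. The information matrix is accumulated as a per-subject
  weighted Gram matrix, which avoids n×p×p temporaries and keeps
  genome-wide screens fast.
* **Failure is data, not an exception.** Non-convergence (e.g. monotone
  likelihood under separation) or a singular information matrix marks
  the fit `converged=False`; screening treats such genes as
  non-significant instead of aborting a 2000-gene scan.
* **Overall tests.** LRT from 2·(ll_fit − ll_null); Wald from
  βᵀI(β̂)β; score test from U(0)ᵀI(0)⁻¹U(0) — each against χ²(p). The
  score test is the log-rank test in the overall-test triple.
* **Panel fits.** The 4·k covariates of a 10-gene panel are often
  collinear; a singular panel fit is retried with an L2 (ridge) penalty
  starting at 1e-6 and escalating ×10 until the Newton solve succeeds.
* **Concordance.** Pairs are comparable iff the smaller observed time is
  an event (time ties are not comparable); risk ties count 1/2.
* **Median split.** Samples at or below the median risk go to the low
  group; if everything ties at the median the tie block flips upward so
  both groups are non-empty; an all-tied risk vector is an error.
* **Resampling.** Each replicate subsamples ⌊0.9·n⌋ without
  replacement; a replicate whose panel fit fails is redrawn at most
  three times, then recorded at the uninformative value 0.5 and counted
  in the log. "Median significantly above 0.5" is assessed by a
  one-sided sign test (the simplest assumption-free choice).
* **Seeds.** A single seed drives each stochastic routine; derived seeds
  come from `numpy.random.default_rng` fan-out, so identical inputs and
  seeds give byte-identical outputs.

## Design decisions taken where the procedure was open

* The merged-matrix robustness check treats every (gene, layer) pair as
  a separate feature. A literal joint multivariate fit over all 4·G
  features is singular whenever 4·G exceeds the sample count, so the
  check screens each merged feature univariately and counts significant
  features per gene; with the default threshold (≥ 2) this recovers a
  subset of the voting candidates by construction.
* GS's sample count m is the number of samples entering the
  multivariate fit (complete cases after harmonization).
* The univariate screen uses continuous z-scored covariates, not
  dichotomized values.
* SCNA is treated as a continuous gene-level matrix (no thresholding of
  copy-number scores).

## Problem sizes in the test battery

The bundled tests run the full pipeline on 500 gene × 300 sample cohorts
(20 seeds for driver recovery, 10 for the multi-vs-single-omics
comparison, 100 resampling replicates each), a 1000-gene null cohort for
screen calibration, and exhaustive enumeration up to a 12-gene universe
for the hypergeometric oracle — sizes chosen so the whole battery
completes in a few minutes on one CPU while keeping every Monte-Carlo
margin wide.

## Known limitations

* The voting screen's raw p < 0.05 per layer ignores multiplicity by
  design; the BH option quantifies the cost.
* The resampled C-index is computed on the same subsample used to fit
  the panel model, so it is an optimistic (apparent) estimate; the
  train/test mode gives the honest counterpart.
* With several strong drivers, omitting any of them from a per-gene Cox
  fit attenuates coefficients toward zero (non-collapsibility of the
  hazard ratio); per-gene fits therefore estimate marginal, not joint,
  effects, and parameter-recovery checks must use the jointly specified
  model.
* SAM q-values use a fixed-s0 simplification and a modest permutation
  count; they are reproducible but slightly conservative relative to the
  original adaptive-s0 procedure.
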