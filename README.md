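# panprog

Multi-omics prognostic biomarker discovery for survival cohorts.

Cancer prognosis rarely hides in one data type: a gene can touch patient
survival through its expression, its copy number, its promoter
methylation or the miRNAs that silence it. `panprog` integrates four
omics layers — gene expression (GE), somatic copy-number alteration
(SCNA), DNA methylation (DM) and gene-mapped miRNA expression (ME) —
measured on the same tumors, and ranks genes by a single prognostic
score. It is aimed at researchers who have TCGA-style gene × sample
matrices plus a clinical survival table and want reproducible,
inspectable gene panels rather than a black-box predictor.

## The method

1. **Voting screen.** For each gene and each layer, a univariate Cox
   proportional-hazards model `h(t|x) = h0(t)·exp(βx)` is fitted on the
   z-scored layer value; the layer votes "1" when the likelihood-ratio
   p-value is below 0.05. Genes voted in ≥ 2 of the 4 layers are
   candidates.
2. **Multivariate integration.** Each candidate gets a 4-covariate Cox
   fit on its `[GE, SCNA, DM, ME]` values and is retained only when all
   three overall tests (likelihood ratio, Wald, score/log-rank) are
   significant. With coefficients `B` and per-sample omics vector `V`:

   ```
   RS_j  = B · V_j          per-sample risk score
   GS    = mean_j RS_j      gene score
   Score = A + B + C + D + GS
   ```

   where A–D are the four vote flags. The top-10 genes by Score form the
   biomarker panel.
3. **Validation.** Panel-level risk scores from one Cox fit over all
   panel covariates; high/low risk stratification with Kaplan–Meier
   curves and the log-rank test; the median of 100 Harrell concordance
   indexes on random 90% subsamples; and decision-curve analysis
   (net benefit = TP/n − FP/n · p_t/(1−p_t)) against treat-all /
   treat-none policies.

A synthetic-data module generates four-layer cohorts with planted driver
genes (known per-layer log hazard ratios, configurable cross-layer
correlation, censoring, missingness and duplicate probes), so the whole
pipeline can be exercised against a ground truth. Hypergeometric
gene-set enrichment and SAM-style tumor-vs-normal differential
expression round out the analysis. See `docs/methods.md` for the full
model description and design decisions.

## Worked example

```python
from panprog.synthetic import SimConfig, generate_dataset
from panprog.harmonize import harmonize_dataset
from panprog.scoring import (univariate_screen, select_candidates,
                             score_candidates, rank_genes)
from panprog.evaluation import cindex_resampling

raw, truth = generate_dataset(SimConfig(n_genes=200, n_samples=250,
                                        n_drivers=3, seed=42))
dataset = harmonize_dataset(dict(raw.layers), raw.clinical)

votes, _ = univariate_screen(dataset, alpha=0.05)
candidates = select_candidates(votes, min_votes=2)
records, rejects = score_candidates(dataset, votes, candidates)
panel = rank_genes(records, k=5, cancer_label="simulated")
print(panel.to_frame().round(3).to_string(index=False))

dist = cindex_resampling(panel, dataset, frac=0.9, reps=100, seed=42)
print(f"median C-index: {dist.median:.3f} (sign-test p = {dist.p_sign:.2e})")
```

Output:

```
gene_id  A  B  C  D  beta_GE  beta_SCNA  beta_DM  beta_ME     GS  Score  rank
  g0002  1  1  1  1    0.540      0.517   -0.021    0.035  0.085  4.085     1
  g0001  1  1  1  1    0.504     -0.295   -0.689    0.108 -0.030  3.970     2
  g0003  1  1  1  1   -0.008      0.504   -0.077   -0.300 -0.067  3.933     3
  g0052  1  1  0  1    0.044      0.205    0.066   -0.130 -0.015  2.985     4
  g0040  1  1  0  0   -0.288     -0.147   -0.121   -0.072  0.011  2.011     5
median C-index: 0.910 (sign-test p = 7.89e-31)
```

The three planted drivers (`g0001`–`g0003`) occupy the top three ranks:
each was voted survival-related on all four layers (A=B=C=D=1), and
their multivariate coefficients point in the planted directions (e.g.
`g0001`'s methylation coefficient is negative — methylation of a risk
gene is protective). The Score separates them cleanly from the two
borderline candidates below. A median resampled C-index of 0.91 says
the 5-gene panel orders patient survival almost perfectly in this
simulated cohort; 0.5 would be a coin flip.

The same workflow is available from the shell:

```bash
panprog simulate --n-genes 200 --n-samples 250 --n-drivers 3 --seed 42 --out sim/
panprog run --ge sim/ge.tsv --scna sim/scna.tsv --dm sim/dm.tsv \
            --me sim/me.tsv --clinical sim/clinical.tsv --seed 42 --out results/
```

`panprog run` writes every intermediate table (votes, candidates,
scores, panel, C-index distribution, KM curves, decision curve) plus a
`manifest.json` with per-stage gene/sample counts.

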