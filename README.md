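# tauset

**Weighted Kendall's tau significance tests for *ranked* gene sets in ranked
gene lists.**

Many gene sets carry more information than bare membership: transcription-
factor (TF) target sets derived from binding-site prediction or ChIP
experiments assign each member gene a confidence score (e.g. the −log10 FDR
of its binding site), which induces a rank order *inside* the set.
Classical enrichment tests (hypergeometric, Kolmogorov–Smirnov/GSEA-style)
ignore that internal ranking. `tauset` instead asks directly: **is the rank
order of the genes within the set correlated with their rank order in a
genome-wide expression-derived gene list?** — with extra emphasis on the top
of the rankings, where the informative genes live.

It is aimed at transcriptomics and regulatory-genomics analyses (bulk or
single cell) where the gene list is a per-sample differential-expression
ranking and the gene sets are scored TF-target collections.

## The statistic

For a gene set matched against the list in `n` genes, let `(i, R_i)` be the
paired ranks: `i` is the gene's rank within the set and `R_i` its rank in
the gene list (both re-ranked within the overlap, ties averaged).  With
top-down item weights `u_i` the weighted Kendall's tau is

```
tau = Σ_{i<j} u_i u_j · sgn(R_j − R_i)  /  Σ_{i<j} u_i u_j
```

The item weights come from the bounded, strictly decreasing family

```
v_i = 1 − ((i − 0.5)/n)^(p/(1−p)),   p ∈ (0, 1)
```

evaluated at the set rank (`-w 3`, default), the list rank (`-w 2`), or
combined by geometric mean (`-w 1`).  `p = 0.5` is the linear profile;
smaller `p` concentrates weight on the top ranks.  An automatic sweep
(`-p`) tries `p ∈ {0.2, 0.35, 0.5, 0.65, 0.8}` and keeps the minimum-FDR
result per set.

Under the null hypothesis of an exchangeable list ranking, the unnormalized
numerator `T` has mean 0 and the exact variance

```
Var(T) = Σ_p w_p² + ⅓ Σ' w_p w_q − ⅓ Σ'' w_p w_q ,    w_p = u_i u_j
```

where `Σ'` runs over pairs of gene pairs sharing their lower or their upper
member and `Σ''` over chained pairs (validated against exhaustive `n!`
enumeration in the tests).  `z = T/√Var(T)` is asymptotically `N(0, 1)`,
giving two-sided p-values; small overlaps, tied ranks, or an explicit
request fall back to a permutation p-value (add-one estimator).  p-values
are FDR-adjusted across sets (Benjamini–Hochberg).

The package also ships:

* an **RDE builder** (`tauset.rde`): quantile normalization of an
  expression matrix, leave-one-out differential expression
  `DE = e_target − mean(e_others)`, prediction-interval t p-values,
  per-sample FDR, and the signed rank metric `RDE = sign(DE)·(−log10 FDR)`
  plus tissue-specific gene calls (FC > 2, FDR < 1e-3);
* a **simulator and benchmark** (`tauset.simulate`): set/list pairs mixing
  `m` correlated genes (bivariate-normal scores, correlation `r`) with
  `round(q·m)` noise genes, calibration and detection experiments over the
  `(q, r)` grid, and confusion-matrix metrics (Sen, Spe, Pre, Acc, Err, F1
  and the G-mean SQR_P).

## Worked example

Simulate a ranked TF-target-style set of 130 genes (100 of them with list
scores correlated at r = 0.6) inside a 5,130-gene list, and test it:

```python
import numpy as np, tauset

gene_set, gene_list = tauset.simulate_pair(m_correlated=100, q=0.3, r=0.6, seed=1)
res = tauset.run_enrichment([gene_set], gene_list)
print(res.summary())
```

```
Ranked gene-set enrichment (weighted Kendall's tau)
===================================================
Gene list size:      5130
Gene sets:           1 (tested 1, skipped 0)
Weight mode:         3  shape p: 0.5
Significant (FDR < 0.05): 1

set_id  n_overlap    tau    z   p_value       fdr direction  p_param  weight_mode
   SIM        130 0.2624 3.93 8.482e-05 8.482e-05         +      0.5            3
```

The set overlaps the list in 130 genes; their set-rank and list-rank orders
agree with weighted tau 0.262 (direction `+`), which standardizes to
z = 3.93 and a two-sided p ≈ 8.5e-05 — the injected correlation is
recovered.  The sliding-window diagnostic (five non-overlapping windows of
0.2·n genes from the top of the set ranking to the bottom) shows the list
scores drifting downward, the signature of a positive rank correlation:

```python
prof = res.sliding_window("SIM")
print([round(float(np.median(w)), 3) for w in prof])
# [0.497, 0.092, 0.201, -0.301, -0.785]
```

The same run from the shell, on RNK / scored-GMT files:

```bash
tauset -s sets.gmt -i list.rnk -o results.tsv -w 3 --p-value 0.5
```

To rank genes from an expression matrix first:

```python
from tauset import TissueSpecificity
res = TissueSpecificity(ntpm_matrix).fit()     # genes × samples, nTPM-like
gene_list = res.gene_list("skeletal muscle")   # RDE-ranked gene list
```

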