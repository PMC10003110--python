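# deltapcc

Patient-specific differential miRNA–RNA correlation networks for
metastasis prediction and prognostic biomarker discovery in cancer
transcriptomics.

Bulk RNA-seq cohorts with tumor and normal tissue allow a per-patient
perturbation statistic: for a miRNA X and a candidate target RNA Y
(mRNA, lncRNA or pseudogene), let PCC_n(X, Y) be the Pearson correlation
over the n normal samples. Adding a single tumor sample s and recomputing
gives

    ΔPCC(X, Y; s) = PCC_{n+1}(X, Y) − PCC_n(X, Y)  ∈ [−2, 2],

the change that one patient's tumor causes in the normal-tissue
co-expression of the pair. `deltapcc` turns a raw count matrix, a gene
biotype annotation and a TNM-staged clinical table into:

* **ΔPCC feature tables** over screened miRNA–RNA pairs (TMM/CPM
  normalization, class-correlation filter at |PCC| ≥ 0.4, Wilcoxon
  rank-sum screen at p < 0.01);
* **metastasis predictions** from two stacked classifiers (PCA → RBF-SVM +
  logistic regression → logistic meta-learner; stratified 70/30 × 10
  evaluation), combined into a four-way call (none / LNM / DM / both);
* **prognostic star networks**: per-pair univariate Cox on |ΔPCC|,
  concordance index C = Σ 1[T_i>T_j] 1[η_i<η_j] d_j / Σ 1[T_i>T_j] d_j,
  maximally selected log-rank cutpoints with selection-corrected
  p-values, BH adjustment, and miRNA-centered networks (≤ 15 members)
  scored per patient by risk(i) = Σ_j |ΔPCC|_{j,i} β_j and selected at
  C-index > 0.6 with adjusted p < 0.01.

A fully specified synthetic-cohort generator with planted differential
correlations and survival signal makes every stage testable without
external data. See `docs/methods.md` for the model, assumptions and
numerical choices.

## Worked example

Simulate a cohort with a planted signal and run every stage:

```sh
deltapcc all --out run --seed 1
```

which logs:

```
[simulate] cohort: 190 genes x 490 samples
[ingest] classes: {'nonM': 200, 'LNM_only': 200, 'normal': 30, 'DM_only': 30, 'LNM_DM': 30}
[normalize] 185/190 genes pass the low-expression filter
[pairs] 10 pairs after class filter; 10 kept by the Wilcoxon screen
[metastasis] task LNM mean AUC 0.886
[survival] 10 pairs tested, 5 significant after BH
[networks] 1 networks evaluated, 1 selected
```

Reading the numbers: of the 300 possible miRNA–RNA pairs, the
class-correlation filter and the ΔPCC Wilcoxon screen recover exactly the
10 pairs whose correlation was planted to differ between metastatic and
non-metastatic tumors (here with zero false positives). The stacked LNM
classifier reaches a mean held-out AUC of 0.886 over 10 random 70/30
splits. Five pairs — those of the planted prognostic hub miRNA — pass the
survival screen, and they assemble into one selected star network,
`run/network_summary.tsv`:

```
network        n_edges  hr           logrank_p        logrank_p_adj    c_index       cutpoint     selected
Network_MIR01  5        1.386246192  6.663175418e-22  6.663175418e-22  0.7768721927  1.488541566  True
```

The network's risk score separates high- from low-risk patients
(log-rank p ≈ 7e-22 at the optimal score cutpoint, selection-corrected)
and its concordance index 0.777 exceeds that of its best single member
pair — the network is a stronger prognostic marker than any one of its
edges. `run/` also holds the ΔPCC table, per-pair survival statistics,
the mean ROC curve, a GraphML export of the network and a manifest with
the config hash and seed; rerunning with the same seed reproduces every
TSV/JSON byte for byte.

To run on real data, replace the simulated inputs:

```sh
deltapcc all --out run --seed 7 \
    --counts counts.tsv --annotation genes.tsv --clinical clinical.tsv
```

with counts as a genes × samples TSV, annotation as (gene_id, biotype) —
or a GTF with biotype attributes — and clinical columns sample_id,
t_stage, n_stage, m_stage, is_normal, os_time, os_event. Stages can also
be run individually (`simulate`, `ingest`, `normalize`, `pairs`,
`metastasis`, `survival`, `networks`); thresholds live in a YAML config
or flags (`--pcc-cutoff`, `--wilcoxon-alpha`, `--c-min`, ...).

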