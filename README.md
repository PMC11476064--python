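# gradesig

Signature-gene selection and benchmarking for two-class expression studies,
motivated by the problem of separating grade 2 from grade 3 astrocytoma on
log2-scale transcriptomic profiles.  Different feature-selection algorithms
answer the question "which genes distinguish the grades?" with strikingly
different gene sets, and the choice propagates into classification accuracy,
pathway enrichment, and survival screening.  `gradesig` implements six
selection strategies and the downstream stages needed to compare them as one
tested, seeded pipeline:

- **DGE** — per-gene two-sample *t* tests (pooled, Welch or variance-moderated),
  Benjamini–Hochberg adjustment, selection by adjusted *p* < 0.01 **or**
  |log2FC| > 1;
- **STIR** — statistical ReliefF: per-gene nearest-hit vs nearest-miss
  absolute differences (Manhattan distance on range-scaled features,
  *k* = ⌊n/6⌋ neighbours) compared with a Welch-type *t* statistic and
  BH-adjusted;
- **Boruta** — shadow-feature all-relevant selection on random-forest
  permutation-importance z-scores, with binomial hit testing and the
  median-importance rough fix for leftover tentative features;
- **iterative RF** — repeated-CV `mtry` tuning with per-iteration retention of
  genes whose permutation importance exceeds 2;
- **LASSO** — L1-penalised logistic regression over a λ grid (0.01–0.35,
  step 0.01), λ chosen by repeated-CV balanced accuracy;
- **CACTUS** — the fully specified selector–classifier: each gene is abstracted
  to a two-state *flip* (U/D) at its accuracy-maximising ROC cut-off; features
  are filtered by the binomial margin of error
  ME(z, p, n) = z·√(p(1−p)/n) (z = 5, n = feature count, p = single-feature
  accuracy); classification scores each class s by the cost function
  C_s = Π_i σ_{s,i}(f_i), the product over selected genes of the Laplace-
  smoothed conditional flip probabilities P(flip | class).

Downstream: stratified 72/35 train/test splits, 10-fold × 3 cross-validation,
KNN / SVM (radial, sigmoid) / unpenalised logistic classifiers scored by
sensitivity, specificity and balanced accuracy BA = (Se + Sp)/2 with grade 3
as the positive class; Venn-partition concordance of signatures; volcano
tables; hypergeometric over-representation against GMT gene-set collections;
Kaplan–Meier/log-rank, per-gene univariate and grade×gene interaction Cox
models (hazard ratios per SD of expression) with Schoenfeld
proportional-hazards filtering.

A seeded simulator (`gradesig.simulate`) generates GSE-shaped cohorts —
2000 genes by default, 55 + 52 samples, planted log2 shifts of 0.3–1.2
(predominantly up-regulated in the higher grade), co-regulated gene blocks,
Weibull survival in months — and is the test bed for every stage.

## Worked example

```python
import gradesig as gs
from gradesig.classify_eval import SplitSpec, CvSpec, evaluate_grid, split_train_test

cfg = gs.SimConfig(seed=7)                       # 2000 genes, 55 + 52 samples
expr, pheno, truth = gs.simulate_expression(cfg)

train, test = split_train_test(pheno, SplitSpec(seed=7))
expr_train, pheno_train = expr.subset_samples(train), pheno.subset(train)

dge = gs.dge_select(expr_train, pheno_train)
stir = gs.stir_select(gs.relief_weights(expr_train, pheno_train))
cactus = gs.CactusModel(expr_train, pheno_train).fit()

print(f"DGE selected {len(dge)} genes, STIR {len(stir)}, CACTUS {len(cactus.selected)}")

_, report = evaluate_grid([dge, stir], expr, pheno,
                          SplitSpec(seed=7), CvSpec(seed=7),
                          classifiers=("knn", "logistic"))
print(report[["selector", "classifier", "sensitivity", "specificity",
              "balanced_accuracy"]].round(3).to_string(index=False))
```

prints

```
DGE selected 34 genes, STIR 57, CACTUS 3
 selector classifier  sensitivity  specificity  balanced_accuracy
all_genes        knn        0.824        0.944              0.884
all_genes   logistic        0.941        1.000              0.971
      dge        knn        1.000        1.000              1.000
      dge   logistic        1.000        1.000              1.000
     stir        knn        1.000        1.000              1.000
     stir   logistic        1.000        1.000              1.000
```

Selection is fitted on the training split only; all rows are judged on the
same 35 held-out samples.  On this cohort both filter selectors recover
planted genes and lift the KNN balanced accuracy above the all-genes baseline
(0.884 → 1.000) — noise reduction by pre-selection, the direction the
benchmark is designed to measure.  CACTUS's margin-error filtration keeps
only genes within one margin of the best single feature, so its signatures
are small and high-precision.

The same pipeline is scriptable from the shell:

```bash
gradesig simulate --seed 7 --out-dir cohort/
gradesig select --method dge --expr cohort/expression.tsv \
    --pheno cohort/phenotype.tsv --out sigs/dge.tsv
gradesig classify --signatures sigs/ --expr cohort/expression.tsv \
    --pheno cohort/phenotype.tsv --out report.tsv
gradesig survive --expr cohort/expression.tsv --pheno cohort/phenotype.tsv \
    --signature sigs/dge.tsv --out survival.tsv
```

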