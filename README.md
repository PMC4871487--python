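# regnet

Regulator–target network inference from per-sample sparse models of tumour
gene expression.

Differential gene expression in cancer reflects copy-number changes, promoter
methylation, and altered transcriptional and post-transcriptional regulation.
`regnet` models the log2 expression of each gene in each tumour sample as a
sparse linear function of that gene's regulatory features —

```
y_g = w0 + wC·C_g + wM·M_g + Σ_TF w·N_g^TF + Σ_miR w·N_g^miR + Σ_RBP w·N_g^RBP + ε
```

where `C_g` is copy number, `M_g` methylation, and the `N_g` terms count
binding sites of transcription factors (promoter), miRNAs and RNA-binding
proteins (3'UTR). One lasso model is fitted per sample (genes are the
observations), with λ chosen by cross-validation. On top of the fits the
package provides:

* **candidate-regulator ranking** by fixed-λ selective (post-selection)
  inference — valid p-values for lasso-chosen coefficients via the
  truncated-Gaussian polyhedral test — counting, per feature, the samples in
  which it is active and significant;
* **target-gene discovery** per regulator: the change in summed squared
  prediction error when the regulator's fitted contribution is removed,
  tested against a column-permutation null with empirical p-values and
  per-regulator Benjamini–Hochberg correction;
* **feature building** from FASTA/annotation/JASPAR-PFM/BED inputs: exact
  motif-score p-values by dynamic programming, top-k-mer RBP site counting,
  peak intersection with background subtraction, duplicate-feature merging;
* **preprocessing** (TPM conversion, low-expression and low-CPM filters,
  most-negative-correlation methylation probe selection);
* a **synthetic-data generator** with planted regulators, target sets and
  motif-bearing sequences whose builder round trip is exact, used by the
  test suite and the acceptance script.

It is aimed at computational biologists studying regulatory programs in
bulk expression cohorts (e.g. TCGA-style tumour panels) who need a tested,
reproducible implementation of this model family rather than one-off
scripts.

## Worked example

```python
import numpy as np
from regnet import (SimulationConfig, generate_features, draw_truth,
                    generate_expression, select_lambda_cv, fit_lasso,
                    estimate_sigma, selective_pvalues, count_selections,
                    discover_targets, stable_seed)

cfg = SimulationConfig(n_genes=500, n_samples=40, n_tf=8, n_mirna=6, n_rbp=6,
                       n_active_per_class=(2, 1, 1), seed=3)
fm = generate_features(cfg)          # genes x (CNV, METH, 20 regulators)
truth = draw_truth(fm, cfg)          # 4 planted regulators + targets
expr = generate_expression(fm, truth, cfg)

results, fits, ys = [], [], []
for s in expr.samples:
    y = expr.values[s]
    lam = select_lambda_cv(fm.values, y, K=10, seed=stable_seed(3, "fit", s)).lam
    fit = fit_lasso(fm.values, y, lam, sample=s)
    sigma = estimate_sigma(fm.values, y)
    results.append(selective_pvalues(fm.values, y, lam, sigma, fit=fit))
    fits.append(fit); ys.append(y.to_numpy())

table = count_selections(results, alpha=0.05, classes=fm.classes)
print(table.head(7).to_string(index=False))

regulators = table[table["class"].isin(["TF", "MIRNA", "RBP"])]
top = regulators.iloc[0]["regulator"]
calls = discover_targets(fm.values, ys, fits, top, B=500, seed=11,
                         q_threshold=0.05)
pred = set(calls.loc[calls.is_target, "gene"])
ref = truth.target_sets[top]
print(f"{top}: {len(pred)} targets called, "
      f"{len(pred & ref)} of {len(ref)} true targets recovered, "
      f"{len(pred - ref)} false")
```

prints

```
regulator class  n_selected  selection_pct
   TF_001    TF          40          100.0
  miR_006 MIRNA          39           97.5
     METH  METH          37           92.5
   TF_002    TF          37           92.5
      CNV   CNV          36           90.0
  RBP_004   RBP          36           90.0
   TF_006    TF           5           12.5
TF_001: 115 targets called, 115 of 191 true targets recovered, 0 false
```

The selection table ranks features by how many of the 40 samples selected
them with a significant selective p-value: the four planted regulators
(TF_001, miR_006, TF_002, RBP_004) and the two genuine covariates (METH,
CNV) fill the top six rows, all selected in ≥ 90% of samples, while the
first null feature (TF_006) drops to 12.5%. Target discovery for the
top-ranked regulator then calls 115 genes at q ≤ 0.05, every one of them a
true planted target (the remaining true targets are mostly single-site
genes below the permutation test's resolution at this sample size).

The same analysis is available from the shell. `regnet run` drives the full
pipeline (simulate → build features from emitted sequences → fit → select →
targets → validate) from a YAML config:

```yaml
# run.yaml
simulation:
  n_genes: 200
  n_samples: 20
  n_tf: 12
  n_mirna: 8
  n_rbp: 8
  n_active_per_class: [2, 2, 2]
  seed: 5
permutations: 200
q_threshold: 0.05
max_target_regulators: 3
seed: 5
```

```bash
regnet simulate --outdir demo --seed 3 --sequences   # standalone fixtures
regnet run --config run.yaml --outdir demo_run       # full pipeline
```

The run directory contains one TSV/JSON per stage plus `manifest.json`
(seeds, thresholds, output checksums); re-running with the same config and
seed reproduces every result table byte for byte.

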