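# fsmkl

Pathway-based multiple kernel learning (MKL) for predicting a binary clinical
outcome — e.g. survival at a fixed horizon — from several data types at once:
gene expression, copy-number values and clinical covariates.

## Who this is for

Anyone with (a) one or more sample × feature numeric matrices sharing a sample
index, (b) an optional clinical covariate table, (c) a GMT file of pathway
gene sets and (d) a binary label per sample, who wants a classifier that both
integrates the data types and reports *which pathways and covariates carried
the decision*.

## The model

Each candidate feature set — the t-test top-k features of a data type, the
genes of one pathway, or one Boolean-encoded clinical covariate — becomes a
*base kernel* K⁽ˡ⁾ (linear, polynomial (x·z + 1)^d with d ∈ {2, 3}, or
Gaussian), normalized to unit trace so differently scaled data types are
commensurable. The classifier is a soft-margin SVM over the composite kernel

    K = Σₗ dₗ K⁽ˡ⁾,   dₗ ≥ 0,  Σₗ dₗ = 1,

with the simplex weights d learned by SimpleMKL-style reduced-gradient
descent on the SVM dual objective J(d). The two-norm regularization drives
most dₗ to exactly zero, so the surviving kernels — typically a handful of
pathways and covariates — are directly interpretable as the decision's
ingredients.

Decision values f(z) are mapped to posteriors p(+1|f) = 1/(1 + e^{Af+B})
(Platt scaling, fitted by cross-entropy minimization). The posterior serves
two purposes:

* **ambiguous-label pruning** — training samples whose own label has
  posterior < 0.8 are removed and the model refitted once;
* **cautious classification** — a label is emitted only when
  max(p, 1−p) ≥ 0.95, otherwise the classifier abstains; accuracy on the
  predicted subset is reported together with coverage.

## Worked example

No external data is needed: the `fsmkl.synthetic` module generates a seeded
two-block cohort (expression-like and copy-number-like) with overlapping
pathways, of which a known few drive the labels.

```python
import warnings
from fsmkl import ExperimentConfig, cross_validate, aggregate_kernel_report
from fsmkl.synthetic import recovery_config, simulate, truth_recovery_score

ds = simulate(recovery_config(seed=7))           # n=300, 20 pathways, 3 causal
config = ExperimentConfig(blocks=["EXP", "CNV"], use_pathway=True,
                          folds=5, seed=7)
result = cross_validate(ds.blocks, None, ds.pathways, ds.labels, config)
report = aggregate_kernel_report(result)

print(f"5-fold CV accuracy: {result.mean:.3f} +- {result.sd:.3f}")
print(report.head(5).to_string(index=False))
print(f"informative-pathway recovery: "
      f"{truth_recovery_score(report, ds.truth):.2f}")
```

prints

```
5-fold CV accuracy: 0.787 +- 0.085
            detail source selection   func  mean_weight  selection_frequency
CNV/path000/linear    CNV   pathway linear     0.168098                  1.0
EXP/path000/linear    EXP   pathway linear     0.126133                  1.0
EXP/path009/linear    EXP   pathway linear     0.120292                  1.0
EXP/path006/linear    EXP   pathway linear     0.102612                  1.0
CNV/path009/linear    CNV   pathway linear     0.098505                  1.0
```

The three causal pathways in this dataset are `path000`, `path006` and
`path009`: the kernel ranking puts exactly those at the top across every
fold (`recovery: 1.00`), and the integrated model is more accurate than
either block alone (~0.69 for expression only, ~0.67 for copy number only
under the same folds).

The same pipeline is available from the shell:

```sh
fsmkl simulate --config config.yml --out data/
fsmkl cv       --config config.yml --out results/
fsmkl compare  --config config.yml --out results/
```

All commands take a YAML config (see `fsmkl.cli`'s module docstring for the
layout), write TSV outputs and a `manifest.json` carrying the config hash and
seed, and are byte-for-byte reproducible for a fixed config and seed.

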