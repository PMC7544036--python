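# irgps — immune-related gene-pair prognostic signatures

Rank-based survival signatures from bulk expression data. Instead of
absolute expression values — which are incomparable across sequencing
platforms without normalization — the model uses *within-sample*
orderings of gene pairs: the feature for an ordered pair (a, b) in a
sample is `1` if gene a is expressed more highly than gene b in that
sample, else `0`. A risk score is a linear combination of such
indicators with Cox-model coefficients,

    r(sample) = Σ_k β_k · 1[ expr(a_k) > expr(b_k) ],

so it is exactly invariant to any strictly increasing per-sample
transformation of the data: a signature fitted on RNA-seq FPKM applies
unchanged to array intensities. The package is aimed at researchers
building or applying such signatures for overall survival in cancer
cohorts (the bundled reference signature targets melanoma and
immune-related genes), and at anyone who needs the surrounding
machinery tested against oracles: time-dependent ROC cutoffs under
censoring, log-rank / Cox evaluation, and FDR-controlled comparison of
immune-cell-fraction tables between risk groups.

What it provides:

* **Pair features** — scoring, antisymmetry-aware enumeration,
  near-constant pair filtering (`irgps.pairs`).
* **Signature construction** — univariate Cox + log-rank candidate
  screening at p < 1e-4 (vectorised over tens of thousands of pairs),
  consensus selection over repeated cross-validated lasso-Cox cycles,
  and a Youden cutoff from the 3-year Kaplan–Meier time-dependent ROC
  (`irgps.screen`, `irgps.select`, `irgps.roc`).
* **Evaluation** — log-rank tests, uni/multivariate Cox tables with
  hazard ratios and 95% CIs, restricted mean survival, mutation-
  stratified subgroup analysis (`irgps.survival`); Wilcoxon +
  Benjamini–Hochberg comparison of cell-fraction tables
  (`irgps.compare`).
* **Synthetic cohorts** with planted prognostic pairs, calibrated
  censoring, and per-sample monotone "platform distortions", so the
  whole pipeline runs and is testable with no downloads
  (`irgps.simulate`).
* A bundled reference signature: 33 immune-gene pairs over 52 genes
  with a companion risk-score cutoff of −1.130
  (`irgps.load_melanoma_signature()`).

## Worked example

```python
from irgps import SimulationConfig, simulate_cohort
from irgps.pipeline import RunConfig, fit_workflow

# 300 patients x 100 genes, three planted prognostic pairs, 30% censoring
expression, clinical, truth = simulate_cohort(SimulationConfig(seed=2024))
result = fit_workflow(expression, clinical, config=RunConfig(n_cycles=100, seed=2024))
print(result.stage_counts, result.cutoff)
print(truth["true_pairs"], [(p.pair_id, round(c, 2)) for p, c in result.signature.entries])
```

prints (seed 2024):

```
{'genes_input': 100, 'genes_filtered': 100, 'pairs_built': 4950,
 'pairs_variable': 4830, 'pairs_candidate': 12, 'pairs_signature': 10} 1.1982
['G0002__G0057', 'G0087__G0075', 'G0062__G0065']
[('G0002__G0024', 0.3), ('G0002__G0057', 0.87), ('G0002__G0086', 0.49),
 ('G0045__G0062', -0.16), ('G0047__G0057', 0.24), ('G0055__G0085', -0.56),
 ('G0062__G0065', 0.98), ('G0062__G0080', 0.22), ('G0065__G0075', -0.3),
 ('G0075__G0087', 0.86)]
```

Reading this: of 4,950 candidate pairs, 4,830 vary enough to be usable,
12 pass the p < 1e-4 survival screen, and the consensus lasso keeps 10.
All three planted pairs are recovered — `G0087__G0075` (generated with
log-HR −1.2) reappears in the opposite orientation `G0075__G0087` with
a positive coefficient, which is the same feature (the indicator flips,
the sign absorbs it). The remaining entries are correlated "shadow"
pairs sharing a gene with a true pair. The cutoff 1.20 is the risk
score maximising sensitivity + specificity for 3-year survival; scoring
a cohort then splits it at that value into high/low risk groups
(high > cutoff), here giving log-rank χ² = 124.2, p = 7.6e-29, and a
36-month restricted-mean-survival ratio of 0.43 (high vs low).

The same steps as a shell pipeline:

```bash
irgps simulate --seed 2024 --out cohort/
irgps fit --expression cohort/expression.tsv --clinical cohort/clinical.tsv \
          --n-cycles 100 --seed 2024 --out fit/
irgps score --expression cohort/expression.tsv --clinical cohort/clinical.tsv \
            --signature fit/signature.json --out eval/
```

The numbered scripts under `analysis/` run the full narrative —
simulate, fit, verify cross-platform invariance, evaluate the
stratification, compare simulated immune-cell fractions — writing
tables under `results/` (bulky intermediates under `scratch/`).

## Applying the bundled melanoma signature

```python
from irgps import load_melanoma_signature, risk_score, assign_groups

signature = load_melanoma_signature()   # 33 pairs, 52 genes, cutoff -1.130
scores = risk_score(expression_matrix, signature)
groups = assign_groups(scores, signature.cutoff)
```

The expression matrix only needs the 52 signature genes on any
monotone-equivalent scale; no normalization.

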