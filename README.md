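# synerstack

Anticancer drug-combination synergy scoring and stacked-ensemble prediction
on drug + multi-omics features.

`synerstack` is for computational pharmacologists who work with combination
drug screens: it turns raw dose–response matrices of drug pairs on cancer
cell lines into synergy scores under five reference models, builds a
conservative "full agreement" classification dataset, joins drug molecular
descriptors with dimensionality-reduced multi-omics cell-line profiles into
model-ready tables, trains a zoo of base learners stacked into an
outlier-robust ensemble, evaluates it under leave-cell/drug/combination-out
scenarios, and explains predictions with permutation importance propagated
back through PCA loadings. A synthetic-data module generates complete
studies with known injected synergy, so every stage is testable without any
external download.

## The models

Monotherapy responses are modeled by a four-parameter logistic (Hill)
curve

    y(x) = (E_min + E_max (x/m)^λ) / (1 + (x/m)^λ)

where `m` is the dose of midpoint effect (relative IC50) and `λ` the slope.
For a pair of drugs at doses (x₁, x₂) with single-agent responses (y₁, y₂),
the expected non-interacting response is

- **Bliss** independence: `y₁ + y₂ − y₁y₂`
- **HSA** (highest single agent): `max(y₁, y₂)`
- **Loewe** additivity: the Hill curve evaluated at the total dose `x₁ + x₂`
- **ZIP**: the Bliss combination of the two unit-interval Hill terms
  `(xᵢ/mᵢ)^λᵢ / (1 + (xᵢ/mᵢ)^λᵢ)`

The synergy score of a matrix is 100 × the mean of observed-minus-expected
responses over all grid points with both doses positive; a score above 0 is
synergistic. A sample enters the classification dataset only when all four
reference models agree on its label. A fifth, CSS-style sensitivity score
integrates the fitted combination dose–response curve (partner drug pinned
near its IC50) over log₁₀ dose, normalized to a 0–100 scale; it serves as a
regression target only.

Downstream, each of seven omics blocks (expression, copy number,
methylation, chromatin profiling, metabolomics, microRNA, proteomics) is
standardized and reduced to 25 principal components — 175 features per cell
line — or to the bottleneck of a 7-layer hourglass autoencoder. Drug
descriptors are filtered (non-numeric and zero-variance columns removed)
and z-scored. Base learners (random forest, extremely randomized trees,
SVM, linear SGD, k-NN, gradient-boosted trees, feed-forward nets) are
stacked by a shallow network trained on their predictions, after replacing
any prediction whose magnitude exceeds 10× the mean of the remaining
models' predictions for that sample.

## Worked example

```python
from synerstack import SyntheticConfig, simulate_study, score_table, label_table

bundle = simulate_study(SyntheticConfig(n_drugs=8, n_cells=6, n_tissues=3,
                                        n_pairs=10, seed=7))
scores = score_table(bundle.matrices[:5])
print(label_table(scores).round(2).to_string(index=False))
```

prints

```
drug1 drug2 cell  score_bliss  score_hsa  score_loewe  score_zip  score_css agreement_label
 D001  D002 C001        -1.26      11.33         5.48     -23.47      50.42         dropped
 D001  D002 C002        -1.67       9.69         6.04     -18.87      57.24         dropped
 D001  D002 C003        -0.41      11.21         4.52     -16.94      57.79         dropped
```

These pairs carry no injected synergy (the generator's ground-truth offset
is 0), and the Bliss score — the generator's own expectation model — is
correctly near zero; HSA, Loewe and ZIP disagree because their null models
differ, so the full-agreement filter drops the samples rather than
mislabeling them. The CSS column is the combination's overall sensitivity
(≈50–60% of the dose range is effective), not a synergy measure.

The full pipeline on a study bundle:

```python
from synerstack import run_study
result = run_study(bundle, seed=0)
print(result.report["regression"]["ensemble"]["test"])
```

A command-line interface mirrors the library:
`synerstack simulate`, `score`, `label`, `featurize`, `reduce`, `run`.

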