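# Methods

## Response convention

All internal computation uses the inhibition fraction (0 = untreated
growth, 1 = complete inhibition). Readers accept screen-convention growth
percentages and convert via `inhibition = (100 − growth) / 100`; values
outside [0, 1] (cytotoxic wells, over-growth) are deliberately passed
through, since the reference-model algebra is defined for them too. Drug
pairs are put in canonical lexicographic order at ingestion so each
(pair, cell) key is unique.

## Monotherapy curve fitting

`fit_hill` fits the four-parameter logistic
`y = (Emin + Emax·t)/(1 + t)`, `t = (x/m)^λ`, by bounded nonlinear least
squares (trust-region reflective, analytic Jacobian, tolerances 1e-12) in
(Emin, Emax, log m, log λ). Initialization uses a fixed 4×4 grid of
starting values — m log-spaced across the tested dose range, λ in
{0.5, 1, 2, 4} — ranked by initial residual, with the best four polished
and the lowest-SSE solution kept. The fixed grid and stable ranking make
the fit deterministic for given data. Bounds: λ ∈ [0.1, 20], m within
[min dose/10, max dose×10], Emin/Emax within the observed response range
padded by half its span plus 0.1. Constant responses (range < 1e-12)
return a degenerate flat curve (`Emin = Emax = mean`) carrying a flag;
IC50 is undefined for flat curves, and the Loewe/ZIP expectations of a
degenerate curve return the flat value. The relative IC50 is the midpoint
dose `m`; an absolute mode solves `y(x) = 0.5` in closed form.

## Synergy scores

Per-dose expected responses follow the four reference models (Bliss, HSA,
Loewe, ZIP). The matrix-level score is 100 × the arithmetic mean of
observed-minus-expected over grid points with both doses positive — the
simplest defensible aggregation, chosen because a single summary score per
(pair, cell) is what the downstream learners consume. The Loewe form uses
one (Emin, Emax, m, λ) set; by default the more potent drug's curve (lower
fitted m) supplies it, configurable to either drug or the parameter-wise
mean curve, because the attribution is genuinely ambiguous when the two
single-agent curves differ.

The CSS-style sensitivity score is a documented variant, not a numerical
clone of any database implementation: for each orientation the partner
drug is pinned at its tested dose nearest its IC50 (ties toward the lower
dose, since the score operates on discrete grids), a 4PL is fitted to the
combination responses along the free axis, integrated over log₁₀ dose
between the smallest and largest positive tested doses, normalized by the
log-dose span and scaled by 100; the score is the mean of the two
orientations. Monotherapy fits are cached per (drug, cell) across a
scoring run, which is what makes large scoring tables cheap.

## Labels

Scores binarize at threshold 0, strictly-above reading: a score of exactly
0 is nonsynergistic. Only Bliss, HSA, Loewe and ZIP vote; CSS is a
regression target only, since it measures sensitivity rather than excess
over a null model. Samples with a unanimous vote keep that label; all
others are dropped from the classification dataset.

## Drug descriptors

Descriptor preprocessing drops any column that is non-numeric, has a
missing value (treated as non-numeric, the conservative choice), or has
zero variance across drugs, then z-scores with population variance
(divide by n) — the standard-scaler convention, stated explicitly because
z-score expectations depend on it. `standardize` returns its fitted
means/scales and applies them without refitting in transform mode, so
held-out drugs can be scaled leak-free; the desk-scale pipeline fits the
scaling on the full drug panel before splitting because drug clustering
(used to choose the drug hold-out) needs scaled descriptors first. The
module also ships a 28-category bookkeeping table (586 descriptors total)
for categorizing filtered 2-D descriptor sets, and an optional RDKit-based
descriptor computation from SMILES with per-drug error isolation.

## Omics reduction

Each block is standardized per feature (population variance, missing
entries ignored, zero-variance features mapped to 0 rather than erroring).
Missing values are then handled by one of two policies: `drop_sample`
removes any cell row with a gap; `fill_zero` writes zeros — applied after
standardization, zeros are mean-imputation in original units.

PCA keeps 25 components per block at full scale (175-wide profiles over
seven blocks); each component is sign-fixed so its largest-magnitude
loading is positive, making scores reproducible across platforms. The
hourglass autoencoder has 7 layers (5 hidden): input → h1 → h2 →
bottleneck → h2 → h1 → output, ReLU in all layers including the output,
Adam at learning rate 0.001, MSE loss. The bottleneck width follows a
divisor rule — ⌊n/50⌋ for n ≥ 10,000 features, ⌊n/10⌋ for 500 ≤ n <
10,000, ⌊n/2⌋ below — and h1/h2 interpolate geometrically between input
and bottleneck widths (clamped to keep a strict hourglass when the widths
leave room). Epochs follow block size: 1,000 (≤ 500 features), 250
(≤ 10,000), 100 otherwise; all configurable. The all-ReLU output clips
negative reconstructions of standardized data; the bottleneck activations,
which are what the pipeline consumes, are unaffected by that clipping
beyond what training absorbs. Since no deep-learning framework is a
dependency, all networks run on a small in-package NumPy implementation
(`synerstack.nn`): dense layers, He initialization, inverted dropout,
Adam, BCE/MSE losses, fully deterministic under a seed.

Profiles concatenate the reduced blocks in a fixed order (expression, cnv,
methylation, chromatin, metabolomics, microrna, proteomics) by inner join
on cell id; cells missing from any block are excluded, cells without a
tissue annotation are kept and flagged `unknown`.

## Dataset assembly and hold-outs

A sample's feature vector is drug-1 descriptors ⊕ drug-2 descriptors ⊕
cell profile (no swapped-order augmentation; the canonical pair order is
used, a documented choice). Hold-outs, in fixed precedence: 3 whole cell
lines from distinct tissues, then 5 whole drugs from distinct hierarchical
descriptor clusters (average linkage, Euclidean) where available, then 5
whole drug pairs; the remaining pool splits 80/20 at the row level. All
selections draw from one seeded generator over sorted candidate lists, so
a seed fully determines the plan. Precedence resolves overlaps
deterministically: a row touching a held-out cell never re-enters the drug
or pair pools.

## Learners, stacking, evaluation

Tabular families are fitted through scikit-learn (RF, extra trees, SVM,
SGD, k-NN) and xgboost; feed-forward nets use the in-package MLP with
ReLU hidden layers, dropout after each hidden layer, sigmoid + binary
cross-entropy (classification) or linear + MSE (regression) heads, Adam
at learning rate 1e-4 for 125 epochs by default. Margin-based classifiers
(SVM, linear SGD) emit probabilities through a logistic link on their
decision score so every base model produces a [0, 1] score for stacking.
Grid search evaluates a declared cartesian grid by 3-fold CV on a seeded
5% subsample of the training rows, with ties broken toward enumeration
order; the default axes (12 net architectures × 4 dropout rates; standard
per-family tabular axes) are package defaults, fully configurable.

Meta-features are the aligned base-model predictions after outlier
replacement: a value whose magnitude exceeds 10× the magnitude of the
remaining models' mean for that sample is replaced by that mean ("above or
below" read as magnitude, since synergy scales are signed). The pass
repeats to a fixed point — each replacement shrinks the cell by more than
10×, so termination is guaranteed — and is skipped where the remaining
mean is exactly 0, where the rule is undefined. All replacements are
logged. The stacker is a shallow MLP on the meta-features; its reference
recipe is learning rate 1e-4 for 3 epochs, which at a training-set size in
the hundreds of thousands means roughly half a million Adam updates. The
desk-scale pipeline default (hidden width 16, learning rate 1e-3, 300
epochs, batch 16 on a few hundred rows) was chosen a priori to keep the
update count within two orders of magnitude of that reference; both are
plain config fields.

Classification metrics: accuracy, precision, recall, F1 at threshold 0.5
(configurable) plus rank-based AUROC (tied pairs averaged; undefined and
reported as NaN for single-class truth). Regression: RMSE, MSE, MAE,
Pearson, Spearman (mid-rank ties). Permutation importance shuffles one
column at a time on held-out rows (default 10 seeded repeats) and records
the mean metric degradation; reduced-column importance propagates to
original omics features via squared PCA loadings, which conserves
importance mass because loadings are orthonormal. Block shares normalize
absolute importances to percentages over drug descriptors plus the seven
omics blocks. Propagation through autoencoder encoders is unsupported.

## Synthetic studies

The generator emulates a combination screen joined to an omics panel:

- **Monotherapy**: per-drug Hill truths with Emin = 0, Emax ~ U(0.6, 1),
  log₁₀ m ~ U(−1, 1), λ ~ U(0.8, 2.5) — midpoints spread over two decades
  of dose with realistic slopes. Five log-spaced doses around each drug's
  m, drawn once per (drug, cell).
- **Combinations**: 3×3 (or 5×3) positive dose grids; response = Bliss
  expectation of the true curves + δ + N(0, σ²), σ = 0.02 (≈2% of the
  response scale, an optimistic but plausible assay noise). Bliss is the
  generative expectation because it has the simplest closed form; this
  means Bliss-scored synergy recovers δ directly while HSA/Loewe/ZIP
  scores are systematically offset — a feature, used to test that the
  models are distinguishable.
- **Synergy offsets**: δ is a mixture — point mass at 0 (weight 0.3),
  positive (0.45) and negative (0.25) components with magnitude
  U(0.03, 0.15) — modulated multiplicatively by a per-cell latent factor
  (`pair_cell` mode) or driven entirely by that factor (`cell_only` mode).
  The factor is the first latent factor of the expression block, so omics
  features genuinely carry predictive signal.
- **Drugs**: descriptors = one of 5 archetype vectors + N(0, 0.3) noise,
  plus injected constant and text columns so filtering has real work;
  archetypes make hierarchical clustering recoverable.
- **Omics**: seven blocks of latent-factor structure (rank 3–4, noise
  0.3) with 2% missing entries; tissues assigned round-robin over 4 types.

The default desk-scale study is 20 drugs, 12 cell lines, 4 tissues, 50
pairs (600 matrices). With 12 cell lines, 25 components per block are not
estimable, so the pipeline default is 5 components (35-wide profiles); the
175-wide construction is exercised on a 30-cell panel. The generator does
**not** emulate real screens' heteroscedastic noise, plate/batch effects,
non-rectangular or censored grids, correlated omics blocks, or realistic
descriptor semantics — so passing tests demonstrate that the machinery is
correct and that injected signal of realistic magnitude is recoverable,
not that any particular real-data performance level is attainable.

One identifiability caveat found while designing the contribution tests:
when the synergy offset is a pure function of cell identity and the panel
is small, every omics block encodes cell identity equally well and block
attribution is arbitrary. Attribution to the causal block becomes
identifiable once the panel is wide enough (≈40 cells) that chance
correlations between blocks' latent factors are small; the contribution
tests use such a panel.

## Known limitations

- The CSS-style score is a variant; absolute values are not comparable to
  database CSS values, though orderings broadly agree on well-behaved
  matrices.
- The Loewe implementation evaluates a shared 4PL at total dose; it is not
  an implicit-equation dose-equivalence solver.
- Desk-scale classification datasets derived from Bliss-generated
  responses are near single-class after full agreement (HSA's null is
  dominated by Bliss's, so its label is almost always synergistic); the
  pipeline skips classification training with a note when a class has
  fewer than 5 training rows.
- Autoencoder-reduced features cannot be propagated to original features
  for contribution analysis.
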