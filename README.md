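# chromafactor

Non-negative matrix factorization (NMF) of single-molecule chromatin
conformation ensembles.

Single-molecule chromatin tracing and single-cell Hi-C deliver, per cell, a
b × b matrix of pairwise spatial distances (or contacts) between consecutive
genomic loci. These maps are extremely heterogeneous: trends that are obvious
in the population average — a domain boundary appearing when a gene is
transcribed, an enhancer moving closer to its promoter — are nearly invisible
in any individual cell. `chromafactor` is for researchers who want to know
*which cells* carry a bulk trend. It decomposes the stack of per-cell maps
into a small set of non-negative **templates** (recurrent organization
patterns) and per-cell **weights**, so that each cell's map is an additive
mixture:

```
X_i  ≈  Σ_k  W_k · H_ki ,        W_k ∈ ℝ^{b×b}_{≥0},  H ∈ ℝ^{k×n}_{≥0}
```

Concretely, every map is flattened to a length-b² vector, the b² × n matrix
V is factorized as V ≈ WH by NMF (coordinate descent, Frobenius loss,
deterministic NNDSVD initialization), and the columns of W are reshaped back
into symmetric b × b templates. On top of the factorization the package
provides:

- **preprocessing** — coordinate-table ingestion, QC filtering of cells by
  missing-locus fraction, linear interpolation of missing loci, Euclidean
  distance maps, max-normalization (per cell or global);
- **k selection** — a multi-metric framework scoring each candidate k by
  reconstruction error, component stability across random restarts,
  component redundancy, variance explained, fit time and (optionally)
  cross-validated transcription-prediction accuracy;
- **template analysis** — sliding-window insulation profiles and boundary
  calls, the directionality index, dominant-component labels, UMAP
  embedding of the weight matrix, protein-peak colocalization;
- **association** — position-wise and component-wise two-sided Mann-Whitney
  U tests with Benjamini-Hochberg FDR control, plus a balanced random-forest
  classifier with feature importances and a label-permutation null;
- **subpopulations** — high/low-contribution cell groups from the
  transcription-associated components, their median contact maps, contrast
  maps, and anchor-enhancer distances;
- **synthetic data** — a ground-truthed generator planting boundary, stripe
  and compartment-checkerboard templates with known weights, noise, locus
  dropout and label coupling, so every stage is testable without any
  download.

## Worked example

```python
import numpy as np
import chromafactor as cf

# a synthetic locus: 32 bins, 3 planted templates, 500 cells, noise sd 0.05,
# transcription labels coupled to component 0
config = cf.SyntheticConfig(b=32, k_true=3, n=500, noise_sd=0.05,
                            label_components=(0,), label_effect=2.0, seed=0)
dataset = cf.generate_dataset(config)
tensor = cf.normalize_max(dataset.tensor, "per_cell_max")

model = cf.ChromaFactorModel(tensor)
results = model.fit(k=3, seed=0)
print(results.summary())

diff = cf.componentwise_differential(results.weights, dataset.labels)
print("component q-values:", np.round(diff.q_fdr, 4))
print("significant (FDR < 0.1):", np.flatnonzero(diff.significant).tolist())

idx = cf.balanced_subset(dataset.labels, seed=0)
report = cf.fit_rf_classifier(results.weights.T[idx],
                              dataset.labels[idx], seed=0)
print("balanced RF accuracy:", round(report.accuracy, 3))
```

This prints:

```
ChromaFactor decomposition
==========================
bins (b):              32
cells (n):             500
components (k):        3
init / solver:         nndsvd / coordinate descent
iterations run:        200 (max 200)
converged:             False
reconstruction error:  11.5943
asymmetry norm:        0
variance explained:    0.9987

component q-values: [0.0001 0.     0.0001]
significant (FDR < 0.1): [0, 1, 2]
balanced RF accuracy: 0.641
```

Three components capture 99.9% of the variance of the normalized maps. All
three components test significant: labels are driven by component 0, but
per-cell max normalization couples the remaining weights to it, so they
carry signal too — the same effect that makes most components significant in
real tracing data. The balanced random forest predicts transcription from
the three weights alone at 64% accuracy, well above the 50% chance level
that balancing guarantees.

The same workflow is available from the shell:

```bash
chromafactor simulate --b 32 --k-true 3 --n 500 --seed 0 --out sim/
chromafactor preprocess --input sim/coordinates.tsv --out tensor/
chromafactor decompose --tensor tensor/ --k 3 --seed 0 --out model/
chromafactor select-k --tensor tensor/ --k-min 2 --k-max 8 --out ksel/
chromafactor analyze --model model/ --window 2 --out tracks/
chromafactor run --config run.toml       # full pipeline with stage caching
```

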