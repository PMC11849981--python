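# Methods

## Model

Each cell contributes one b × b matrix of pairwise Euclidean distances
between traced genomic loci (the contact-map analog for imaging data; the
package also accepts contact matrices from single-cell Hi-C). The working
assumption is additive mixing: after max-normalization, cell i's map is

X_i = Σ_k W_k H_ki + ε_i,

with non-negative templates W_k and weights H_ki. The stack is flattened to
V ∈ ℝ^{b²×n} and factorized by NMF minimizing ½‖V − WH‖²_F under
non-negativity, with a coordinate-descent solver, tolerance 1e-4, at most
200 iterations, and deterministic NNDSVD initialization so repeated fits are
bit-identical. An element-wise L2 penalty is exposed (`l2_reg`) but defaults
to 0: no principled positive coefficient presents itself, and the desk-scale
problems here are well conditioned without it. Flattened NMF knows nothing
about matrix symmetry, so fitted templates are symmetrized as
(W_k + W_kᵀ)/2 after the fit and the pre-symmetrization discrepancy is
recorded as `asymmetry_norm` rather than discarded — downstream track
computations (insulation, directionality) assume symmetric maps. In
practice the discrepancy is at floating-point level because the input
columns are themselves symmetric. Convergence is reported, never raised:
`converged` simply records whether the relative-error change fell below the
tolerance before the iteration cap.

The default k is 20, the conventional choice for a single ~10 Mb-or-smaller
locus; the KSelector (below) exists precisely because k is the one genuinely
free knob.

## Choosing k

For each k in a grid the framework records: reconstruction error
(Frobenius); component stability — NMF is rerun from `n_inits` *random*
initializations (deterministic initialization would trivially score 1.0),
components are matched one-to-one between every pair of runs by the
assignment maximizing total Pearson correlation of flattened templates
(Hungarian algorithm up to k = 64, greedy beyond), and the matched
correlations are averaged; component redundancy — mean |Pearson r| over all
template pairs (defined as 0 at k = 1, where there are no pairs); variance
explained; wall-clock fit time; and, when transcription labels are
supplied, 5-fold stratified cross-validated accuracy of a balanced random
forest predicting labels from H. Each metric is min-max normalized over the
grid and oriented higher-is-better (error and redundancy inverted); a
metric constant over the grid is uninformative and contributes 0.5
everywhere. The proposed k maximizes the unweighted mean; ties break to the
smaller k. Fit time is recorded and plotted — computational efficiency is
one of the balancing criteria — but deliberately excluded from the
automated proposal: wall-clock measurements are not a function of the data
and seed, and min-max normalization over the narrow time range of a small
grid amplifies millisecond jitter enough to flip near-tied proposals
between otherwise identical runs. Users who want to weigh run time do so
from the reported curve. Raw curves are likewise retained so the elbow
heuristic can be applied instead of the average.

## Preprocessing

Coordinate tables are TSV with columns `cell_id, locus_index, x, y, z` and
optional `label_<gene>` columns; a locus with any coordinate absent counts
as missing. QC removes cells whose missing fraction *strictly exceeds* the
threshold — the rules are phrased as "over"/"more than", so boundary-equal
cells stay. Remaining gaps are filled by per-axis linear interpolation
along the locus index; leading/trailing runs take the nearest observed
value (constant extrapolation — the interpolation convention does not
specify extrapolation, and inventing a trend at the ends would manufacture
structure). Observed coordinates are copied bit-for-bit. Distances are
plain Euclidean norms. Normalization divides by the maximum distance
observed, either per cell (default) or dataset-wide; "the maximum observed"
is ambiguous between the two, so both are implemented and the mode is
recorded on the tensor. Per-cell is the default because it makes every map
live on [0, 1], which in turn makes the 0.05 insulation threshold
scale-free. All text output uses 17 significant digits and round-trip float
parsing, so save/load cycles are bit-stable.

## Tracks

Insulation at bin i is the mean of the cross-window block
M[i−w+1..i, i+1..i+w] (clipped at the edges; the last bin has an empty
downstream block and is undefined). On *normalized distance* maps a domain
boundary is a local *maximum* — loci straddling a boundary are far apart —
and boundary calls are interior strict local maxima above the 0.05
threshold, plateaus resolved to their leftmost bin. The directionality
index divides by expected contacts, so distance input is first transformed
to similarity s = 1 − m (valid on max-normalized maps); then per bin
A and B are the upstream/downstream window sums, E = (A+B)/2, and
DI = sign(B−A)·[(A−E)²/E + (B−E)²/E], zero when A = B or E = 0, with
truncated windows at the edges. The window is a required parameter
(default 5 bins); published analyses rarely state it, and the synthetic
tests show planted boundaries are recovered within ±1 bin for windows 2–4.
UMAP embedding of H uses n_neighbors = 5 with library defaults and a fixed
`random_state`, trading parallelism for determinism.

## Statistics

Group comparisons use the two-sided Mann-Whitney U test: exact enumeration
when both groups have ≤ 8 observations and no ties (so toy examples are
exact), otherwise the normal approximation with tie and continuity
corrections (fast at dataset scale). Multiple testing is controlled by
Benjamini-Hochberg step-up, over all b(b−1)/2 locus pairs for position-wise
tests (significance at FDR < 0.05) and over the k components for
component-wise tests (FDR < 0.1). The diagonal is identically zero and
never tested. Cells imaged from one sample are not independent; no
clustering correction is applied, and every result object carries that
caveat in its metadata.

The classifier is a random forest with standard defaults (100 trees, Gini
impurity, √d features per split, unlimited depth), trained on a
class-balanced subset (majority class downsampled without replacement) with
a stratified 70/30 split, so 0.5 is true chance level. Feature importances
are impurity-based and normalized to sum to 1. The permutation null refits
the identical pipeline on label permutations (class proportions preserved
by construction) and reports p = (#{null ≥ observed} + 1)/(n_perm + 1).

## Subpopulations

Given the components whose weights track transcription, cells are scored by
the mean weight over those components (an `any_component` union mode is
provided for sensitivity analysis, since aggregating over several
components admits either reading). With quantile q, the high group is the
top ⌈q·n⌉ transcribing cells and the low group the bottom ⌈q·n⌉
non-transcribing cells, ties at the boundary included. Groups are
contrasted by element-wise median maps, their difference map, and mean
anchor-to-target distances (the anchor may not appear among the targets —
its self-distance is 0 by construction and would bias the mean downward).

## Synthetic data

The generator plants what the templates of real decompositions look like:
two-block boundaries (within-block 0.1, cross-block 0.9), stripes (one
locus's row/column at 0.9 over a zero background) and compartment
checkerboards (period-q alternation, cross-compartment 0.9). Zero
backgrounds for stripe and checkerboard give each motif entries where the
others vanish, which keeps the planted factorization identifiable —
without anchors, NMF recovers the mixture only up to rotation and matched
correlations degrade even on noiseless data. Motifs pairwise correlated at
≥ 0.8 are rejected as redundant. Weights are Gamma(2, 0.5) (mean 1),
active per entry with probability `weight_sparsity`; an all-zero cell gets
one component activated. Noise is additive Gaussian (the minimal choice
consistent with an additive error term), clipped at zero, re-symmetrized,
diagonal re-zeroed. Dropout removes whole loci (row and column), as a
failed probe would, never isolated matrix cells. Labels follow a logistic
model on the column-standardized mean weight of the chosen components, the
intercept solved by bisection so expected prevalence is 0.5 — matching the
balanced designs used downstream. Coordinates, when needed, come from
per-cell classical (Torgerson) MDS with deterministic sign conventions;
exact for Euclidean-embeddable maps.

Default conditions: b = 32, k_true = 3, n = 500, noise sd 0.05 on the
normalized-distance scale, 10% locus dropout, labels on component 0 with
log-odds slope 2. No public noise/dropout characterization of tracing data
exists to calibrate against, so these are chosen for testability: strong
enough that recovery is non-trivial, weak enough that the planted truth is
recoverable. What the generator does **not** emulate: polymer physics
(planted maps are generally not Euclidean-embeddable), microscopy
point-spread noise, spatially correlated dropout, genome-wide multi-locus
structure, or cell-cell dependence. Passing tests therefore demonstrate
correctness of the machinery under the additive-mixture model, not
robustness to every artifact of real imaging data.

## Pipeline and reproducibility

`run_pipeline` executes preprocess → decompose → (optional select-k) →
analyze → associate → subpop. Each stage hashes its parameters together
with the upstream stage hash (SHA-256); re-running an unchanged
configuration skips completed stages, and changing a parameter invalidates
exactly the downstream stages. `components = "auto"` takes the components
significant in the component-wise test; it requires labels and is validated
before any stage runs. The manifest records package version, configuration,
per-stage status and per-file SHA-256 hashes; two runs with the same
configuration and seeds produce byte-identical numeric outputs. The UMAP
embedding is not part of the default pipeline run (it is available as a
library call and through the CLI): it contributes visualization, not
numbers, and keeping it out makes the end-to-end run light and its
determinism contract dependent only on the numeric stages.

## Problem sizes

Tests and the acceptance script run on synthetic conditions sized so the
statistical claims are meaningful at desk scale: template recovery and k
selection on 32 bins × 500 cells; error control over 100 replicates of 3
components × 500 cells; power over 20 replicates at n = 2000; subpopulation
recovery over 20 replicates of 16 bins × 400 cells; determinism on a full
double pipeline run at 16 bins × 120 cells.

## Known limitations

- NMF non-uniqueness: on real data without anchor structure, templates are
  identifiable only up to mixing; stability across restarts (the KSelector
  metric) is the practical diagnostic.
- Per-cell max normalization couples weights across components (the
  normalizer depends on the dominant component), which inflates the number
  of significant components in component-wise testing; this mirrors
  behavior on real data and is why subpopulation extraction should use the
  few components that are also top-ranked by classifier importance.
- No correction for within-sample dependence of cells; p-values are
  anti-conservative to an unknown degree on clustered data.
- The exact/asymptotic Mann-Whitney switch at n ≤ 8 means borderline-small
  groups use the normal approximation; at those sizes power is negligible
  anyway.
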