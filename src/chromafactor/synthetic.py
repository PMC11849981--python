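"""Ground-truthed synthetic ensembles with planted template-mixture structure.

The generative assumption under test is that each cell's normalized distance
matrix is (approximately) an additive, non-negative mixture of a small set of
shared template matrices plus noise:

    X_i  =  sum_k  W_k * H_ki  +  eps_i .

This module plants known templates W_true (chromatin-boundary, stripe and
compartment-checkerboard motifs), samples non-negative per-cell weights
H_true, adds truncated Gaussian noise, optionally drops whole loci (as a
failed probe would), couples binary transcription labels to a chosen subset
of component weights through a logistic model, and can embed each matrix back
into 3D coordinates so the coordinate-ingestion path is testable end to end.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .io_preproc import (CellEnsemble, DistanceTensor, FLOAT_FMT,
                         write_coordinate_table)

MOTIF_KINDS = ("boundary", "stripe", "checkerboard")

# Distinct RNG streams per operation, so that e.g. the noise draw does not
# shift when the weight sampler changes.
_STREAM_WEIGHTS = 1
_STREAM_NOISE = 2
_STREAM_LABELS = 3

#: Pairwise Pearson correlation (off-diagonal entries) above which two
#: requested motifs are considered redundant and rejected.
REDUNDANCY_LIMIT = 0.8


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic ensemble.

    Defaults describe a mid-sized single-locus tracing experiment: 32 bins,
    three well-separated planted templates, 500 cells, additive noise with
    s.d. 0.05 on the normalized-distance scale, 10% of loci dropped per cell,
    and transcription labels coupled to component 0 with log-odds slope 2.
    """

    b: int = 32
    k_true: int = 3
    n: int = 500
    template_spec: tuple | None = None
    weight_sparsity: float = 1.0
    noise_sd: float = 0.05
    dropout_frac: float = 0.1
    label_components: tuple = (0,)
    label_effect: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.b < 4:
            raise ValueError("b must be >= 4")
        if not 1 <= self.k_true <= self.b:
            raise ValueError("k_true must lie in [1, b]")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 < self.weight_sparsity <= 1:
            raise ValueError("weight_sparsity must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.dropout_frac < 1:
            raise ValueError("dropout_frac must lie in [0, 1)")
        comps = tuple(self.label_components)
        object.__setattr__(self, "label_components", comps)
        if any(not 0 <= c < self.k_true for c in comps):
            raise ValueError("label_components must be a subset of {0..k_true-1}")
        if self.template_spec is not None:
            spec = tuple(tuple(m) for m in self.template_spec)
            object.__setattr__(self, "template_spec", spec)
            if len(spec) != self.k_true:
                raise ValueError("template_spec length must equal k_true")

    def resolved_spec(self) -> tuple:
        return self.template_spec or default_template_spec(self.b, self.k_true)


@dataclass
class SyntheticDataset:
    """A generated ensemble together with its ground truth."""

    tensor: DistanceTensor
    W_true: np.ndarray          # (b, b, k_true)
    H_true: np.ndarray          # (k_true, n)
    labels: np.ndarray | None = None
    coords: np.ndarray | None = None   # (n, b, 3) once embedded
    missing_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.missing_mask is None:
            self.missing_mask = np.zeros((self.tensor.n, self.tensor.b), dtype=bool)


def default_template_spec(b: int, k_true: int) -> tuple:
    """Well-separated default motifs: boundaries, stripes, checkerboards in turn."""
    kinds = [MOTIF_KINDS[i % 3] for i in range(k_true)]
    counts = {kind: kinds.count(kind) for kind in MOTIF_KINDS}
    spec, seen = [], {kind: 0 for kind in MOTIF_KINDS}
    for kind in kinds:
        i = seen[kind]
        seen[kind] += 1
        if kind == "boundary":
            p = max(2, min(b - 2, b * (i + 1) // (counts["boundary"] + 1)))
            spec.append(("boundary", p))
        elif kind == "stripe":
            g = max(1, min(b - 2, b * (2 * i + 1) // (2 * counts["stripe"] + 2)))
            spec.append(("stripe", g))
        else:
            q = max(2, b // (8 * (i + 1)))
            spec.append(("checkerboard", q))
    return tuple(spec)


def _motif_matrix(kind: str, param: int, b: int) -> np.ndarray:
    """One b x b motif on the normalized-distance scale (small = close)."""
    if kind == "boundary":
        # two self-interacting blocks [0, p) and [p, b): close within, far across
        if not 1 <= param <= b - 1:
            raise ValueError(f"boundary position {param} outside [1, {b - 1}]")
        side = (np.arange(b) >= param).astype(int)
        M = np.where(side[:, None] == side[None, :], 0.1, 0.9)
    elif kind == "stripe":
        # locus param stands apart from everything: its row/column are elevated
        # over a zero background (zero background gives each motif anchor
        # entries, keeping the planted factorization identifiable)
        if not 0 <= param < b:
            raise ValueError(f"stripe bin {param} outside [0, {b})")
        M = np.zeros((b, b))
        M[param, :] = 0.9
        M[:, param] = 0.9
    elif kind == "checkerboard":
        # alternating compartments of period param: close within, far across
        if not 1 <= param <= b:
            raise ValueError(f"checkerboard period {param} outside [1, {b}]")
        comp = (np.arange(b) // param) % 2
        M = np.where(comp[:, None] == comp[None, :], 0.0, 0.9)
    else:
        raise ValueError(f"unknown motif kind {kind!r}")
    M = M.astype(float)
    np.fill_diagonal(M, 0.0)
    return M


def make_block_templates(config: SyntheticConfig) -> np.ndarray:
    """Build the planted template stack (b, b, k_true) from the motif spec.

    Raises ``ValueError`` if any motif falls outside the locus or if two
    motifs are redundant (off-diagonal Pearson correlation >= 0.8).
    """
    spec = config.resolved_spec()
    b = config.b
    W = np.stack([_motif_matrix(kind, param, b) for kind, param in spec], axis=2)
    off = ~np.eye(b, dtype=bool)
    for i in range(W.shape[2]):
        for j in range(i + 1, W.shape[2]):
            r = np.corrcoef(W[:, :, i][off], W[:, :, j][off])[0, 1]
            if not r < REDUNDANCY_LIMIT:
                raise ValueError(
                    f"motifs {spec[i]} and {spec[j]} are redundant (r = {r:.3f})")
    return W


def sample_weight_matrix(config: SyntheticConfig) -> np.ndarray:
    """Sample non-negative weights H_true of shape (k_true, n).

    Each entry is active with probability ``weight_sparsity``; active entries
    draw Gamma(2, 0.5) magnitudes (mean 1).  A column that comes out all zero
    gets one uniformly chosen component activated, so no cell is empty.
    """
    if config.weight_sparsity <= 0:
        raise ValueError("weight_sparsity must be positive")
    k, n = config.k_true, config.n
    rng = np.random.default_rng([config.seed, _STREAM_WEIGHTS])
    active = rng.random((k, n)) < config.weight_sparsity
    values = rng.gamma(2.0, 0.5, size=(k, n))
    H = np.where(active, values, 0.0)
    dead = np.flatnonzero(~active.any(axis=0))
    if dead.size:
        rows = rng.integers(0, k, size=dead.size)
        H[rows, dead] = rng.gamma(2.0, 0.5, size=dead.size)
    return H


def generate_distance_tensor(W_true: np.ndarray, H_true: np.ndarray,
                             noise_sd: float, dropout_frac: float,
                             seed: int) -> SyntheticDataset:
    """Mix templates into per-cell matrices; add noise; mark dropped loci.

    Slice ``i`` equals ``sum_k W_k H_ki`` plus Gaussian noise, clipped at
    zero, re-symmetrized and with the diagonal zeroed.  Dropout removes
    ``round(dropout_frac * b)`` whole loci per cell (recorded in
    ``missing_mask``; the tensor itself stays complete so the ground truth
    remains available).
    """
    W_true = np.asarray(W_true, dtype=float)
    H_true = np.asarray(H_true, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0 <= dropout_frac < 1:
        raise ValueError("dropout_frac must lie in [0, 1)")
    if W_true.ndim != 3 or H_true.ndim != 2 or W_true.shape[2] != H_true.shape[0]:
        raise ValueError("W_true (b,b,k) and H_true (k,n) must be conformable")
    b = W_true.shape[0]
    n = H_true.shape[1]
    rng = np.random.default_rng([seed, _STREAM_NOISE])
    data = np.einsum("ijk,kn->ijn", W_true, H_true)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
        data = np.clip(data, 0.0, None)
        data = 0.5 * (data + data.transpose(1, 0, 2))
        data[np.arange(b), np.arange(b), :] = 0.0
    mask = np.zeros((n, b), dtype=bool)
    n_drop = int(round(dropout_frac * b))
    if n_drop:
        for c in range(n):
            mask[c, rng.choice(b, size=n_drop, replace=False)] = True
    tensor = DistanceTensor(data, normalized=False, normalization_mode="none")
    return SyntheticDataset(tensor, W_true, H_true, missing_mask=mask)


def generate_transcription_labels(H_true: np.ndarray, label_components,
                                 label_effect: float, seed: int) -> np.ndarray:
    """Binary labels coupled to the mean weight over ``label_components``.

    P(label=1 | cell i) = logistic(label_effect * z_i + c) where z is the
    column-standardized mean of the selected weight rows and the intercept c
    is chosen (by bisection) so the expected positive fraction is 0.5.
    """
    comps = tuple(label_components)
    if not comps:
        raise ValueError("label_components must be non-empty")
    H_true = np.asarray(H_true, dtype=float)
    score = H_true[list(comps), :].mean(axis=0)
    sd = score.std()
    z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)

    def prevalence_gap(c):
        return expit(label_effect * z + c).mean() - 0.5

    intercept = brentq(prevalence_gap, -80.0, 80.0, xtol=1e-12)
    p = expit(label_effect * z + intercept)
    rng = np.random.default_rng([seed, _STREAM_LABELS])
    return (rng.random(p.shape) < p).astype(int)


def _cmdscale(D: np.ndarray, dim: int = 3) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling to ``dim`` coordinates."""
    b = D.shape[0]
    J = np.eye(b) - 1.0 / b
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dim]
    lam = np.clip(w[order], 0.0, None)
    X = V[:, order] * np.sqrt(lam)
    # eigenvectors have arbitrary sign; pin it for determinism
    for j in range(X.shape[1]):
        lead = np.argmax(np.abs(X[:, j]))
        if X[lead, j] < 0:
            X[:, j] = -X[:, j]
    return X


def embed_to_coordinates(dataset, seed: int = 0) -> np.ndarray:
    """Embed each cell's distance matrix into 3D via classical MDS.

    Accepts a :class:`SyntheticDataset` or a :class:`DistanceTensor`.
    Returns coordinates of shape (n, b, 3); exact for Euclidean-embeddable
    matrices, a least-squares 3D approximation otherwise.  ``seed`` is part
    of the generator contract but classical MDS is deterministic.
    """
    tensor = dataset.tensor if isinstance(dataset, SyntheticDataset) else dataset
    if np.isnan(tensor.data).any():
        raise ValueError("distance matrices contain NaN")
    n, b = tensor.n, tensor.b
    coords = np.empty((n, b, 3))
    for c in range(n):
        coords[c] = _cmdscale(tensor.data[:, :, c], dim=3)
    if isinstance(dataset, SyntheticDataset):
        dataset.coords = coords
    return coords


def generate_dataset(config: SyntheticConfig,
                     with_coords: bool = False) -> SyntheticDataset:
    """Full generator: templates -> weights -> tensor -> labels (-> coords)."""
    W = make_block_templates(config)
    H = sample_weight_matrix(config)
    dataset = generate_distance_tensor(W, H, config.noise_sd,
                                       config.dropout_frac, config.seed)
    dataset.labels = generate_transcription_labels(
        H, config.label_components, config.label_effect, config.seed)
    if with_coords:
        embed_to_coordinates(dataset, config.seed)
    return dataset


def to_cell_ensemble(dataset: SyntheticDataset, gene: str = "geneA") -> CellEnsemble:
    """View a generated dataset as a raw :class:`CellEnsemble`.

    Coordinates are embedded if absent; loci flagged in ``missing_mask`` are
    blanked out, emulating failed probes.
    """
    if dataset.coords is None:
        embed_to_coordinates(dataset)
    coords = dataset.coords.copy()
    coords[dataset.missing_mask] = np.nan
    labels = {} if dataset.labels is None else {gene: dataset.labels}
    ids = [f"cell_{c:05d}" for c in range(dataset.tensor.n)]
    return CellEnsemble(coords, dataset.missing_mask.copy(), ids, labels)


def write_dataset(dataset: SyntheticDataset, outdir, gene: str = "geneA") -> None:
    """Write the coordinate table plus a ground-truth sidecar.

    The sidecar manifest (``truth.json``) names TSV files holding W_true
    (flattened to b*b rows by k columns), H_true, labels and the dropout mask.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ensemble = to_cell_ensemble(dataset, gene=gene)
    write_coordinate_table(ensemble, outdir / "coordinates.tsv")
    b = dataset.tensor.b
    np.savetxt(outdir / "W_true.tsv", dataset.W_true.reshape(b * b, -1),
               fmt=FLOAT_FMT, delimiter="\t")
    np.savetxt(outdir / "H_true.tsv", dataset.H_true, fmt=FLOAT_FMT, delimiter="\t")
    np.savetxt(outdir / "missing_mask.tsv", dataset.missing_mask.astype(int),
               fmt="%d", delimiter="\t")
    manifest = {"b": b, "n": dataset.tensor.n, "k_true": dataset.W_true.shape[2],
                "coordinates": "coordinates.tsv", "W_true": "W_true.tsv",
                "H_true": "H_true.tsv", "missing_mask": "missing_mask.tsv"}
    if dataset.labels is not None:
        np.savetxt(outdir / "labels.tsv", dataset.labels, fmt="%d", delimiter="\t")
        manifest["labels"] = "labels.tsv"
        manifest["gene"] = gene
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
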