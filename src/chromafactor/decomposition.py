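"""Non-negative matrix factorization of distance-matrix stacks.

Each cell's b x b matrix is flattened to a length-b^2 vector; the resulting
b^2 x n matrix V is factorized as V ~ W H with W, H >= 0.  Columns of W,
reshaped back to b x b, are the *templates* — recurrent organization patterns
shared across the population — and H gives each template's weight in each
cell, so cell i is reconstructed as sum_k W_k H_ki.

The model object follows the statsmodels convention: build a
:class:`ChromaFactorModel` from data, call :meth:`~ChromaFactorModel.fit`,
and work with the returned :class:`Decomposition` results object.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .io_preproc import FLOAT_FMT, DistanceTensor


def flatten_tensor(tensor) -> np.ndarray:
    """Flatten a (b, b, n) tensor to the b^2 x n matrix V (row-major slices)."""
    data = tensor.data if isinstance(tensor, DistanceTensor) else np.asarray(tensor)
    if data.ndim != 3 or data.shape[0] != data.shape[1]:
        raise ValueError("expected a (b, b, n) stack")
    b = data.shape[0]
    return data.reshape(b * b, data.shape[2])


def unflatten_matrix(V: np.ndarray, b: int) -> np.ndarray:
    """Inverse of :func:`flatten_tensor`: b^2 x n -> (b, b, n)."""
    V = np.asarray(V)
    if V.shape[0] != b * b:
        raise ValueError("row count does not match b*b")
    return V.reshape(b, b, -1)


@dataclass
class Decomposition:
    """Fitted factorization results.

    Attributes
    ----------
    templates : ndarray, shape (b, b, k)
        Non-negative template matrices (symmetrized; see ``asymmetry_norm``).
    weights : ndarray, shape (k, n)
        Non-negative per-cell contribution of each template.
    solver_meta : dict
        init scheme, tolerance, max_iter, regularization, seed, iterations
        actually run, and a convergence flag.
    reconstruction_error : float
        Frobenius norm ||V - W H|| with the symmetrized templates.
    asymmetry_norm : float
        max_k ||W_k - W_k^T||_F / ||W_k||_F before symmetrization; flattened
        NMF does not know about matrix symmetry, so this records how much the
        raw factors violated it.
    """

    templates: np.ndarray
    weights: np.ndarray
    k: int
    b: int
    n: int
    solver_meta: dict
    reconstruction_error: float
    asymmetry_norm: float
    model: "ChromaFactorModel | None" = field(default=None, repr=False)

    def __post_init__(self):
        if (self.templates < 0).any() or (self.weights < 0).any():
            raise ValueError("templates and weights must be non-negative")

    # -- results API ---------------------------------------------------------

    def flat_templates(self) -> np.ndarray:
        """Templates as a b^2 x k matrix (columns flattened row-major)."""
        return self.templates.reshape(self.b * self.b, self.k)

    def reconstruct_cell(self, cell_index: int) -> np.ndarray:
        """Denoised map of one cell: sum_k templates[:, :, k] * weights[k, i]."""
        if not 0 <= cell_index < self.n:
            raise IndexError(f"cell_index {cell_index} outside [0, {self.n})")
        return np.tensordot(self.templates, self.weights[:, cell_index], axes=([2], [0]))

    def variance_explained(self) -> float:
        """Fraction of total variance captured, 1 - ||V - WH||^2 / ||V||^2."""
        if self.model is None:
            raise ValueError("results were loaded without data; "
                             "use variance_explained(V, dec) with the original matrix")
        return variance_explained(self.model.V, self)

    def summary(self) -> str:
        meta = self.solver_meta
        lines = [
            "ChromaFactor decomposition",
            "==========================",
            f"bins (b):              {self.b}",
            f"cells (n):             {self.n}",
            f"components (k):        {self.k}",
            f"init / solver:         {meta.get('init_scheme')} / coordinate descent",
            f"iterations run:        {meta.get('n_iter_run')} (max {meta.get('max_iter')})",
            f"converged:             {meta.get('converged')}",
            f"reconstruction error:  {self.reconstruction_error:.6g}",
            f"asymmetry norm:        {self.asymmetry_norm:.3g}",
        ]
        if self.model is not None:
            lines.append(f"variance explained:    {self.variance_explained():.4f}")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, outdir) -> None:
        """Write manifest JSON + per-component template TSVs + weights TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = []
        for j in range(self.k):
            fname = f"template_{j:03d}.tsv"
            np.savetxt(outdir / fname, self.templates[:, :, j],
                       fmt=FLOAT_FMT, delimiter="\t")
            files.append(fname)
        np.savetxt(outdir / "weights.tsv", self.weights, fmt=FLOAT_FMT, delimiter="\t")
        manifest = {
            "b": self.b, "n": self.n, "k": self.k,
            "templates": files, "weights": "weights.tsv",
            "solver_meta": self.solver_meta,
            "reconstruction_error": self.reconstruction_error,
            "asymmetry_norm": self.asymmetry_norm,
        }
        (outdir / "decomposition.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, indir) -> "Decomposition":
        indir = Path(indir)
        manifest = json.loads((indir / "decomposition.json").read_text())
        b, k = manifest["b"], manifest["k"]
        templates = np.empty((b, b, k))
        for j, fname in enumerate(manifest["templates"]):
            templates[:, :, j] = np.loadtxt(indir / fname, delimiter="\t").reshape(b, b)
        weights = np.loadtxt(indir / "weights.tsv", delimiter="\t").reshape(k, -1)
        return cls(templates=templates, weights=weights, k=k, b=b,
                   n=manifest["n"], solver_meta=manifest["solver_meta"],
                   reconstruction_error=manifest["reconstruction_error"],
                   asymmetry_norm=manifest["asymmetry_norm"], model=None)


class ChromaFactorModel:
    """NMF model over a stack of per-cell distance (or contact) matrices.

    Parameters
    ----------
    data : DistanceTensor or ndarray
        Either a :class:`~chromafactor.io_preproc.DistanceTensor` or a raw
        (b, b, n) array of non-negative symmetric matrices.

    Examples
    --------
    >>> model = ChromaFactorModel(tensor)            # doctest: +SKIP
    >>> results = model.fit(k=20, seed=0)            # doctest: +SKIP
    >>> print(results.summary())                     # doctest: +SKIP
    """

    def __init__(self, data):
        if isinstance(data, DistanceTensor):
            self.tensor = data
            self.V = flatten_tensor(data)
            self.b = data.b
        else:
            data = np.asarray(data, dtype=float)
            if data.ndim != 3 or data.shape[0] != data.shape[1]:
                raise ValueError("expected a (b, b, n) array or DistanceTensor")
            self.tensor = None
            self.V = flatten_tensor(data)
            self.b = data.shape[0]
        self.n = self.V.shape[1]

    @classmethod
    def from_matrix(cls, V: np.ndarray, b: int) -> "ChromaFactorModel":
        """Build directly from an already-flattened b^2 x n matrix."""
        return cls(unflatten_matrix(np.asarray(V, dtype=float), b))

    def fit(self, k: int = 20, tol: float = 1e-4, max_iter: int = 200,
            l2_reg: float = 0.0, init: str = "nndsvd", seed: int = 0) -> Decomposition:
        """Factorize V ~ W H under non-negativity and return the results.

        Coordinate-descent solver with Frobenius loss; ``init="nndsvd"``
        (deterministic SVD-based non-negative initialization) by default, or
        ``"random"`` for stability analyses.  ``l2_reg`` is the element-wise
        L2 penalty strength on both factors (default 0).  Raw templates are
        symmetrized as (W_k + W_k^T)/2 after fitting; the pre-symmetrization
        discrepancy is recorded, never silently discarded.
        """
        V = self.V
        if not np.isfinite(V).all():
            raise ValueError("V contains NaN or infinite entries")
        if (V < 0).any():
            raise ValueError("V contains negative entries")
        k_max = min(self.b * self.b, self.n)
        if not 1 <= k <= k_max:
            raise ValueError(f"k must lie in [1, {k_max}]")
        nmf = NMF(n_components=k, init=init, solver="cd", beta_loss="frobenius",
                  tol=tol, max_iter=max_iter, alpha_W=l2_reg, alpha_H="same",
                  l1_ratio=0.0, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            W_flat = nmf.fit_transform(V)
        H = nmf.components_
        W = W_flat.reshape(self.b, self.b, k)

        asym = 0.0
        for j in range(k):
            denom = np.linalg.norm(W[:, :, j])
            if denom > 0:
                asym = max(asym, np.linalg.norm(W[:, :, j] - W[:, :, j].T) / denom)
        W_sym = 0.5 * (W + W.transpose(1, 0, 2))
        err = float(np.linalg.norm(V - W_sym.reshape(self.b * self.b, k) @ H))
        meta = {
            "init_scheme": init,
            "tolerance": tol,
            "max_iter": max_iter,
            "regularization": l2_reg,
            "seed": seed,
            "n_iter_run": int(nmf.n_iter_),
            "converged": bool(nmf.n_iter_ < max_iter),
        }
        return Decomposition(templates=W_sym, weights=H, k=k, b=self.b, n=self.n,
                             solver_meta=meta, reconstruction_error=err,
                             asymmetry_norm=float(asym), model=self)

    def select_k(self, k_grid, n_inits: int = 4, labels=None, seed: int = 0):
        """Evaluate candidate component numbers; see :mod:`chromafactor.kselector`."""
        from .kselector import evaluate_k_grid
        return evaluate_k_grid(self, k_grid, n_inits=n_inits, labels=labels, seed=seed)


def fit_decomposition(V: np.ndarray, k: int, tolerance: float = 1e-4,
                      max_iter: int = 200, seed: int = 0,
                      l2_reg: float = 0.0, init: str = "nndsvd") -> Decomposition:
    """Functional entry point: fit a flattened b^2 x n matrix directly.

    ``V`` must have a square number of rows.
    """
    V = np.asarray(V, dtype=float)
    b = int(round(np.sqrt(V.shape[0])))
    if b * b != V.shape[0]:
        raise ValueError("V must have b^2 rows")
    model = ChromaFactorModel.from_matrix(V, b)
    return model.fit(k=k, tol=tolerance, max_iter=max_iter, l2_reg=l2_reg,
                     init=init, seed=seed)


def reconstruct_cell(dec: Decomposition, cell_index: int) -> np.ndarray:
    """Module-level alias of :meth:`Decomposition.reconstruct_cell`."""
    return dec.reconstruct_cell(cell_index)


def variance_explained(V, dec: Decomposition) -> float:
    """1 - ||V - WH||^2_F / ||V||^2_F, clipped to [0, 1].

    ``V`` may be the flattened matrix or a (b, b, n) stack / DistanceTensor.
    """
    if isinstance(V, DistanceTensor) or (hasattr(V, "ndim") and np.asarray(V).ndim == 3):
        V = flatten_tensor(V)
    V = np.asarray(V, dtype=float)
    total = np.linalg.norm(V)
    if total == 0:
        raise ValueError("V is all zeros; variance explained undefined")
    err = np.linalg.norm(V - dec.flat_templates() @ dec.weights)
    return float(np.clip(1.0 - (err / total) ** 2, 0.0, 1.0))
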