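"""Reading, QC filtering, imputation and normalization of chromatin traces.

Single-molecule chromatin tracing yields, per cell, the 3D position (nm) of a
contiguous run of genomic loci ("bins").  Probes fail, so loci can be missing.
This module turns a plain-text coordinate table into a stack of per-cell
pairwise Euclidean distance matrices, after excluding cells with too many
missing loci and linearly interpolating the remainder, and max-normalizes the
maps so that downstream boundary thresholds are scale-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import EmptyResultError, FormatError

REQUIRED_COLUMNS = ("cell_id", "locus_index", "x", "y", "z")
LABEL_PREFIX = "label_"
#: 17 significant digits round-trips any float64 bit-for-bit through text.
FLOAT_FMT = "%.17g"

NORMALIZATION_MODES = ("per_cell_max", "global_max", "none")


@dataclass
class CellEnsemble:
    """Per-cell locus coordinates with a missingness mask and optional labels.

    Parameters
    ----------
    coords : ndarray, shape (n, b, 3)
        Locus coordinates in nm; NaN at missing loci.
    missing_mask : ndarray of bool, shape (n, b)
        True where a locus was not observed (all three coordinates absent).
    cell_ids : list of str
        Stable identifiers, one per cell, in input order.
    labels : dict, optional
        Maps gene name -> length-n binary vector (1 = nascent transcription
        detected in that cell).
    bin_size : int, optional
        Genomic span per bin in bp; metadata only.
    """

    coords: np.ndarray
    missing_mask: np.ndarray
    cell_ids: list
    labels: dict = field(default_factory=dict)
    bin_size: int | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n, b, 3)")
        n, b, _ = self.coords.shape
        if n < 1 or b < 2:
            raise ValueError("need at least 1 cell and 2 loci")
        if self.missing_mask.shape != (n, b):
            raise ValueError("missing_mask must have shape (n, b)")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length must equal n")
        # mask true <=> all three coordinates absent
        all_nan = np.isnan(self.coords).all(axis=2)
        if not np.array_equal(all_nan, self.missing_mask):
            raise ValueError("missing_mask inconsistent with NaN pattern in coords")
        for gene, vec in self.labels.items():
            vec = np.asarray(vec)
            if vec.shape != (n,) or not np.isin(vec, [0, 1]).all():
                raise ValueError(f"label vector for {gene!r} must be length-n binary")
            self.labels[gene] = vec.astype(int)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def b(self) -> int:
        return self.coords.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Fraction of missing loci per cell, shape (n,)."""
        return self.missing_mask.mean(axis=1)


@dataclass
class DistanceTensor:
    """Stack of b x b non-negative symmetric distance matrices, shape (b, b, n)."""

    data: np.ndarray
    normalized: bool = False
    normalization_mode: str = "none"
    cell_ids: list | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("data must have shape (b, b, n)")
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ValueError(f"unknown normalization mode {self.normalization_mode!r}")
        if not np.isfinite(self.data).all():
            raise ValueError("distance tensor contains NaN or infinite entries")
        if (self.data < 0).any():
            raise ValueError("distance tensor contains negative entries")
        asym = np.abs(self.data - self.data.transpose(1, 0, 2)).max() if self.n else 0.0
        if asym > 1e-9:
            raise ValueError(f"slices not symmetric (max |M - M.T| = {asym:g})")
        diag = self.data[np.arange(self.b), np.arange(self.b), :]
        if diag.any():
            raise ValueError("slice diagonals must be exactly zero")
        if self.cell_ids is not None and len(self.cell_ids) != self.n:
            raise ValueError("cell_ids length must equal n")

    @property
    def b(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[2]

    def slice(self, c: int) -> np.ndarray:
        """Distance matrix of cell ``c`` (a view)."""
        return self.data[:, :, c]


def read_coordinate_table(path) -> CellEnsemble:
    """Read a TSV coordinate table into a :class:`CellEnsemble`.

    Expected header: ``cell_id  locus_index  x  y  z`` plus optional
    ``label_<gene>`` columns.  Empty coordinate fields (or NaN tokens) mark a
    missing locus; a locus with any coordinate absent is treated as missing.
    Locus indices must be 0-based and contiguous within every cell, and all
    cells must cover the same loci.
    """
    # round_trip parsing keeps 17-significant-digit writes bit-stable
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    df["cell_id"] = df["cell_id"].astype(str)
    if df.duplicated(subset=["cell_id", "locus_index"]).any():
        raise FormatError("duplicate (cell_id, locus_index) rows")
    cell_ids = list(pd.unique(df["cell_id"]))
    grouped = df.groupby("cell_id", sort=False)["locus_index"]
    sizes = grouped.agg(["size", "min", "max"])
    b = int(sizes["size"].iloc[0])
    if not ((sizes["size"] == b).all() and (sizes["min"] == 0).all()
            and (sizes["max"] == b - 1).all()):
        raise FormatError("ragged or non-contiguous locus_index across cells")

    n = len(cell_ids)
    coords = np.full((n, b, 3), np.nan)
    index_of = {cid: i for i, cid in enumerate(cell_ids)}
    rows = df["cell_id"].map(index_of).to_numpy()
    loci = df["locus_index"].to_numpy(dtype=int)
    coords[rows, loci] = df[["x", "y", "z"]].to_numpy(dtype=float)
    # partially observed loci count as missing (a probe either localized or not)
    partial = np.isnan(coords).any(axis=2)
    coords[partial] = np.nan
    mask = np.isnan(coords).all(axis=2)

    labels = {}
    for col in df.columns:
        if col.startswith(LABEL_PREFIX):
            per_cell = df.groupby("cell_id", sort=False)[col].first().to_numpy(dtype=float)
            if not np.isin(per_cell, [0, 1]).all():
                raise FormatError(f"label column {col!r} must contain only 0/1")
            labels[col[len(LABEL_PREFIX):]] = per_cell.astype(int)
    return CellEnsemble(coords, mask, cell_ids, labels)


def write_coordinate_table(ensemble: CellEnsemble, path) -> None:
    """Write a :class:`CellEnsemble` in the TSV layout read by
    :func:`read_coordinate_table`.  Missing loci become empty fields."""
    n, b = ensemble.n, ensemble.b
    records = {
        "cell_id": np.repeat(ensemble.cell_ids, b),
        "locus_index": np.tile(np.arange(b), n),
        "x": ensemble.coords[:, :, 0].ravel(),
        "y": ensemble.coords[:, :, 1].ravel(),
        "z": ensemble.coords[:, :, 2].ravel(),
    }
    for gene, vec in ensemble.labels.items():
        records[f"{LABEL_PREFIX}{gene}"] = np.repeat(vec, b)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False,
                                 float_format=FLOAT_FMT, na_rep="")


def filter_cells_by_missingness(ensemble: CellEnsemble,
                                max_missing_frac: float) -> CellEnsemble:
    """Drop cells whose missing-locus fraction strictly exceeds the threshold.

    Boundary cells (fraction exactly equal to ``max_missing_frac``) are kept:
    the QC rules are phrased as "over"/"more than".
    """
    if not 0 <= max_missing_frac < 1:
        raise ValueError("max_missing_frac must lie in [0, 1)")
    frac = ensemble.missing_fraction()
    keep = frac <= max_missing_frac
    if not keep.any():
        raise EmptyResultError(
            f"all {ensemble.n} cells exceed missing fraction {max_missing_frac}")
    labels = {g: v[keep] for g, v in ensemble.labels.items()}
    ids = [cid for cid, k in zip(ensemble.cell_ids, keep) if k]
    return CellEnsemble(ensemble.coords[keep], ensemble.missing_mask[keep],
                        ids, labels, ensemble.bin_size)


def impute_linear(ensemble: CellEnsemble) -> CellEnsemble:
    """Fill missing loci by per-axis linear interpolation along the locus index.

    Leading/trailing missing runs take the nearest observed value (constant
    extrapolation, the `numpy.interp` edge behaviour).  Observed coordinates
    are copied bit-for-bit; only masked positions are written.
    """
    observed = (~ensemble.missing_mask).sum(axis=1)
    if (observed < 2).any():
        bad = int(observed.argmin())
        raise ValueError(
            f"cell {ensemble.cell_ids[bad]!r} has fewer than 2 observed loci; "
            "filter before imputing")
    coords = ensemble.coords.copy()
    for c in range(ensemble.n):
        mask = ensemble.missing_mask[c]
        if not mask.any():
            continue
        obs = np.flatnonzero(~mask)
        miss = np.flatnonzero(mask)
        for axis in range(3):
            coords[c, miss, axis] = np.interp(miss, obs, ensemble.coords[c, obs, axis])
    zero_mask = np.zeros_like(ensemble.missing_mask)
    return CellEnsemble(coords, zero_mask, list(ensemble.cell_ids),
                        dict(ensemble.labels), ensemble.bin_size)


def compute_distance_tensor(ensemble: CellEnsemble) -> DistanceTensor:
    """All-by-all Euclidean distances (nm) between loci of each cell."""
    if ensemble.missing_mask.any() or np.isnan(ensemble.coords).any():
        raise ValueError("coordinates contain missing values; impute first")
    b, n = ensemble.b, ensemble.n
    data = np.empty((b, b, n))
    for c in range(n):
        data[:, :, c] = squareform(pdist(ensemble.coords[c]))
    return DistanceTensor(data, normalized=False, normalization_mode="none",
                          cell_ids=list(ensemble.cell_ids))


def normalize_max(tensor: DistanceTensor, mode: str = "per_cell_max") -> DistanceTensor:
    """Divide distances by the maximum observed, per cell or dataset-wide.

    ``per_cell_max`` scales every slice to [0, 1] (its own maximum becomes 1);
    ``global_max`` divides all slices by the dataset-wide maximum.  Both are
    idempotent.
    """
    if mode == "per_cell_max":
        maxima = tensor.data.max(axis=(0, 1))
        if (maxima <= 0).any():
            raise ValueError("a slice is all zeros; per-cell normalization undefined")
        out = tensor.data / maxima
    elif mode == "global_max":
        m = tensor.data.max()
        if m <= 0:
            raise ValueError("tensor is all zeros; normalization undefined")
        out = tensor.data / m
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return DistanceTensor(out, normalized=True, normalization_mode=mode,
                          cell_ids=tensor.cell_ids)


def save_tensor(tensor: DistanceTensor, outdir) -> None:
    """Persist a tensor as one TSV matrix per cell plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = tensor.cell_ids or [f"cell_{c}" for c in range(tensor.n)]
    files = []
    for c in range(tensor.n):
        fname = f"cell_{c:05d}.tsv"
        np.savetxt(outdir / fname, tensor.data[:, :, c], fmt=FLOAT_FMT, delimiter="\t")
        files.append(fname)
    manifest = {
        "b": tensor.b,
        "n": tensor.n,
        "normalized": tensor.normalized,
        "normalization_mode": tensor.normalization_mode,
        "cell_ids": list(ids),
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_tensor(indir) -> DistanceTensor:
    """Inverse of :func:`save_tensor`; round trip is bit-stable."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    b, n = manifest["b"], manifest["n"]
    data = np.empty((b, b, n))
    for c, fname in enumerate(manifest["files"]):
        data[:, :, c] = np.loadtxt(indir / fname, delimiter="\t").reshape(b, b)
    return DistanceTensor(data, normalized=manifest["normalized"],
                          normalization_mode=manifest["normalization_mode"],
                          cell_ids=list(manifest["cell_ids"]))


def read_labels_table(path, cell_ids=None) -> dict:
    """Read a long-format labels TSV (columns: cell_id, gene, state in {0,1}).

    Returns gene -> binary vector.  If ``cell_ids`` is given, vectors are
    aligned to that order and every id must be present for every gene.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    for col in ("cell_id", "gene", "state"):
        if col not in df.columns:
            raise FormatError(f"labels table missing column {col!r}")
    if not np.isin(df["state"].to_numpy(), [0, 1]).all():
        raise FormatError("label states must be 0/1")
    out = {}
    for gene, sub in df.groupby("gene"):
        series = sub.set_index("cell_id")["state"]
        if series.index.duplicated().any():
            raise FormatError(f"duplicate cell_id for gene {gene!r}")
        if cell_ids is not None:
            missing = [c for c in cell_ids if c not in series.index]
            if missing:
                raise FormatError(f"labels for gene {gene!r} missing cells {missing[:3]}")
            out[gene] = series.loc[list(cell_ids)].to_numpy(dtype=int)
        else:
            out[gene] = series.to_numpy(dtype=int)
    return out


def write_labels_table(labels: dict, cell_ids, path) -> None:
    """Write gene -> binary vector labels in the long TSV layout."""
    frames = []
    for gene, vec in labels.items():
        frames.append(pd.DataFrame({"cell_id": cell_ids, "gene": gene,
                                    "state": np.asarray(vec, dtype=int)}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
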