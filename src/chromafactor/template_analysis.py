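"""Characterization of templates and weights.

Insulation profiles and boundary calls on (normalized-distance) templates,
the directionality index on the matching similarity transform, dominant-
component labels, a 2D manifold embedding of the weight matrix, and
colocalization of called boundaries with protein-binding peaks.

Track conventions: templates here are max-normalized *distance* maps, where a
domain boundary shows up as a local *maximum* of the cross-window mean (loci
straddling a boundary are far apart).  The directionality index divides by
expected contacts, so distance input is first transformed to similarity
s = 1 - m; each :class:`TrackProfile` records which convention produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

TRACK_KINDS = ("insulation", "directionality")


@dataclass
class TrackProfile:
    """A per-bin score track along the locus."""

    values: np.ndarray
    window: int
    kind: str
    source: str = "template"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": np.arange(self.values.size),
                             "value": self.values})


@dataclass
class BoundaryCalls:
    """Bins called as domain boundaries on an insulation profile."""

    positions: list
    threshold: float
    profile: TrackProfile

    def __post_init__(self):
        self.positions = [int(p) for p in self.positions]
        if any(b >= a for a, b in zip(self.positions[1:], self.positions)):
            raise ValueError("positions must be strictly increasing")


@dataclass
class PeakTrack:
    """Protein-binding peaks mapped to bins: (bin_index, intensity, protein)."""

    entries: list = field(default_factory=list)

    def proteins(self) -> list:
        return sorted({name for _, _, name in self.entries})


def _check_square_symmetric(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    return M


def insulation_profile(M: np.ndarray, window: int,
                       source: str = "template") -> TrackProfile:
    """Sliding-window insulation score of a symmetric non-negative matrix.

    values[i] averages the cross-window block M[i-window+1..i, i+1..i+window]
    (clipped to valid indices) — the mean interaction value between the
    ``window`` bins ending at i and the ``window`` bins following it.  Bins
    with an empty block (only the last bin) are NaN.  On max-normalized
    distance maps boundaries appear as local maxima.
    """
    M = _check_square_symmetric(M)
    if (M < 0).any():
        raise ValueError("matrix must be non-negative")
    b = M.shape[0]
    if not 1 <= window < b / 2:
        raise ValueError(f"window must lie in [1, b/2) = [1, {b / 2:g})")
    values = np.full(b, np.nan)
    for i in range(b):
        rows = np.arange(max(0, i - window + 1), i + 1)
        cols = np.arange(i + 1, min(b, i + window + 1))
        if rows.size and cols.size:
            values[i] = M[np.ix_(rows, cols)].mean()
    return TrackProfile(values, window, "insulation", source)


def call_boundaries(profile: TrackProfile, threshold: float = 0.05) -> BoundaryCalls:
    """Interior strict local maxima of an insulation profile above threshold.

    A plateau (run of equal values) higher than both flanks is called at its
    leftmost bin.  Edge bins are never called; a flat profile yields nothing.
    """
    if profile.kind != "insulation":
        raise ValueError("boundary calling requires an insulation profile")
    v = profile.values
    b = v.size
    positions = []
    i = 1
    while i < b - 1:
        if np.isnan(v[i]):
            i += 1
            continue
        j = i
        while j + 1 < b and v[j + 1] == v[i]:
            j += 1
        left, right = v[i - 1], (v[j + 1] if j + 1 < b else np.nan)
        is_peak = (not np.isnan(left) and not np.isnan(right)
                   and left < v[i] and right < v[i] and j <= b - 2)
        if is_peak and v[i] > threshold:
            positions.append(i)
        i = j + 1
    return BoundaryCalls(positions, threshold, profile)


def directionality_index(M: np.ndarray, window: int,
                         input_kind: str = "distance",
                         source: str = "template") -> TrackProfile:
    """Signed chi-square-like statistic of upstream/downstream contact bias.

    With s the contact-like matrix (``input_kind="distance"`` applies
    s = 1 - m, appropriate for max-normalized distance maps), per bin i:

        A = sum s(i, i-window..i-1),  B = sum s(i, i+1..i+window)
        E = (A + B) / 2
        DI(i) = sign(B - A) * [ (A-E)^2/E + (B-E)^2/E ]

    Windows are truncated at the edges; DI = 0 when A = B or E = 0.
    Positive DI means downstream bias — the signature left of a boundary.
    """
    M = _check_square_symmetric(M)
    if window < 1:
        raise ValueError("window must be >= 1")
    if input_kind == "distance":
        S = 1.0 - M
    elif input_kind == "contact":
        S = M
    else:
        raise ValueError(f"unknown input_kind {input_kind!r}")
    b = M.shape[0]
    values = np.zeros(b)
    for i in range(b):
        A = S[i, max(0, i - window):i].sum()
        B = S[i, i + 1:min(b, i + window + 1)].sum()
        E = 0.5 * (A + B)
        if A == B or E == 0:
            continue
        values[i] = np.sign(B - A) * ((A - E) ** 2 / E + (B - E) ** 2 / E)
    return TrackProfile(values, window, "directionality", source)


def dominant_component_labels(H: np.ndarray) -> np.ndarray:
    """Per-cell index of the component with the largest weight.

    Ties break to the smallest index; an all-zero column gets sentinel -1.
    """
    H = np.asarray(H, dtype=float)
    if (H < 0).any():
        raise ValueError("H must be non-negative")
    labels = H.argmax(axis=0).astype(int)
    labels[(H == 0).all(axis=0)] = -1
    return labels


def embed_weights(H: np.ndarray, n_neighbors: int = 5, seed: int = 0) -> np.ndarray:
    """2D UMAP embedding of the columns (cells) of the weight matrix.

    ``n_neighbors=5`` with remaining library defaults; fixing ``seed`` makes
    the embedding deterministic (at the cost of parallelism).  The backend is
    umap-learn; its version is pinned by the environment.
    """
    H = np.asarray(H, dtype=float)
    n = H.shape[1]
    if n <= n_neighbors:
        raise ValueError(f"need more than n_neighbors={n_neighbors} cells, got {n}")
    import umap  # deferred: numba compilation is expensive at import time

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, random_state=seed)
    return np.asarray(reducer.fit_transform(H.T), dtype=float)


@dataclass
class ColocalizationResult:
    """Per-protein boundary match counts and per-boundary protein combos."""

    per_protein: dict               # protein -> {"matched": int, "unmatched": int}
    boundary_proteins: list         # tuple of protein names per boundary
    tolerance_bins: int


def peak_colocalization(calls: BoundaryCalls, peaks: PeakTrack,
                        tolerance_bins: int) -> ColocalizationResult:
    """Match called boundaries against protein peaks within a bin tolerance.

    A boundary matches a protein if any peak of that protein lies within
    ``tolerance_bins`` bins of it.  Also reports, per boundary, the sorted
    combination of co-binding proteins (e.g. CTCF+CP190 without Rad21).
    """
    if tolerance_bins < 0:
        raise ValueError("tolerance_bins must be >= 0")
    proteins = peaks.proteins()
    combos = []
    for pos in calls.positions:
        near = sorted({name for bin_idx, _, name in peaks.entries
                       if abs(bin_idx - pos) <= tolerance_bins})
        combos.append(tuple(near))
    per_protein = {}
    for prot in proteins:
        matched = sum(1 for combo in combos if prot in combo)
        per_protein[prot] = {"matched": matched,
                             "unmatched": len(calls.positions) - matched}
    return ColocalizationResult(per_protein, combos, tolerance_bins)


def read_peak_track(path, bin_size: int, n_bins: int | None = None) -> PeakTrack:
    """Read a BED-like TSV (chrom, start, end, name, score) into bins.

    Peaks map to ``midpoint // bin_size``; where several peaks of one protein
    land in a bin, the strongest intensity is kept.  Peaks falling outside
    ``[0, n_bins)`` (when given) are dropped.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score"])
    if df[["start", "end"]].isna().any().any():
        raise FormatError("peak table must have numeric start/end columns")
    bins = ((df["start"] + df["end"]) // 2 // bin_size).astype(int)
    best = {}
    for bin_idx, score, name in zip(bins, df["score"], df["name"]):
        if bin_idx < 0 or (n_bins is not None and bin_idx >= n_bins):
            continue
        key = (name, int(bin_idx))
        best[key] = max(best.get(key, -np.inf), float(score))
    entries = [(bin_idx, score, name) for (name, bin_idx), score in sorted(best.items())]
    return PeakTrack(entries)


def write_track(profile: TrackProfile, path) -> None:
    """Two-column TSV (bin, value); NaN for undefined edge bins."""
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
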