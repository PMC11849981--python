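"""High/low-contribution cell groups and their contact contrasts.

Once association testing has flagged the components whose weights track
transcription, the cells driving a bulk contact trend are isolated by taking
the transcribing cells with the top fraction of weight on those components
("high contribution") and the non-transcribing cells with the bottom
fraction ("low contribution"), then contrasting the groups' median distance
maps and anchor-enhancer distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_preproc import DistanceTensor

AGGREGATIONS = ("mean_weight", "any_component")


@dataclass
class ContributionGroups:
    """Disjoint high/low contribution cell index sets."""

    high_indices: np.ndarray
    low_indices: np.ndarray
    components_used: tuple
    aggregation: str
    quantile: float
    fraction_of_population: float

    def __post_init__(self):
        if np.intersect1d(self.high_indices, self.low_indices).size:
            raise ValueError("high and low groups must be disjoint")


def _select_extreme(indices: np.ndarray, scores: np.ndarray, quantile: float,
                    top: bool) -> np.ndarray:
    """Top (or bottom) ceil(quantile * n) cells of one class, ties included."""
    s = scores[indices]
    m = math.ceil(quantile * indices.size)
    ranked = np.sort(s)
    if top:
        cutoff = ranked[-m]
        return indices[s >= cutoff]
    cutoff = ranked[m - 1]
    return indices[s <= cutoff]


def assign_contribution_groups(H: np.ndarray, labels, components,
                               quantile: float = 0.5,
                               aggregation: str = "mean_weight") -> ContributionGroups:
    """Split cells into high/low contribution groups on selected components.

    ``quantile`` is the selected fraction per class: high = transcribing
    cells in the top ``quantile`` of the aggregated score, low =
    non-transcribing cells in the bottom ``quantile``.  Cells tied with the
    boundary score are included.  ``mean_weight`` scores each cell by the
    mean of the selected components' weights; ``any_component`` takes the
    union over components of the per-component extreme sets.
    """
    components = tuple(int(c) for c in components)
    if not components:
        raise ValueError("components must be non-empty")
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    H = np.asarray(H, dtype=float)
    labels = np.asarray(labels)
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if labels.size != H.shape[1]:
        raise ValueError("labels length must equal number of cells")
    if any(not 0 <= c < H.shape[0] for c in components):
        raise ValueError("component index out of range")
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both label classes must be present")

    if aggregation == "mean_weight":
        score = H[list(components), :].mean(axis=0)
        high = _select_extreme(pos, score, quantile, top=True)
        low = _select_extreme(neg, score, quantile, top=False)
    else:
        high_set, low_set = set(), set()
        for c in components:
            high_set.update(_select_extreme(pos, H[c], quantile, top=True).tolist())
            low_set.update(_select_extreme(neg, H[c], quantile, top=False).tolist())
        high = np.array(sorted(high_set), dtype=int)
        low = np.array(sorted(low_set), dtype=int)
    frac = (high.size + low.size) / labels.size
    return ContributionGroups(high_indices=np.sort(high), low_indices=np.sort(low),
                              components_used=components, aggregation=aggregation,
                              quantile=quantile, fraction_of_population=float(frac))


def median_distance_map(tensor: DistanceTensor, indices) -> np.ndarray:
    """Element-wise median map over the selected cells (symmetric, zero diag)."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("indices must be non-empty")
    return np.median(tensor.data[:, :, indices], axis=2)


def difference_map(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Element-wise map_a - map_b (may be negative): the contrast map."""
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    if map_a.shape != map_b.shape:
        raise ValueError("maps must have the same shape")
    return map_a - map_b


def locus_pair_distances(tensor: DistanceTensor, anchor_bin: int, target_bins,
                         indices) -> tuple:
    """Mean anchor-to-targets distance per selected cell, plus the group mean.

    Typical use: anchor = the gene promoter bin, targets = nearby enhancer
    bins; smaller values mean the enhancers sit closer to the gene.
    """
    target_bins = [int(t) for t in target_bins]
    indices = np.asarray(indices, dtype=int)
    b = tensor.b
    if not 0 <= anchor_bin < b or any(not 0 <= t < b for t in target_bins):
        raise ValueError("bin index out of range")
    if not target_bins:
        raise ValueError("target_bins must be non-empty")
    if anchor_bin in target_bins:
        raise ValueError("anchor_bin must not appear in target_bins "
                         "(self-distance is 0 by construction)")
    if indices.size == 0:
        raise ValueError("indices must be non-empty")
    per_cell = tensor.data[anchor_bin][target_bins][:, indices].mean(axis=0)
    return per_cell, float(per_cell.mean())
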