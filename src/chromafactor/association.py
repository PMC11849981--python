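"""Linking chromatin structure to transcription.

Nonparametric two-sided Mann-Whitney U tests compare transcribing vs
non-transcribing cells, either position-wise on the distance tensor (every
locus pair, BH-corrected at FDR 0.05) or component-wise on the NMF weight
matrix (BH over k components at FDR 0.1).  A balanced random-forest
classifier predicts transcription from the weights; a label-permutation null
calibrates its accuracy.

Caveat carried through to all results: cells imaged from the same sample are
not strictly independent, and no clustering correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

from .io_preproc import DistanceTensor

NON_INDEPENDENCE_CAVEAT = (
    "cells from the same sample may not be independent examples; "
    "no clustering correction applied")

#: Largest group size at which the exact (enumeration) MWU null is used.
EXACT_MWU_LIMIT = 8


def _check_binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both label classes must be present")
    return labels.astype(int)


def mann_whitney_u(x, y) -> tuple:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    U comes from rank sums with midranks for ties.  The p-value is computed
    by exact enumeration when both groups have <= 8 observations and there
    are no ties, otherwise by the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size <= EXACT_MWU_LIMIT and y.size <= EXACT_MWU_LIMIT and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialResult:
    """MWU statistics with BH-FDR control, position- or component-wise."""

    scope: str                       # "position" | "component"
    statistic: np.ndarray
    p_raw: np.ndarray
    q_fdr: np.ndarray
    significant: np.ndarray
    threshold: float
    group_sizes: tuple
    caveats: tuple = (NON_INDEPENDENCE_CAVEAT,)


def positionwise_differential(tensor: DistanceTensor, labels,
                              threshold: float = 0.05) -> DifferentialResult:
    """Test every locus pair (i < j) for a distance shift between classes.

    BH correction runs over all b(b-1)/2 tested pairs; results are mirrored
    into full symmetric b x b matrices with NaN diagonals (the diagonal is
    identically zero and never tested).
    """
    labels = _check_binary_labels(labels)
    if labels.size != tensor.n:
        raise ValueError("labels length must equal the number of cells")
    data = tensor.data
    b = tensor.b
    pos = labels == 1
    iu, ju = np.triu_indices(b, 1)
    stats = np.empty(iu.size)
    ps = np.empty(iu.size)
    for idx, (i, j) in enumerate(zip(iu, ju)):
        stats[idx], ps[idx] = mann_whitney_u(data[i, j, pos], data[i, j, ~pos])
    qs = bh_fdr(ps)

    def mirror(vec, fill=np.nan):
        M = np.full((b, b), fill)
        M[iu, ju] = vec
        M[ju, iu] = vec
        return M

    sig = mirror((qs < threshold).astype(float), fill=0.0).astype(bool)
    return DifferentialResult(scope="position", statistic=mirror(stats),
                              p_raw=mirror(ps), q_fdr=mirror(qs),
                              significant=sig, threshold=threshold,
                              group_sizes=(int(pos.sum()), int((~pos).sum())))


def componentwise_differential(H: np.ndarray, labels,
                               threshold: float = 0.1) -> DifferentialResult:
    """Test each component's weights for a shift between classes (BH over k)."""
    labels = _check_binary_labels(labels)
    H = np.asarray(H, dtype=float)
    if labels.size != H.shape[1]:
        raise ValueError("labels length must equal the number of cells")
    pos = labels == 1
    k = H.shape[0]
    stats = np.empty(k)
    ps = np.empty(k)
    for c in range(k):
        stats[c], ps[c] = mann_whitney_u(H[c, pos], H[c, ~pos])
    qs = bh_fdr(ps)
    return DifferentialResult(scope="component", statistic=stats, p_raw=ps,
                              q_fdr=qs, significant=qs < threshold,
                              threshold=threshold,
                              group_sizes=(int(pos.sum()), int((~pos).sum())))


def balanced_subset(labels, seed: int = 0) -> np.ndarray:
    """Indices giving equal class sizes: majority class downsampled uniformly
    without replacement to the minority size.  Sorted, deterministic."""
    labels = _check_binary_labels(labels)
    idx1 = np.flatnonzero(labels == 1)
    idx0 = np.flatnonzero(labels == 0)
    m = min(idx1.size, idx0.size)
    rng = np.random.default_rng(seed)
    if idx1.size > m:
        idx1 = rng.choice(idx1, size=m, replace=False)
    elif idx0.size > m:
        idx0 = rng.choice(idx0, size=m, replace=False)
    return np.sort(np.concatenate([idx1, idx0]))


@dataclass
class PermutationNull:
    """Label-permutation null distribution of classifier accuracy."""

    null_accuracies: tuple
    mean: float
    sd: float
    p_value: float
    observed: float


@dataclass
class ClassifierReport:
    """Held-out accuracy and feature importances of the balanced classifier."""

    accuracy: float
    feature_importances: np.ndarray
    split: dict
    balanced: bool = True
    permutation_null: PermutationNull | None = None
    caveats: tuple = (NON_INDEPENDENCE_CAVEAT,)


def fit_rf_classifier(features: np.ndarray, labels, train_frac: float = 0.7,
                      seed: int = 0) -> ClassifierReport:
    """Random forest on a balanced set with a stratified train/test split.

    Standard ensemble defaults (100 trees, Gini impurity, sqrt(d) features
    per split, unlimited depth), seeded.  Labels must already be balanced —
    use :func:`balanced_subset` first — so that 0.5 is true chance level.
    Importances are impurity-based and normalized to sum to 1.
    """
    labels = _check_binary_labels(labels)
    features = np.asarray(features, dtype=float)
    if features.shape[0] != labels.size:
        raise ValueError("features and labels disagree on n")
    if labels.size < 10:
        raise ValueError("need at least 10 cells")
    counts = np.bincount(labels, minlength=2)
    if counts[0] != counts[1]:
        raise ValueError("labels must be balanced; apply balanced_subset first")
    X_train, X_test, y_train, y_test = train_test_split(
        features, labels, train_size=train_frac, stratify=labels,
        random_state=seed)
    clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    clf.fit(X_train, y_train)
    accuracy = float(clf.score(X_test, y_test))
    imp = clf.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else np.full(imp.size, 1.0 / imp.size)
    return ClassifierReport(accuracy=accuracy, feature_importances=imp,
                            split={"train_frac": train_frac, "seed": seed})


def permutation_test(features: np.ndarray, labels, n_perm: int,
                     seed: int = 0, train_frac: float = 0.7) -> PermutationNull:
    """Label-permutation null for the balanced random-forest accuracy.

    Each permutation reassigns labels at random while preserving the class
    proportions exactly (a permutation of the label vector), refits the
    classifier pipeline, and records held-out accuracy.  The one-sided
    p-value is (#{null >= observed} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = _check_binary_labels(labels)
    observed = fit_rf_classifier(features, labels, train_frac=train_frac,
                                 seed=seed).accuracy
    rng = np.random.default_rng([seed, 17])
    nulls = []
    for _ in range(n_perm):
        permuted = labels[rng.permutation(labels.size)]
        nulls.append(fit_rf_classifier(features, permuted,
                                       train_frac=train_frac, seed=seed).accuracy)
    nulls = np.asarray(nulls)
    p = (int((nulls >= observed).sum()) + 1) / (n_perm + 1)
    return PermutationNull(null_accuracies=tuple(float(a) for a in nulls),
                           mean=float(nulls.mean()), sd=float(nulls.std()),
                           p_value=float(p), observed=float(observed))
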