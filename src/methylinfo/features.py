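"""Filter-style feature scoring and reduced feature spaces.

Scores each region (attribute) for its power to separate sample classes:

* multi-class AUC (pairwise one-vs-one rank AUCs averaged over class pairs);
* Pearson chi-squared of the class contingency table after entropy-based
  supervised discretization with the MDL stopping rule;
* PCA retaining the smallest prefix of components reaching a target share of
  the total variance, plus selection of regions by their correlation with
  the retained component scores;
* the per-region ratio of LCR- to IR-based chi-squared scores.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA

DEFAULT_VARIANCE_THRESHOLD = 0.80
DEFAULT_AUC_THRESHOLD = 0.80


@dataclass
class FeatureScore:
    region_id: str
    auc: float | None = None
    chi2: float | None = None
    method: str = ""


@dataclass
class PcaModel:
    """Loadings and explained-variance fractions of a centered PCA."""

    components: np.ndarray               # (n_components_total, n_features)
    explained_variance_ratio: np.ndarray
    n_retained: int
    mean: np.ndarray

    def transform(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        k = self.n_retained if n_components is None else n_components
        return (np.asarray(X, dtype=float) - self.mean) @ self.components[:k].T


# ---------------------------------------------------------------------------
# multi-class AUC
# ---------------------------------------------------------------------------

def pairwise_auc_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Multi-class AUC of every column of ``X`` against labels ``y``.

    For each unordered class pair the one-vs-one rank AUC is computed with
    midranks for ties, oriented so it is >= 0.5 (a single attribute has no
    preferred direction); the score is the mean over all class pairs.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < 1):
        raise ValueError("every class needs at least one sample")
    total = np.zeros(X.shape[1])
    n_pairs = 0
    for ci, cj in combinations(classes, 2):
        mask = (y == ci) | (y == cj)
        sub = X[mask]
        is_i = (y[mask] == ci)
        ni, nj = int(is_i.sum()), int((~is_i).sum())
        ranks = rankdata(sub, axis=0)  # midranks
        r_i = ranks[is_i].sum(axis=0)
        a = (r_i - ni * (ni + 1) / 2.0) / (ni * nj)
        total += np.maximum(a, 1.0 - a)
        n_pairs += 1
    return total / n_pairs


def hand_till_auc(values, labels) -> float:
    """Multi-class AUC of a single attribute (see ``pairwise_auc_matrix``)."""
    return float(pairwise_auc_matrix(np.asarray(values, dtype=float), np.asarray(labels))[0])


# ---------------------------------------------------------------------------
# MDL discretization (Fayyad & Irani)
# ---------------------------------------------------------------------------

def _class_entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def mdl_discretize(values, labels) -> list[float]:
    """Supervised discretization: recursive entropy-minimizing binary splits
    accepted only when the information gain beats the MDL criterion.

    Returns the sorted list of cut points (possibly empty).  Candidate cuts
    are midpoints between adjacent distinct values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    classes, y = np.unique(labels[order], return_inverse=True)
    n_classes = len(classes)
    onehot = np.zeros((len(v), n_classes))
    onehot[np.arange(len(v)), y] = 1.0

    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2:
            return
        seg_counts = onehot[lo:hi].sum(axis=0)
        ent_s = _class_entropy(seg_counts)
        if ent_s == 0.0:
            return
        cum = np.cumsum(onehot[lo:hi], axis=0)  # counts left of each boundary
        # boundaries between positions i and i+1 where the value changes
        boundary = np.flatnonzero(v[lo + 1:hi] != v[lo:hi - 1]) + 1
        if len(boundary) == 0:
            return
        left = cum[boundary - 1]
        right = seg_counts - left
        n_left = left.sum(axis=1)
        n_right = right.sum(axis=1)

        def ent_rows(c):
            tot = c.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(tot > 0, c / np.maximum(tot, 1), 0.0)
                t = np.where(p > 0, -p * np.log2(p), 0.0)
            return t.sum(axis=1)

        ent_l = ent_rows(left)
        ent_r = ent_rows(right)
        split_ent = (n_left * ent_l + n_right * ent_r) / n
        best = int(np.argmin(split_ent))
        gain = ent_s - split_ent[best]

        k = int((seg_counts > 0).sum())
        k1 = int((left[best] > 0).sum())
        k2 = int((right[best] > 0).sum())
        delta = math.log2(3 ** k - 2) - (
            k * ent_s - k1 * ent_l[best] - k2 * ent_r[best]
        )
        threshold = (math.log2(n - 1) + delta) / n
        if gain <= threshold:
            return
        b = int(boundary[best])
        cuts.append((v[lo + b - 1] + v[lo + b]) / 2.0)
        recurse(lo, lo + b)
        recurse(lo + b, hi)

    recurse(0, len(v))
    return sorted(cuts)


def chi_squared_score(values, labels) -> float:
    """Pearson chi-squared of the MDL-discretized attribute vs the class.

    Attributes for which discretization yields zero cuts carry no usable
    class information and score 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    cuts = mdl_discretize(values, labels)
    if not cuts:
        return 0.0
    bins = np.digitize(values, cuts)
    table = pd.crosstab(bins, labels).to_numpy(dtype=float)
    return _pearson_chi2(table)


def _pearson_chi2(table: np.ndarray) -> float:
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def chi2_score_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Chi-squared score of every column of ``X``."""
    X = np.asarray(X, dtype=float)
    return np.array([chi_squared_score(X[:, j], y) for j in range(X.shape[1])])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_extract(matrix, variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD):
    """Centered (not scaled) PCA; retain the smallest prefix of components
    whose cumulative explained-variance fraction reaches the threshold.

    ``matrix`` may be a RegionMatrix or a plain 2-D array (samples x
    features).  Returns ``(PcaModel, scores)`` where ``scores`` holds the
    retained component coordinates of each sample.
    """
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must be in (0, 1]")
    X = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    pca = PCA(svd_solver="full")
    all_scores = pca.fit_transform(X)
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    n_retained = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    n_retained = min(n_retained, len(ratio))
    model = PcaModel(
        components=pca.components_,
        explained_variance_ratio=ratio,
        n_retained=n_retained,
        mean=pca.mean_,
    )
    return model, all_scores[:, :n_retained]


def select_by_pc_correlation(
    matrix,
    n_components: int,
    top_k: int | None = None,
    threshold: float | None = None,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
):
    """Rank regions by max |Pearson correlation| with the first
    ``n_components`` PC score vectors; keep the top k or all above a
    correlation threshold.

    Returns ``(region_ids, correlations)`` for the selected regions, ranked
    by decreasing correlation.
    """
    if (top_k is None) == (threshold is None):
        raise ValueError("give exactly one of top_k or threshold")
    X = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    region_ids = list(getattr(matrix, "region_ids", range(X.shape[1])))
    model, scores = pca_extract(matrix, variance_threshold)
    if n_components > scores.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds retained components {scores.shape[1]}"
        )
    pcs = scores[:, :n_components]
    Xc = X - X.mean(axis=0)
    Pc = pcs - pcs.mean(axis=0)
    x_sd = Xc.std(axis=0)
    p_sd = Pc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Xc.T @ Pc) / len(X) / np.outer(x_sd, p_sd)
    corr = np.nan_to_num(corr, nan=0.0)
    best = np.abs(corr).max(axis=1)
    order = np.argsort(-best, kind="mergesort")
    if top_k is not None:
        chosen = order[:top_k]
    else:
        chosen = order[best[order] >= threshold]
    return [region_ids[i] for i in chosen], best[chosen]


# ---------------------------------------------------------------------------
# discriminatory-power ratio
# ---------------------------------------------------------------------------

def discriminatory_power_ratio(chi2_lcr, chi2_ir) -> pd.DataFrame:
    """Per-region ratio chi2_LCR / chi2_IR.

    Inputs are mappings or Series indexed by region id over the *same*
    region set.  Regions with chi2_IR = 0 get an infinite, flagged ratio and
    are excluded from summary statistics by the ``defined`` column.
    """
    s_lcr = pd.Series(chi2_lcr, dtype=float)
    s_ir = pd.Series(chi2_ir, dtype=float)
    if set(s_lcr.index) != set(s_ir.index):
        raise ValueError("region sets of the two score tables differ")
    s_ir = s_ir.reindex(s_lcr.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s_lcr / s_ir
    defined = s_ir > 0
    ratio = ratio.where(defined, np.inf)
    return pd.DataFrame({"ratio": ratio, "defined": defined})


def write_feature_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="region_id", float_format="%.12g")
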