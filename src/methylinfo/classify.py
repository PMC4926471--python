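"""Classifier chains, repeated cross-validation, UPGMA trees, Mantel test.

A chain is an ordered sequence of stages written as a config string, e.g.
``"auc+pca+lda"``: zero or more selection/extraction stages (``auc``,
``chi2``, ``pca``) followed by exactly one terminal classifier (``lda`` or
``svm``).  During cross-validation *every* stage is refit inside each
training fold, so selection never sees held-out samples.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import (
    DEFAULT_AUC_THRESHOLD,
    DEFAULT_VARIANCE_THRESHOLD,
    chi2_score_matrix,
    pairwise_auc_matrix,
)

TERMINAL_STAGES = ("lda", "svm")
SELECTION_STAGES = ("auc", "chi2", "pca")


# ---------------------------------------------------------------------------
# chain stages
# ---------------------------------------------------------------------------

class AucSelect:
    """Keep regions whose multi-class AUC passes a threshold (or the top k)."""

    def __init__(self, threshold: float = DEFAULT_AUC_THRESHOLD, top_k: int | None = None):
        self.threshold = threshold
        self.top_k = top_k

    def fit(self, X, y):
        scores = pairwise_auc_matrix(X, y)
        if self.top_k is not None:
            order = np.argsort(-scores, kind="mergesort")
            support = np.zeros(X.shape[1], dtype=bool)
            support[order[: self.top_k]] = True
        else:
            support = scores >= self.threshold
            if not support.any():  # never return an empty feature space
                support[int(np.argmax(scores))] = True
        self.scores_ = scores
        self.support_ = support
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]


class Chi2Select:
    """Keep regions with a positive MDL/chi-squared score (or the top k)."""

    def __init__(self, top_k: int | None = None):
        self.top_k = top_k

    def fit(self, X, y):
        scores = chi2_score_matrix(X, y)
        if self.top_k is not None:
            order = np.argsort(-scores, kind="mergesort")
            support = np.zeros(X.shape[1], dtype=bool)
            support[order[: self.top_k]] = True
        else:
            support = scores > 0
            if not support.any():
                support[int(np.argmax(scores))] = True
        self.scores_ = scores
        self.support_ = support
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]


class VariancePca:
    """Centered PCA keeping the smallest prefix of components reaching the
    variance threshold (capped at n_samples - 1)."""

    def __init__(self, variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD):
        if not (0.0 < variance_threshold <= 1.0):
            raise ValueError("variance_threshold must be in (0, 1]")
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        from sklearn.decomposition import PCA

        X = np.asarray(X, dtype=float)
        self._pca = PCA(svd_solver="full")
        self._pca.fit(X)
        cum = np.cumsum(self._pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.variance_threshold - 1e-12) + 1)
        self.n_components_ = min(k, len(cum), X.shape[0] - 1)
        return self

    def transform(self, X):
        return self._pca.transform(np.asarray(X, dtype=float))[:, : self.n_components_]


@dataclass
class ClassifierChain:
    """Parsed chain specification."""

    stage_names: tuple[str, ...]
    params: dict = field(default_factory=dict)

    @classmethod
    def from_string(cls, spec: str, **params) -> "ClassifierChain":
        names = tuple(s.strip().lower() for s in spec.split("+") if s.strip())
        if not names:
            raise ValueError("empty chain spec")
        if names[-1] not in TERMINAL_STAGES:
            raise ValueError(f"chain must end in one of {TERMINAL_STAGES}, got {names[-1]!r}")
        for name in names[:-1]:
            if name not in SELECTION_STAGES:
                raise ValueError(f"unknown selection stage {name!r}")
        if sum(n in TERMINAL_STAGES for n in names) != 1:
            raise ValueError("chain must contain exactly one terminal classifier")
        return cls(names, params)

    def __str__(self) -> str:
        return "+".join(self.stage_names)


def _build_stage(name: str, params: dict):
    if name == "auc":
        return AucSelect(
            threshold=params.get("auc_threshold", DEFAULT_AUC_THRESHOLD),
            top_k=params.get("auc_top_k"),
        )
    if name == "chi2":
        return Chi2Select(top_k=params.get("chi2_top_k"))
    if name == "pca":
        return VariancePca(params.get("variance_threshold", DEFAULT_VARIANCE_THRESHOLD))
    if name == "lda":
        return LinearDiscriminantAnalysis(solver="svd")
    if name == "svm":
        return SVC(
            kernel=params.get("svm_kernel", "rbf"),
            C=params.get("svm_c", 1.0),
            gamma=params.get("svm_gamma", "scale"),
        )
    raise ValueError(f"unknown stage {name!r}")


class FittedChain:
    """A chain fitted on one training set."""

    def __init__(self, chain: ClassifierChain, stages: list):
        self.chain = chain
        self.stages = stages

    def _reduce(self, X):
        Z = np.asarray(X, dtype=float)
        for stage in self.stages[:-1]:
            Z = stage.transform(Z)
        return Z

    def predict(self, X):
        return self.stages[-1].predict(self._reduce(X))

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    @property
    def has_lda(self) -> bool:
        return self.chain.stage_names[-1] == "lda"

    def ld_coordinates(self, X) -> np.ndarray:
        """Linear discriminant coordinates (n_samples x (classes - 1))."""
        if not self.has_lda:
            raise ValueError("chain has no LDA terminal stage")
        return self.stages[-1].transform(self._reduce(X))


def fit_chain(chain: ClassifierChain | str, X, y, **params) -> FittedChain:
    """Fit every stage of a chain on the full supplied data."""
    if isinstance(chain, str):
        chain = ClassifierChain.from_string(chain, **params)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    merged = {**chain.params, **params}
    if (
        chain.stage_names[-1] == "lda"
        and "pca" not in chain.stage_names
        and X.shape[1] >= X.shape[0]
    ):
        raise ValueError(
            "within-class scatter is singular with n_features >= n_samples; "
            "add a pca stage to the chain"
        )
    stages = []
    Z = X
    for name in chain.stage_names:
        stage = _build_stage(name, merged)
        stage.fit(Z, y)
        if name != chain.stage_names[-1]:
            Z = stage.transform(Z)
        stages.append(stage)
    return FittedChain(chain, stages)


# ---------------------------------------------------------------------------
# repeated cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Accuracy summary over repeated k-fold cross-validations (percent)."""

    accuracy_mean: float
    q025: float
    q975: float
    n_repeats: int
    n_folds: int
    accuracies: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if not (self.q025 <= self.accuracy_mean + 1e-9 and self.accuracy_mean <= self.q975 + 1e-9):
            raise ValueError("inconsistent quantiles")


def repeated_cv(
    chain: ClassifierChain | str,
    X,
    y,
    n_repeats: int = 1000,
    n_folds: int = 10,
    seed: int = 0,
    **params,
) -> CvResult:
    """Repeated stratified k-fold CV with all chain stages refit per fold.

    Each repeat uses fold seed ``seed + repeat`` so results are reproducible
    and repeats are independently re-runnable.  One accuracy per repeat
    (pooled over its folds); the distribution over repeats is summarized by
    its mean and 2.5%/97.5% quantiles, on a 0-100 scale.
    """
    if isinstance(chain, str):
        chain = ClassifierChain.from_string(chain, **params)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_folds > len(y):
        raise ValueError("n_folds exceeds the number of samples")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    eff_folds = int(min(n_folds, counts.min()))
    if eff_folds < 2:
        raise ValueError("smallest class has fewer than 2 members")
    if eff_folds < n_folds:
        warnings.warn(
            f"reducing folds {n_folds} -> {eff_folds} so every fold keeps "
            "at least one member of each class"
        )
    accuracies = np.empty(n_repeats)
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed + rep)
        correct = 0
        for train_idx, test_idx in skf.split(X, y):
            fitted = fit_chain(chain, X[train_idx], y[train_idx])
            correct += int(np.sum(fitted.predict(X[test_idx]) == y[test_idx]))
        accuracies[rep] = 100.0 * correct / len(y)
    return CvResult(
        accuracy_mean=float(accuracies.mean()),
        q025=float(np.quantile(accuracies, 0.025)),
        q975=float(np.quantile(accuracies, 0.975)),
        n_repeats=n_repeats,
        n_folds=eff_folds,
        accuracies=accuracies,
    )


def write_cv_table(results: dict[str, CvResult], path) -> None:
    """TSV with columns Classifier / Accuracy Mean / 2.5% Quantile / 97.5% Quantile."""
    with open(path, "w") as fh:
        fh.write("Classifier\tAccuracy Mean\t2.5% Quantile\t97.5% Quantile\n")
        for name, res in results.items():
            fh.write(
                f"{name}\t{res.accuracy_mean:.5f}\t{res.q025:.5f}\t{res.q975:.5f}\n"
            )


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    return d


class Dendrogram:
    """UPGMA merge tree with ultrametric heights, serializable as Newick."""

    def __init__(self, merge: np.ndarray, labels: Sequence[str]):
        self.merge = np.asarray(merge, dtype=float)  # scipy linkage format
        self.labels = list(labels)
        n = len(self.labels)
        self.heights = self.merge[:, 2] / 2.0  # node height = cluster distance / 2
        # precompute min leaf label per node for deterministic child ordering
        self._min_label: list[str] = list(self.labels)
        for a, b, *_ in self.merge:
            self._min_label.append(min(self._min_label[int(a)], self._min_label[int(b)]))

    def _node_height(self, node: int) -> float:
        n = len(self.labels)
        return 0.0 if node < n else float(self.heights[node - n])

    def _newick_node(self, node: int, parent_height: float) -> str:
        n = len(self.labels)
        branch = parent_height - self._node_height(node)
        if node < n:
            return f"{self.labels[node]}:{branch:g}"
        a, b = int(self.merge[node - n, 0]), int(self.merge[node - n, 1])
        if self._min_label[a] > self._min_label[b]:
            a, b = b, a
        h = self._node_height(node)
        inner = f"({self._newick_node(a, h)},{self._newick_node(b, h)})"
        return f"{inner}:{branch:g}"

    def newick(self) -> str:
        root = len(self.labels) + len(self.merge) - 1
        n = len(self.labels)
        a, b = int(self.merge[-1, 0]), int(self.merge[-1, 1])
        if self._min_label[a] > self._min_label[b]:
            a, b = b, a
        h = self._node_height(root)
        return f"({self._newick_node(a, h)},{self._newick_node(b, h)});"

    def cophenetic(self) -> np.ndarray:
        return squareform(cophenet(self.merge))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def upgma(dist_matrix, labels: Sequence[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) hierarchical clustering of a distance matrix."""
    d = _check_distance_matrix(dist_matrix)
    if labels is None:
        labels = [f"S{i}" for i in range(d.shape[0])]
    if len(labels) != d.shape[0]:
        raise ValueError("label count does not match matrix size")
    merge = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(merge, labels)


# ---------------------------------------------------------------------------
# distances and the Mantel test
# ---------------------------------------------------------------------------

def ld_distance_matrix(coordinates) -> np.ndarray:
    """Euclidean distances between samples placed at LD coordinates."""
    coords = np.asarray(coordinates, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    return squareform(pdist(coords))


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    method: str


def mantel_test(
    d1,
    d2,
    n_perm: int = 7000,
    method: str = "pearson",
    seed: int | None = None,
) -> MantelResult:
    """Permutation test of correlation between two distance matrices.

    The statistic is the correlation of the upper-triangle entries; the null
    distribution permutes rows and columns of the second matrix jointly.
    One-sided (greater) p-value with the (1 + b)/(1 + m) estimator, so p is
    never exactly 0.
    """
    d1 = _check_distance_matrix(d1)
    d2 = _check_distance_matrix(d2)
    if d1.shape != d2.shape:
        raise ValueError("distance matrices differ in size")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = d1[iu]

    def corr(v2):
        a, b = x, v2
        if method == "spearman":
            a, b = rankdata(a), rankdata(b)
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        if denom == 0:
            return 0.0
        return float((a @ b) / denom)

    r_obs = corr(d2[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(d2[np.ix_(perm, perm)][iu]) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_perm, method=method)


def write_distance_matrix(d: np.ndarray, labels: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, d):
            fh.write(lab + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_distance_matrix(path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in fields[1:]])
    return np.asarray(rows), header
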