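import itertools

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from methylinfo.features import (
    chi_squared_score,
    discriminatory_power_ratio,
    hand_till_auc,
    mdl_discretize,
    pairwise_auc_matrix,
    pca_extract,
    select_by_pc_correlation,
)
from methylinfo.infostats import RegionMatrix


def auc_oracle(values, labels):
    """Brute-force all-pairs rank AUC, averaged over class pairs."""
    classes = sorted(set(labels))
    scores = []
    for ci, cj in itertools.combinations(classes, 2):
        xi = [v for v, l in zip(values, labels) if l == ci]
        xj = [v for v, l in zip(values, labels) if l == cj]
        wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xi for b in xj)
        a = wins / (len(xi) * len(xj))
        scores.append(max(a, 1.0 - a))
    return sum(scores) / len(scores)


# ---------------------------------------------------------------------------
# Hand-Till AUC
# ---------------------------------------------------------------------------

def test_auc_perfect_separation():
    assert hand_till_auc([1, 2, 3, 10, 11, 12], list("AAABBB")) == 1.0
    # direction-free: reversed ordering is equally perfect
    assert hand_till_auc([10, 11, 12, 1, 2, 3], list("AAABBB")) == 1.0


def test_auc_constant_attribute():
    assert hand_till_auc([5, 5, 5, 5], list("AABB")) == 0.5


def test_auc_worked_example():
    assert hand_till_auc([1, 3, 2, 4], list("AABB")) == pytest.approx(0.75)


def test_auc_matches_oracle_random_instances(rng):
    for _ in range(60):
        n_classes = int(rng.integers(2, 5))
        labels = []
        for c in range(n_classes):
            labels += [f"c{c}"] * int(rng.integers(1, 6))
        values = rng.integers(0, 6, size=len(labels)).astype(float)  # many ties
        assert hand_till_auc(values, labels) == pytest.approx(
            auc_oracle(values, labels), abs=1e-12
        )


def test_auc_two_class_equals_classic_auc(rng):
    from sklearn.metrics import roc_auc_score

    y = np.array([0] * 10 + [1] * 15)
    x = rng.normal(size=25) + y
    classic = roc_auc_score(y, x)
    assert hand_till_auc(x, y) == pytest.approx(max(classic, 1 - classic), abs=1e-12)


def test_auc_monotone_transform_invariance(rng):
    x = rng.normal(size=30)
    y = rng.integers(0, 3, size=30)
    base = hand_till_auc(x, y)
    assert hand_till_auc(np.exp(x), y) == pytest.approx(base, abs=1e-12)
    assert hand_till_auc(3 * x - 7, y) == pytest.approx(base, abs=1e-12)


def test_auc_errors():
    with pytest.raises(ValueError):
        hand_till_auc([1, 2, 3], ["A", "A", "A"])


def test_auc_matrix_matches_scalar(rng):
    X = rng.normal(size=(20, 5))
    y = rng.integers(0, 3, size=20)
    scores = pairwise_auc_matrix(X, y)
    for j in range(5):
        assert scores[j] == pytest.approx(hand_till_auc(X[:, j], y), abs=1e-12)


# ---------------------------------------------------------------------------
# MDL discretization
# ---------------------------------------------------------------------------

def test_mdl_simple_split():
    cuts = mdl_discretize([1, 2, 3, 4], list("AABB"))
    assert len(cuts) == 1
    assert 2 < cuts[0] < 3


def test_mdl_all_equal_values():
    assert mdl_discretize([3, 3, 3, 3], list("AABB")) == []


def test_mdl_pure_labels_no_cut():
    assert mdl_discretize([1, 2, 3, 4], list("AAAA")) == []


def test_mdl_rejects_shuffled_labels(rng):
    rejected = 0
    n_rep = 200
    for _ in range(n_rep):
        values = rng.normal(size=8)
        labels = rng.permutation(list("AAAABBBB"))
        if not mdl_discretize(values, labels):
            rejected += 1
    assert rejected / n_rep >= 0.9


def test_mdl_recursive_splits():
    # three well-separated label blocks -> two cuts
    values = [1, 2, 3, 11, 12, 13, 21, 22, 23] * 2
    labels = (["A"] * 3 + ["B"] * 3 + ["C"] * 3) * 2
    cuts = mdl_discretize(values, labels)
    assert len(cuts) == 2
    assert 3 < cuts[0] < 11 and 13 < cuts[1] < 21


# ---------------------------------------------------------------------------
# chi-squared score
# ---------------------------------------------------------------------------

def test_chi2_perfect_2x2_table():
    values = [0.0] * 10 + [1.0] * 10
    labels = ["A"] * 10 + ["B"] * 10
    assert chi_squared_score(values, labels) == pytest.approx(20.0)


def test_chi2_zero_when_no_cuts(rng):
    values = rng.normal(size=8)
    labels = list("ABABABAB")
    # with arbitrary noise the MDL criterion usually rejects; force the
    # degenerate no-information case instead
    assert chi_squared_score([1.0] * 8, labels) == 0.0


def test_chi2_three_class_matches_contingency_oracle():
    values = [1, 2, 3, 4, 11, 12, 13, 14, 21, 22, 23, 24]
    labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
    score = chi_squared_score(values, labels)
    cuts = mdl_discretize(values, labels)
    bins = np.digitize(values, cuts)
    table = np.zeros((len(set(bins)), 3))
    for b, l in zip(bins, labels):
        table[b, "ABC".index(l)] += 1
    expected = chi2_contingency(table, correction=False).statistic
    assert score == pytest.approx(expected, abs=1e-9)


def test_chi2_invariant_to_bin_relabeling():
    # reversing the value axis permutes the bins but not the statistic
    values = np.array([1, 2, 3, 4, 11, 12, 13, 14], dtype=float)
    labels = ["A"] * 4 + ["B"] * 4
    assert chi_squared_score(values, labels) == pytest.approx(
        chi_squared_score(-values, labels)
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_matrix(rng):
    u = rng.normal(size=6)
    v = rng.normal(size=10)
    X = np.outer(u, v)
    model, scores = pca_extract(X, 0.8)
    assert model.n_retained == 1
    assert model.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_reconstruction(rng):
    X = rng.normal(size=(8, 5))
    model, _ = pca_extract(X, 1.0)
    full_scores = (X - model.mean) @ model.components.T
    recon = full_scores @ model.components + model.mean
    assert np.allclose(recon, X, atol=1e-10)


def test_pca_isotropic_noise_component_count(rng):
    X = rng.normal(size=(2000, 10))
    model, _ = pca_extract(X, 0.8)
    assert model.n_retained == 8  # equal eigenvalues: need k/10 >= 0.8


def test_pca_threshold_validation(rng):
    with pytest.raises(ValueError):
        pca_extract(rng.normal(size=(5, 3)), 0.0)
    with pytest.raises(ValueError):
        pca_extract(rng.normal(size=(5, 3)), 1.5)
    with pytest.raises(ValueError):
        pca_extract(rng.normal(size=(1, 3)), 0.8)


def test_pca_order_invariance_up_to_sign(rng):
    X = rng.normal(size=(12, 6)) @ np.diag([5, 3, 1, 1, 1, 1])
    _, scores = pca_extract(X, 0.8)
    perm = rng.permutation(12)
    _, scores_perm = pca_extract(X[perm], 0.8)
    k = min(scores.shape[1], scores_perm.shape[1])
    for j in range(k):
        a, b = scores[perm, j], scores_perm[:, j]
        assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


# ---------------------------------------------------------------------------
# PC-correlation selection
# ---------------------------------------------------------------------------

def _matrix_from(X):
    return RegionMatrix(
        [f"s{i}" for i in range(X.shape[0])],
        [f"r{j}" for j in range(X.shape[1])],
        X,
    )


def test_pc_correlation_selects_pc_aligned_region(rng):
    X = rng.normal(size=(30, 20))
    X[:, 3] = 20 * rng.normal(size=30)  # dominant direction -> PC1
    m = _matrix_from(X)
    selected, corr = select_by_pc_correlation(m, 1, top_k=1)
    assert selected == ["r3"]
    assert corr[0] > 0.99


def test_pc_correlation_noise_is_weak(rng):
    base = 10 * rng.normal(size=(100, 1)) @ rng.normal(size=(1, 5))
    noise = rng.normal(size=(100, 1))
    X = np.hstack([base, noise])
    m = _matrix_from(X)
    _, corr = select_by_pc_correlation(m, 1, top_k=6)
    ids, corrs = select_by_pc_correlation(m, 1, threshold=0.3)
    assert "r5" not in ids  # pure-noise region stays below threshold


def test_pc_correlation_top_k_count(rng):
    m = _matrix_from(rng.normal(size=(15, 20)))
    selected, _ = select_by_pc_correlation(m, 2, top_k=5)
    assert len(selected) == 5


def test_pc_correlation_argument_validation(rng):
    m = _matrix_from(rng.normal(size=(10, 4)))
    with pytest.raises(ValueError):
        select_by_pc_correlation(m, 1)
    with pytest.raises(ValueError):
        select_by_pc_correlation(m, 1, top_k=2, threshold=0.5)


# ---------------------------------------------------------------------------
# discriminatory-power ratio
# ---------------------------------------------------------------------------

def test_ratio_basics():
    out = discriminatory_power_ratio({"r1": 4.0, "r2": 3.0}, {"r1": 2.0, "r2": 3.0})
    assert out.loc["r1", "ratio"] == pytest.approx(2.0)
    assert out.loc["r2", "ratio"] == pytest.approx(1.0)
    assert out["defined"].all()


def test_ratio_zero_denominator_flagged():
    out = discriminatory_power_ratio({"r1": 4.0}, {"r1": 0.0})
    assert np.isinf(out.loc["r1", "ratio"])
    assert not out.loc["r1", "defined"]


def test_ratio_region_mismatch():
    with pytest.raises(ValueError):
        discriminatory_power_ratio({"r1": 1.0}, {"r2": 1.0})


def test_ratio_symmetric_generation_near_one(rng):
    # scores drawn from the same distribution for both statistics
    a = rng.chisquare(4, size=400)
    b = rng.chisquare(4, size=400)
    ids = [f"r{i}" for i in range(400)]
    out = discriminatory_power_ratio(dict(zip(ids, a)), dict(zip(ids, b)))
    med = np.median(out.loc[out["defined"], "ratio"])
    assert 0.7 < med < 1.4
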