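"""PLS-DA: latent structure, VIP identities and oracles, component
selection and the permutation test."""

import numpy as np
import pandas as pd
import pytest

from metabscreen.plsda import (
    PLSDAClassifier,
    permutation_test,
    q2_score,
    select_components,
)

from conftest import planted_matrix


def test_score_vectors_are_orthogonal():
    X, y = planted_matrix(n_per_class=30, p=12, informative=(0, 1, 2), seed=3)
    m = PLSDAClassifier(n_components=4).fit(X, y)
    T = m.x_scores_
    gram = T.T @ T
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_first_score_follows_single_informative_direction():
    rng = np.random.default_rng(0)
    n = 80
    latent = np.concatenate([rng.normal(-2, 0.3, n // 2), rng.normal(2, 0.3, n // 2)])
    direction = rng.normal(size=15)
    direction /= np.linalg.norm(direction)
    X = np.outer(latent, direction) + rng.normal(0, 0.05, (n, 15))
    y = np.array(["CTRL"] * (n // 2) + ["CRC"] * (n // 2))
    m = PLSDAClassifier(n_components=1).fit(X, y)
    r = np.corrcoef(m.x_scores_[:, 0], latent)[0, 1]
    assert abs(r) > 0.99


def test_row_permutation_equivariance():
    X, y = planted_matrix(seed=5)
    m1 = PLSDAClassifier(n_components=2).fit(X, y)
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(X))
    m2 = PLSDAClassifier(n_components=2).fit(X.iloc[perm], y.iloc[perm])
    np.testing.assert_allclose(m1.x_weights_, m2.x_weights_, atol=1e-8)
    np.testing.assert_allclose(m1.x_scores_[perm], m2.x_scores_, atol=1e-8)
    np.testing.assert_allclose(m1.vip_, m2.vip_, atol=1e-10)


def test_n_components_beyond_rank_rejected():
    X, y = planted_matrix(n_per_class=4, p=3)
    with pytest.raises(ValueError, match="exceeds rank"):
        PLSDAClassifier(n_components=8).fit(X, y)


def test_vip_sum_of_squares_equals_p():
    X, y = planted_matrix(n_per_class=25, p=17, informative=(0, 4), seed=9)
    m = PLSDAClassifier(n_components=3).fit(X, y)
    assert np.sum(m.vip_**2) == pytest.approx(17, abs=1e-6)


def test_vip_constant_when_weights_equal():
    """One component with equal |weights| on all features gives VIP = 1
    everywhere (the normalisation identity)."""
    rng = np.random.default_rng(2)
    n, p = 60, 6
    latent = rng.normal(size=n)
    X = np.outer(latent, np.ones(p)) + rng.normal(0, 1e-6, (n, p))
    y = np.where(latent > 0, "CRC", "CTRL")
    m = PLSDAClassifier(n_components=1).fit(X, y)
    np.testing.assert_allclose(m.vip_, 1.0, atol=1e-3)


def test_vip_matches_step_by_step_recomputation():
    """VIP on a 10x6 matrix equals the brute-force recomputation from
    W, T and q."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(10, 6))
    y = np.array(["CTRL"] * 5 + ["CRC"] * 5)
    m = PLSDAClassifier(n_components=3).fit(X, y)

    W, T, q = m.x_weights_, m.x_scores_, m.y_loadings_
    p, A = W.shape
    ssy = np.array([q[a] ** 2 * (T[:, a] @ T[:, a]) for a in range(A)])
    vip_oracle = np.empty(p)
    for j in range(p):
        acc = 0.0
        for a in range(A):
            w_ja = W[j, a] / np.sqrt(W[:, a] @ W[:, a])
            acc += ssy[a] * w_ja**2
        vip_oracle[j] = np.sqrt(p * acc / ssy.sum())
    np.testing.assert_allclose(m.vip_, vip_oracle, atol=1e-8)


def test_informative_feature_attains_max_vip():
    X, y = planted_matrix(n_per_class=40, p=20, informative=(7,), shift=3.0, seed=11)
    m = PLSDAClassifier(n_components=1).fit(X, y)
    assert int(np.argmax(m.vip_)) == 7


def test_r2_non_decreasing_and_q2_below_r2():
    X, y = planted_matrix(n_per_class=30, p=15, informative=(0, 1), seed=13)
    r2s = [PLSDAClassifier(n_components=a).fit(X, y).r2_ for a in range(1, 6)]
    assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))
    q2 = q2_score(X, y, 2, folds=5, seed=0)
    r2 = PLSDAClassifier(n_components=2).fit(X, y).r2_
    assert q2 <= r2 + 1e-12


def test_select_components_finds_two_direction_signal():
    """Signal confined to two orthogonal directions: never selects 1
    component over repeated seeds."""
    chosen = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = 100
        y01 = np.repeat([0, 1], n // 2)
        nuisance = rng.normal(0, 2.0, n)  # strong class-independent direction
        X = rng.normal(0, 0.3, (n, 12))
        X[:, 0] += 1.2 * y01 + nuisance  # signal contaminated by nuisance
        X[:, 1] += nuisance  # nuisance reference channel
        y = np.where(y01 == 1, "CRC", "CTRL")
        best, _ = select_components(X, y, max_c=4, folds=5, seed=seed)
        chosen.append(best)
    assert all(c >= 2 for c in chosen)  # one component cannot remove the nuisance
    assert sum(c in (2, 3) for c in chosen) >= 15


def test_select_components_single_option():
    X, y = planted_matrix(seed=17)
    best, acc = select_components(X, y, max_c=1, folds=5)
    assert best == 1 and list(acc.index) == [1]


def test_q2_non_positive_on_pure_noise_labels():
    vals = []
    for seed in range(30):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 30))
        y = np.array(["CTRL", "CRC"] * 30)
        vals.append(q2_score(X, y, 2, folds=5, seed=seed))
    assert np.mean(vals) <= 0


def test_permutation_p_attains_lower_bound_on_separable_data():
    X, y = planted_matrix(n_per_class=25, p=8, informative=(0, 1), shift=6.0, seed=19)
    p, obs, null = permutation_test(X, y, n_perm=99, seed=0, n_components=1, folds=5)
    assert obs == pytest.approx(1.0)
    assert p == pytest.approx(1 / 100)
    assert len(null) == 99


def test_permutation_null_is_calibrated():
    """Random labels: permutation p is roughly uniform (mean ~ 0.5)."""
    ps = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 10))
        y = rng.permutation(np.array(["CTRL", "CRC"] * 20))
        p, _, _ = permutation_test(X, y, n_perm=19, seed=seed, n_components=1, folds=4)
        ps.append(p)
    assert 0.3 < np.mean(ps) < 0.7


def test_permutation_rejects_zero_permutations():
    X, y = planted_matrix(seed=23)
    with pytest.raises(ValueError):
        permutation_test(X, y, n_perm=0)
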