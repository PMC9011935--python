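"""Internal clustering indices against brute-force oracles and an
independent library implementation."""

import warnings

import numpy as np
import pytest

from molclust.validation_metrics import (
    calinski_harabasz,
    davies_bouldin,
    evaluate_all,
    silhouette_index,
)

# ---------------------------------------------------------------------------
# brute-force oracles: literal double/triple loops over the definitions,
# written independently of the vectorized implementations


def silhouette_oracle(X, labels):
    n = len(X)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = np.inf
        for c in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, np.mean([np.linalg.norm(X[i] - X[j]) for j in other]))
        scores.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(scores))


def calinski_harabasz_oracle(X, labels):
    n, d = X.shape
    ks = sorted(set(labels))
    c_all = X.mean(axis=0)
    B = np.zeros((d, d))
    W = np.zeros((d, d))
    for q in ks:
        pts = X[np.asarray(labels) == q]
        c_q = pts.mean(axis=0)
        B += len(pts) * np.outer(c_q - c_all, c_q - c_all)
        for x in pts:
            W += np.outer(x - c_q, x - c_q)
    return (np.trace(B) / np.trace(W)) * ((n - len(ks)) / (len(ks) - 1))


def davies_bouldin_oracle(X, labels):
    ks = sorted(set(labels))
    cents = {q: X[np.asarray(labels) == q].mean(axis=0) for q in ks}
    spread = {
        q: np.mean([np.linalg.norm(x - cents[q]) for x in X[np.asarray(labels) == q]])
        for q in ks
    }
    total = 0.0
    for u in ks:
        worst = -np.inf
        for v in ks:
            if v == u:
                continue
            r = (spread[u] + spread[v]) / np.linalg.norm(cents[u] - cents[v])
            worst = max(worst, r)
        total += worst
    return total / len(ks)


def random_instance(rng, n_max=50, d_max=5):
    n = int(rng.integers(6, n_max + 1))
    d = int(rng.integers(1, d_max + 1))
    k = int(rng.integers(2, min(5, n - 1)))
    X = rng.standard_normal((n, d)) * rng.uniform(0.5, 3)
    labels = rng.integers(0, k, size=n)
    while np.unique(labels).size < 2:
        labels = rng.integers(0, k, size=n)
    return X, labels


# ---------------------------------------------------------------------------


def test_silhouette_frozen_1d_example():
    """{0,1} in cluster A and {10,11} in cluster B: a=1, b=mean(10,11)=10.5
    for point 0, and symmetrically for the others."""
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    labels = np.array([0, 0, 1, 1])
    expected = np.mean([9.5 / 10.5, 8.5 / 9.5, 8.5 / 9.5, 9.5 / 10.5])
    assert silhouette_index(X, labels) == pytest.approx(expected, abs=1e-12)
    assert silhouette_oracle(X, labels) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "ours,oracle,tol",
    [
        (silhouette_index, silhouette_oracle, 1e-12),
        (calinski_harabasz, calinski_harabasz_oracle, 1e-9),
        (davies_bouldin, davies_bouldin_oracle, 1e-12),
    ],
    ids=["silhouette", "calinski_harabasz", "davies_bouldin"],
)
def test_matches_brute_force_oracle(ours, oracle, tol):
    rng = np.random.default_rng(0)
    for _ in range(100):
        X, labels = random_instance(rng)
        assert ours(X, labels) == pytest.approx(oracle(X, labels), abs=tol)


def test_matches_independent_library():
    from sklearn import metrics as skm

    rng = np.random.default_rng(1)
    for _ in range(20):
        X, labels = random_instance(rng)
        assert silhouette_index(X, labels) == pytest.approx(
            skm.silhouette_score(X, labels), abs=1e-10
        )
        assert calinski_harabasz(X, labels) == pytest.approx(
            skm.calinski_harabasz_score(X, labels), rel=1e-10
        )
        # sklearn computes centroid distances via a dot-product identity,
        # which carries a little more float error than the direct norms
        assert davies_bouldin(X, labels) == pytest.approx(
            skm.davies_bouldin_score(X, labels), abs=1e-6
        )


def test_silhouette_random_labels_near_zero():
    rng = np.random.default_rng(2)
    for _ in range(20):
        X = rng.standard_normal((200, 4))
        labels = rng.integers(0, 3, size=200)
        assert abs(silhouette_index(X, labels)) < 0.1


def test_silhouette_limit_of_high_separation():
    rng = np.random.default_rng(3)
    prev = 0.0
    for sep in [5.0, 50.0, 500.0]:
        X = np.vstack(
            [rng.normal(0, 1, (10, 2)), rng.normal(sep, 1, (10, 2))]
        )
        s = silhouette_index(X, np.repeat([0, 1], 10))
        assert s > prev
        prev = s
    assert prev > 0.99


def test_silhouette_bounds_fuzz():
    rng = np.random.default_rng(4)
    for _ in range(300):
        X, labels = random_instance(rng, n_max=20, d_max=3)
        assert -1.0 <= silhouette_index(X, labels) <= 1.0


def test_singleton_cluster_contributes_zero():
    X = np.array([[0.0], [0.2], [5.0]])
    labels = np.array([0, 0, 1])
    assert silhouette_index(X, labels) == pytest.approx(
        silhouette_oracle(X, labels), abs=1e-12
    )


def test_ch_translation_invariance():
    rng = np.random.default_rng(5)
    X, labels = random_instance(rng)
    shifted = X + rng.standard_normal(X.shape[1]) * 37
    assert calinski_harabasz(X, labels) == pytest.approx(
        calinski_harabasz(shifted, labels), rel=1e-9
    )


def test_ch_increases_with_separation():
    rng = np.random.default_rng(6)
    blob = rng.standard_normal((30, 3))
    labels = np.repeat([0, 1], 30)
    scores = []
    for sep in [1.0, 2.0, 4.0, 8.0, 16.0]:
        X = np.vstack([blob, blob + sep])
        scores.append(calinski_harabasz(X, labels))
    assert np.all(np.diff(scores) > 0)


def test_ch_zero_within_dispersion_is_infinite():
    X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
    labels = np.array([0, 0, 1])
    with pytest.warns(UserWarning, match="infinite"):
        assert calinski_harabasz(X, labels) == np.inf


def test_db_separation_scaling_law():
    """Identical-shape blobs: doubling the centroid distance exactly halves
    the index (spreads unchanged, denominator doubled)."""
    rng = np.random.default_rng(7)
    blob = rng.standard_normal((40, 3))
    labels = np.repeat([0, 1], 40)
    shift = np.ones(3)
    near = davies_bouldin(np.vstack([blob, blob + 10 * shift]), labels)
    far = davies_bouldin(np.vstack([blob, blob + 20 * shift]), labels)
    assert far == pytest.approx(near / 2, rel=1e-9)


def test_db_directionality():
    rng = np.random.default_rng(8)
    labels = np.repeat([0, 1], 50)
    tight_far = np.vstack(
        [rng.normal(0, 0.3, (50, 2)), rng.normal(20, 0.3, (50, 2))]
    )
    overlapping = np.vstack(
        [rng.normal(0, 2.0, (50, 2)), rng.normal(1, 2.0, (50, 2))]
    )
    assert davies_bouldin(tight_far, labels) < davies_bouldin(overlapping, labels)


def test_db_coincident_centroids_rejected():
    X = np.array([[0.0], [2.0], [1.0], [1.0]])
    labels = np.array([0, 0, 1, 1])  # both centroids at 1.0
    with pytest.raises(ValueError, match="coincident"):
        davies_bouldin(X, labels)


class TestEvaluateAll:
    def test_deterministic_and_permutation_invariant(self):
        rng = np.random.default_rng(9)
        X, labels = random_instance(rng)
        r1 = evaluate_all(X, labels)
        r2 = evaluate_all(X, labels)
        assert r1 == r2
        relabeled = (np.asarray(labels) + 1) % (np.max(labels) + 1)
        r3 = evaluate_all(X, relabeled)
        assert r1.silhouette == pytest.approx(r3.silhouette, abs=1e-12)
        assert r1.calinski_harabasz == pytest.approx(r3.calinski_harabasz, rel=1e-12)
        assert r1.davies_bouldin == pytest.approx(r3.davies_bouldin, abs=1e-12)

    def test_translation_invariance_of_triple(self):
        rng = np.random.default_rng(10)
        X, labels = random_instance(rng)
        r1 = evaluate_all(X, labels)
        r2 = evaluate_all(X + 11.5, labels)
        assert r1.silhouette == pytest.approx(r2.silhouette, abs=1e-9)
        assert r1.davies_bouldin == pytest.approx(r2.davies_bouldin, abs=1e-9)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            evaluate_all(np.zeros((5, 2)), np.zeros(5, dtype=int))


def test_directionality_sweep_all_three():
    """As blob separation grows: Silhouette up, CH up, DB down."""
    rng = np.random.default_rng(11)
    blob = rng.standard_normal((40, 4))
    labels = np.repeat([0, 1], 40)
    sil, ch, db = [], [], []
    for sep in [2.0, 4.0, 8.0, 16.0, 32.0]:
        X = np.vstack([blob, blob + sep / 2])
        r = evaluate_all(X, labels)
        sil.append(r.silhouette)
        ch.append(r.calinski_harabasz)
        db.append(r.davies_bouldin)
    assert np.all(np.diff(sil) > 0)
    assert np.all(np.diff(ch) > 0)
    assert np.all(np.diff(db) < 0)
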