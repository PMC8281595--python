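"""Feature selection, clustering, survival ordering and clustering metrics."""

from math import comb

import numpy as np
import pytest

from omicsurv.data_model import SurvivalTable
from omicsurv.embedding import LatentMatrix
from omicsurv.errors import ClusteringError, NoSurvivalSignalError
from omicsurv.subtyping import (
    SurvivalFeatureMatrix,
    adjusted_rand_index,
    cluster_subtypes,
    clustering_stability,
    order_labels_by_survival,
    select_survival_features,
    silhouette,
)

from conftest import make_survival


def latent(values, tag="RNA", sample_ids=None):
    values = np.asarray(values, dtype=float)
    ids = sample_ids or [f"s{i:03d}" for i in range(values.shape[0])]
    return LatentMatrix(ids, [f"{tag}.{j}" for j in range(values.shape[1])], values)


def ari_contingency_oracle(a, b):
    """Hubert-Arabie ARI straight from the contingency-table formula."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    table = np.array([[(np.sum((a == x) & (b == y))) for y in ub] for x in ua])
    sum_ij = sum(comb(int(nij), 2) for nij in table.flatten())
    sum_a = sum(comb(int(ni), 2) for ni in table.sum(axis=1))
    sum_b = sum(comb(int(nj), 2) for nj in table.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if sum_ij == max_index else 0.0
    return (sum_ij - expected) / (max_index - expected)


def silhouette_oracle(X, labels):
    """Direct O(n^2) silhouette."""
    X, labels = np.asarray(X), np.asarray(labels)
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            scores.append(0.0)
            continue
        a = D[i][same].mean()
        b = min(
            D[i][labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestSelectSurvivalFeatures:
    def test_signal_column_retained(self):
        surv = make_survival(200, seed=0, censor=0.2)
        rng = np.random.default_rng(0)
        # column 0 tracks the hazard (scaled event-time rank); others noise
        signal = -np.log(surv.time)
        noise = rng.standard_normal((200, 5))
        lm = latent(np.column_stack([signal, noise]), sample_ids=surv.sample_ids)
        Z = select_survival_features([lm], surv, alpha=0.01)
        assert any(lid == "RNA.0" for _, lid, _ in Z.provenance)

    def test_pure_noise_false_positive_rate(self):
        # expected retained ~ alpha * columns, within binomial bounds over seeds
        total = kept = 0
        for seed in range(5):
            surv = make_survival(200, seed=seed, censor=0.2)
            rng = np.random.default_rng(seed)
            lm = latent(rng.standard_normal((200, 100)), sample_ids=surv.sample_ids)
            total += 100
            try:
                Z = select_survival_features([lm], surv, alpha=0.01)
                kept += Z.n_features
            except NoSurvivalSignalError:
                pass
        # binomial(500, 0.01): 99.9% upper bound ~ 16
        assert kept <= 16

    def test_alpha_one_retains_everything(self):
        surv = make_survival(50, seed=1)
        lm = latent(np.random.default_rng(1).standard_normal((50, 7)),
                    sample_ids=surv.sample_ids)
        Z = select_survival_features([lm], surv, alpha=1.0)
        assert Z.n_features == 7

    def test_no_signal_is_typed_outcome(self):
        surv = make_survival(50, seed=2)
        lm = latent(np.random.default_rng(2).standard_normal((50, 3)),
                    sample_ids=surv.sample_ids)
        with pytest.raises(NoSurvivalSignalError):
            select_survival_features([lm], surv, alpha=1e-12)


class TestCluster:
    def blobs(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        truth = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 4)) + truth[:, None] * 6
        return SurvivalFeatureMatrix([f"s{i}" for i in range(n)], X, []), truth

    def test_two_blobs_recovered(self):
        Z, truth = self.blobs()
        labels = cluster_subtypes(Z, K=2, seed=0, n_init=10)
        assert adjusted_rand_index(labels, truth) == 1.0

    def test_seed_determinism(self):
        Z, _ = self.blobs(seed=1)
        a = cluster_subtypes(Z, K=2, seed=5, n_init=10)
        b = cluster_subtypes(Z, K=2, seed=5, n_init=10)
        np.testing.assert_array_equal(a, b)

    def test_kmeans_backend(self):
        Z, truth = self.blobs(seed=2)
        labels = cluster_subtypes(Z, K=2, method="kmeans", seed=0, n_init=10)
        assert adjusted_rand_index(labels, truth) == 1.0

    def test_labels_within_range(self):
        rng = np.random.default_rng(3)
        truth = np.arange(90) % 3
        X = rng.standard_normal((90, 3)) + truth[:, None] * 5
        Z = SurvivalFeatureMatrix([f"s{i}" for i in range(90)], X, [])
        labels = cluster_subtypes(Z, K=2, seed=0, n_init=10)
        assert set(labels) <= {0, 1}

    def test_degenerate_input_rejected(self):
        Z = SurvivalFeatureMatrix(["a", "b", "c", "d"], np.ones((4, 2)), [])
        with pytest.raises(ClusteringError):
            cluster_subtypes(Z, K=2, seed=0)


class TestOrderLabels:
    def survival_for(self, times):
        return SurvivalTable(
            [f"s{i}" for i in range(len(times))],
            np.asarray(times, dtype=float),
            np.ones(len(times), dtype=int),
        )

    def test_worst_survival_becomes_label_zero(self):
        raw = np.array([0, 0, 0, 1, 1, 1])
        surv = self.survival_for([500, 520, 480, 100, 110, 90])
        lab = order_labels_by_survival(raw, surv)
        np.testing.assert_array_equal(lab.ordered_labels, [1, 1, 1, 0, 0, 0])
        assert np.all(np.diff(lab.median_survival_per_label) >= 0)

    def test_three_group_permutation(self):
        raw = np.repeat([0, 1, 2], 4)
        surv = self.survival_for([300] * 4 + [100] * 4 + [200] * 4)
        lab = order_labels_by_survival(raw, surv)
        np.testing.assert_array_equal(lab.ordered_labels, np.repeat([2, 0, 1], 4))

    def test_tied_medians_deterministic_smaller_group_first(self):
        raw = np.array([0, 0, 0, 1, 1])
        surv = self.survival_for([100, 100, 100, 100, 100])
        a = order_labels_by_survival(raw, surv)
        b = order_labels_by_survival(raw, surv)
        np.testing.assert_array_equal(a.ordered_labels, b.ordered_labels)
        assert a.ordered_labels[3] == 0  # group of 2 < group of 3

    def test_censoring_uses_km_median_not_naive(self):
        # heavy censoring in group 0 hides its long true survival
        sample_ids = [f"s{i}" for i in range(8)]
        time = np.array([50.0, 60, 70, 80, 30, 35, 40, 45])
        event = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        surv = SurvivalTable(sample_ids, time, event)
        raw = np.repeat([0, 1], 4)
        lab = order_labels_by_survival(raw, surv)
        assert lab.ordered_labels[0] == 1  # censored-rich group is not "worst"


class TestMetrics:
    def test_ari_identity_and_renaming(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, 40)
        assert adjusted_rand_index(x, x) == 1.0
        assert adjusted_rand_index(x, 2 - x) == 1.0

    def test_ari_matches_contingency_oracle(self):
        a = [0, 0, 1, 1, 2]
        b = [0, 0, 1, 2, 2]
        assert adjusted_rand_index(a, b) == pytest.approx(ari_contingency_oracle(a, b))
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(5, 30)
            x = rng.integers(0, 4, n)
            y = rng.integers(0, 4, n)
            assert adjusted_rand_index(x, y) == pytest.approx(
                ari_contingency_oracle(x, y), abs=1e-12
            )

    def test_silhouette_matches_direct_computation(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            X = rng.standard_normal((25, 3))
            labels = rng.integers(0, 3, 25)
            if len(np.unique(labels)) < 2:
                continue
            Z = SurvivalFeatureMatrix([f"s{i}" for i in range(25)], X, [])
            assert silhouette(Z, labels) == pytest.approx(
                silhouette_oracle(X, labels), abs=1e-10
            )

    def test_stability_is_mean_pairwise_ari(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 0, 1, 1])
        c = np.array([0, 1, 0, 1])
        expected = np.mean(
            [
                adjusted_rand_index(a, b),
                adjusted_rand_index(a, c),
                adjusted_rand_index(b, c),
            ]
        )
        assert clustering_stability([a, b, c]) == pytest.approx(expected)
        assert np.isnan(clustering_stability([a]))


def test_worst_label_has_higher_event_rate(strong_cohort, fast_config):
    """On a hazard-ratio-3 cohort the ordered label 0 group dies more."""
    from omicsurv import fit_ensemble, predict_ensemble

    ens = fit_ensemble(strong_cohort.dataset, n_models=2, K=2, seed=3, config=fast_config)
    pred = predict_ensemble(ens, strong_cohort.dataset)
    ev = strong_cohort.dataset.survival.event
    worst_rate = ev[pred.labels == 0].mean()
    other_rate = ev[pred.labels == 1].mean()
    assert worst_rate > other_rate
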