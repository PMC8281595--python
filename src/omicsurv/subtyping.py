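"""Survival-associated latent feature selection and subtype clustering.

The latent features of every omic's autoencoder are screened with a
univariate Cox-PH model; those associated with survival (likelihood-ratio
p < ``alpha``, default 0.01) are concatenated across omics into the matrix
``Z``. Samples are then clustered on ``Z`` — by default with a diagonal-
covariance Gaussian mixture (up to 1000 EM iterations, best of 100
seeded initializations) — and the clusters are relabeled by survival so
that label 0 always denotes the worst-survival subtype.

"Median survival" of a cluster means its Kaplan-Meier median; when the KM
curve never crosses 1/2 the restricted mean survival time (horizon = last
observed time) is used instead, since a naive median of observed times is
biased under censoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.mixture import GaussianMixture

from .data_model import MultiOmicsDataset, SurvivalTable
from .embedding import LatentMatrix
from .errors import ClusteringError, NoSurvivalSignalError
from .survival_stats import CoxPrep, fit_univariate_coxph

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
DEFAULT_GMM_INIT = 100
DEFAULT_GMM_ITER = 1000


@dataclass
class SurvivalFeatureMatrix:
    """Retained latent features (samples x p) with per-column provenance."""

    sample_ids: list[str]
    values: np.ndarray
    provenance: list[tuple[str, str, float]]  # (omic_tag, latent_id, cox_p)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SubtypeLabeling:
    """Cluster labels reordered so label 0 has the worst survival."""

    sample_ids: list[str]
    raw_labels: np.ndarray
    ordered_labels: np.ndarray
    K: int
    median_survival_per_label: np.ndarray  # days, non-decreasing


@dataclass
class MetricsReport:
    """Quality metrics of one fitted model or ensemble; unavailable metrics
    are carried as NaN rather than dropped."""

    logrank_p: float = np.nan
    c_index: float = np.nan
    silhouette: float = np.nan
    stability_ari: float = np.nan
    K: int = 0
    n_retained_models: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "logrank_p": self.logrank_p,
            "c_index": self.c_index,
            "silhouette": self.silhouette,
            "stability_ari": self.stability_ari,
            "K": self.K,
            "n_retained_models": self.n_retained_models,
        }
        out.update(self.extra)
        return out


def select_survival_features(
    latents: list[LatentMatrix],
    survival: SurvivalTable,
    alpha: float = DEFAULT_ALPHA,
) -> SurvivalFeatureMatrix:
    """Concatenate all latent columns whose univariate Cox p-value < alpha.

    Raises :class:`NoSurvivalSignalError` when nothing passes — callers in
    the boosting loop treat that as an invalid member, not a crash.
    """
    if not latents:
        raise ValueError("no latent matrices given")
    sample_ids = list(latents[0].sample_ids)
    for lm in latents:
        if list(lm.sample_ids) != sample_ids:
            raise ValueError("latent matrices must share sample order")
    if list(survival.sample_ids) != sample_ids:
        raise ValueError("latents and survival must share sample order")
    prep = CoxPrep(survival)
    cols, provenance = [], []
    for lm in latents:
        for j, latent_id in enumerate(lm.latent_ids):
            res = fit_univariate_coxph(lm.values[:, j], survival, prep=prep)
            if res.p_value < alpha:
                cols.append(lm.values[:, j])
                omic_tag = latent_id.rsplit(".", 1)[0]
                provenance.append((omic_tag, latent_id, res.p_value))
    if not cols:
        raise NoSurvivalSignalError(
            f"no latent feature reached Cox p < {alpha}"
        )
    return SurvivalFeatureMatrix(sample_ids, np.column_stack(cols), provenance)


def cluster_subtypes(
    Z: SurvivalFeatureMatrix,
    K: int,
    method: str = "gmm",
    seed: int = 0,
    n_init: int = DEFAULT_GMM_INIT,
    max_iter: int = DEFAULT_GMM_ITER,
) -> np.ndarray:
    """Cluster samples on Z; returns raw (unordered) labels.

    ``gmm`` is the default: diagonal covariance, ``max_iter`` EM iterations,
    best of ``n_init`` initializations by likelihood. ``kmeans`` is the
    drop-in alternative.
    """
    values = Z.values
    n = values.shape[0]
    if K < 2:
        raise ClusteringError("K must be >= 2")
    if n <= K:
        raise ClusteringError(f"need more than K={K} samples, got {n}")
    if np.allclose(values, values[0]):
        raise ClusteringError("degenerate feature matrix: all samples identical")
    if method == "gmm":
        model = GaussianMixture(
            n_components=K,
            covariance_type="diag",
            max_iter=max_iter,
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-6,
        )
        return model.fit_predict(values)
    if method == "kmeans":
        model = KMeans(n_clusters=K, n_init=n_init, max_iter=max_iter, random_state=seed)
        return model.fit_predict(values)
    raise ValueError(f"unknown clustering method '{method}'")


def _km_median_or_rmst(time: np.ndarray, event: np.ndarray) -> float:
    kmf = KaplanMeierFitter().fit(time, event)
    median = kmf.median_survival_time_
    if np.isfinite(median):
        return float(median)
    # KM curve never reaches 1/2: fall back to restricted mean survival time
    return float(restricted_mean_survival_time(kmf, t=float(time.max())))


def order_labels_by_survival(
    raw_labels: np.ndarray, survival: SurvivalTable
) -> SubtypeLabeling:
    """Relabel clusters so label 0 has the lowest median survival.

    Ties in median survival are broken deterministically: the smaller group
    gets the worse label (with a warning), then the raw label id.
    """
    raw_labels = np.asarray(raw_labels)
    groups = np.unique(raw_labels)
    if any((raw_labels == g).sum() == 0 for g in groups):
        raise ClusteringError("empty cluster in labeling")
    stats = []
    for g in groups:
        mask = raw_labels == g
        med = _km_median_or_rmst(survival.time[mask], survival.event[mask])
        stats.append((med, int(mask.sum()), g))
    medians = [s[0] for s in stats]
    if len(set(medians)) < len(medians):
        logger.warning("tied median survival between clusters; smaller group ranked worse")
    order = sorted(stats)  # by (median, group size, raw label)
    mapping = {g: new for new, (_, _, g) in enumerate(order)}
    ordered = np.array([mapping[g] for g in raw_labels])
    return SubtypeLabeling(
        sample_ids=list(survival.sample_ids),
        raw_labels=raw_labels,
        ordered_labels=ordered,
        K=len(groups),
        median_survival_per_label=np.array([m for m, _, _ in order]),
    )


def silhouette(Z: SurvivalFeatureMatrix | np.ndarray, labels) -> float:
    """Mean silhouette coefficient (Euclidean) of a labeling on Z."""
    values = Z.values if isinstance(Z, SurvivalFeatureMatrix) else np.asarray(Z)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ClusteringError("silhouette requires >= 2 clusters")
    return float(silhouette_score(values, labels, metric="euclidean"))


def adjusted_rand_index(a, b) -> float:
    """Hubert-Arabie chance-corrected agreement between two labelings."""
    return float(adjusted_rand_score(np.asarray(a), np.asarray(b)))


def clustering_stability(labelings: list[np.ndarray]) -> float:
    """Mean pairwise ARI over all model pairs; NaN for fewer than two."""
    if len(labelings) < 2:
        return float("nan")
    scores = [
        adjusted_rand_index(labelings[i], labelings[j])
        for i in range(len(labelings))
        for j in range(i + 1, len(labelings))
    ]
    return float(np.mean(scores))


def select_K(
    dataset: MultiOmicsDataset,
    candidates=(2, 3, 4, 5),
    seed: int = 0,
    **ensemble_kwargs,
):
    """Fit the full boosting ensemble for each candidate K and pick the one
    with the best silhouette (stability ARI breaks ties).

    Returns ``(best_K, {K: MetricsReport})``; candidates whose ensemble
    fails entirely are reported with an empty MetricsReport and skipped.
    """
    from .ensemble import fit_ensemble  # local import: avoids cycle
    from .errors import EnsembleFailedError

    candidates = sorted(candidates)
    reports: dict[int, MetricsReport] = {}
    scored = []
    for K in candidates:
        try:
            ens = fit_ensemble(dataset, K=K, seed=seed, **ensemble_kwargs)
        except EnsembleFailedError as exc:
            logger.warning("K=%d: ensemble failed (%s)", K, exc)
            reports[K] = MetricsReport(K=K)
            continue
        reports[K] = ens.metrics
        scored.append((ens.metrics.silhouette, ens.metrics.stability_ari, -K))
    if not scored:
        raise ClusteringError("no candidate K produced a valid ensemble")
    valid = [K for K in candidates if reports[K].n_retained_models > 0]
    best = max(
        valid,
        key=lambda K: (
            np.nan_to_num(reports[K].silhouette, nan=-2.0),
            np.nan_to_num(reports[K].stability_ari, nan=-2.0),
            -K,
        ),
    )
    return best, reports
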