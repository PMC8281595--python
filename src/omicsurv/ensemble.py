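"""Boosting ensemble: many subtype models on random subsamples, aggregated.

Each member ("submodel") is fit on a random draw of ``subsample`` (default
80%) of the cohort: per-omic rank/distance normalization, autoencoder
embedding, Cox screening of latent features, Gaussian-mixture subtyping
ordered by survival, and a calibrated SVM classifier. Members that found no
survival-associated latent feature, or whose labels are not associated with
survival on their training samples (log-rank p > 0.05), are eliminated.

The retained members each score a sample with a per-subtype probability
vector; the ensemble prediction is the unweighted mean of those vectors,
matched on the survival-ordered label index (0 = worst survival). The
probability of subtype 0 is the sample's *risk score*. Optional weighting
of members by their hold-out C-index is available behind a flag.

Hold-out evaluation reports both views of the 20% samples each member never
saw: the mean of per-member metrics, and metrics of the pooled
out-of-bag predictions (each sample averaged over the members that held it
out).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classification import ClassifierState, fit_subtype_classifier, predict_subtype
from .data_model import MultiOmicsDataset, OmicsMatrix, SurvivalTable
from .embedding import (
    EncoderState,
    encode,
    encode_pca,
    fit_autoencoder,
    fit_pca_embedding,
)
from .errors import (
    ClassifierError,
    ClusteringError,
    EnsembleFailedError,
    InsufficientFeaturesError,
    MetricUnavailableError,
    NoSurvivalSignalError,
)
from .normalization import NormalizerState, fit_normalizer, transform_training
from .subtyping import (
    MetricsReport,
    SubtypeLabeling,
    SurvivalFeatureMatrix,
    cluster_subtypes,
    clustering_stability,
    order_labels_by_survival,
    select_survival_features,
    silhouette,
)
from .survival_stats import concordance_index, logrank_test

logger = logging.getLogger(__name__)

REASON_NO_FEATURES = "no survival features"
REASON_LABELS_NOT_ASSOCIATED = "labels not survival-associated"


@dataclass
class RunConfig:
    """Every tunable of the fit pipeline, serialized next to each run."""

    top_k: int = 100  # highest-variance features kept per omic
    hidden_size: int = 100  # autoencoder bottleneck width
    epochs: int = 10
    dropout: float = 0.5
    activation: str = "tanh"
    loss: str = "bce"
    embedding_backend: str = "autoencoder"  # or "pca"
    alpha: float = 0.01  # Cox p threshold for latent features
    label_alpha: float = 0.05  # log-rank threshold for member retention
    clustering_method: str = "gmm"
    gmm_n_init: int = 100
    gmm_max_iter: int = 1000
    per_omic_classifier_features: int = 50
    weight_by_cindex: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SubModel:
    """One fitted boosting member (or the record of why it is invalid)."""

    index: int
    training_ids: list[str]
    holdout_ids: list[str]
    valid: bool = False
    reason: str = ""
    normalizers: dict[str, NormalizerState] = field(default_factory=dict)
    encoders: dict[str, object] = field(default_factory=dict)
    Z: SurvivalFeatureMatrix | None = None
    labeling: SubtypeLabeling | None = None
    classifier: ClassifierState | None = None
    silhouette: float = np.nan
    train_logrank_p: float = np.nan
    holdout_probs: np.ndarray | None = None  # rows follow holdout_ids
    holdout_c_index: float = np.nan
    holdout_logrank_p: float = np.nan


@dataclass
class Ensemble:
    models: list[SubModel]
    n_requested: int
    subsample: float
    K: int
    seed: int
    config: RunConfig
    survival: SurvivalTable  # training cohort survival, for hold-out metrics
    metrics: MetricsReport = field(default_factory=MetricsReport)
    weights: np.ndarray | None = None

    @property
    def retained(self) -> list[SubModel]:
        return [m for m in self.models if m.valid]


@dataclass
class EnsemblePrediction:
    sample_ids: list[str]
    probabilities: np.ndarray  # samples x K, columns = ordered subtype index
    labels: np.ndarray
    risk_score: np.ndarray  # probability of the worst-survival subtype
    n_models_used: int = 0


def _fit_submodel(
    dataset: MultiOmicsDataset,
    index: int,
    training_ids: list[str],
    holdout_ids: list[str],
    K: int,
    config: RunConfig,
    seeds: np.ndarray,
) -> SubModel:
    sub = SubModel(index=index, training_ids=training_ids, holdout_ids=holdout_ids)
    train = dataset.subset_samples(training_ids)
    latents = []
    for i, (tag, layer) in enumerate(sorted(train.layers.items())):
        norm = fit_normalizer(layer, top_k=config.top_k)
        dfm = transform_training(norm)
        if config.embedding_backend == "autoencoder":
            enc = fit_autoencoder(
                dfm,
                omic_tag=tag,
                hidden_size=config.hidden_size,
                epochs=config.epochs,
                dropout=config.dropout,
                seed=int(seeds[i]),
                activation=config.activation,
                loss=config.loss,
            )
            latents.append(encode(enc, dfm))
        elif config.embedding_backend == "pca":
            k = min(config.hidden_size, len(training_ids) - 1, dfm.values.shape[1])
            enc = fit_pca_embedding(dfm, k=k, omic_tag=tag)
            latents.append(encode_pca(enc, dfm))
        else:
            raise ValueError(f"unknown embedding backend '{config.embedding_backend}'")
        sub.normalizers[tag] = norm
        sub.encoders[tag] = enc

    try:
        sub.Z = select_survival_features(latents, train.survival, alpha=config.alpha)
    except NoSurvivalSignalError:
        sub.reason = REASON_NO_FEATURES
        return sub

    try:
        raw = cluster_subtypes(
            sub.Z,
            K,
            method=config.clustering_method,
            seed=int(seeds[len(train.layers)]),
            n_init=config.gmm_n_init,
            max_iter=config.gmm_max_iter,
        )
        sub.labeling = order_labels_by_survival(raw, train.survival)
    except ClusteringError as exc:
        sub.reason = f"clustering failed: {exc}"
        return sub
    if len(np.unique(sub.labeling.ordered_labels)) < 2:
        sub.reason = REASON_LABELS_NOT_ASSOCIATED
        return sub
    sub.train_logrank_p = logrank_test(
        sub.labeling.ordered_labels, train.survival
    ).p_value
    if sub.train_logrank_p > config.label_alpha:
        sub.reason = REASON_LABELS_NOT_ASSOCIATED
        return sub
    sub.silhouette = silhouette(sub.Z, sub.labeling.ordered_labels)

    normalized_layers = {
        tag: OmicsMatrix(
            tag,
            norm.selected_features,
            norm.training_sample_ids,
            norm.training_rank_profiles.T,
        )
        for tag, norm in sub.normalizers.items()
    }
    try:
        sub.classifier = fit_subtype_classifier(
            normalized_layers,
            sub.labeling.ordered_labels,
            per_omic=config.per_omic_classifier_features,
            seed=int(seeds[len(train.layers) + 1]),
        )
    except ClassifierError as exc:
        sub.reason = f"classifier failed: {exc}"
        return sub
    sub.valid = True

    if holdout_ids:
        holdout = dataset.subset_samples(holdout_ids)
        probs, labels = predict_subtype(sub.classifier, holdout.layers)
        sub.holdout_probs = probs
        risk = probs[:, 0]
        try:
            sub.holdout_c_index = concordance_index(risk, holdout.survival)
        except MetricUnavailableError:
            pass
        if len(np.unique(labels)) >= 2 and holdout.survival.n_events > 0:
            sub.holdout_logrank_p = logrank_test(labels, holdout.survival).p_value
    return sub


def filter_models(models: list[SubModel]) -> list[SubModel]:
    """The retention rule: a member survives iff it found >= 1 survival-
    associated latent feature and its labels are survival-associated."""
    return [m for m in models if m.valid]


def fit_ensemble(
    dataset: MultiOmicsDataset,
    n_models: int = 10,
    subsample: float = 0.8,
    K: int = 2,
    seed: int = 0,
    config: RunConfig | None = None,
) -> Ensemble:
    """Fit ``n_models`` members on independent seeded subsamples and retain
    the valid ones; raises :class:`EnsembleFailedError` if none survive."""
    if not 0 < subsample <= 1:
        raise ValueError("subsample must be in (0, 1]")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    config = config or RunConfig()
    n = dataset.n_samples
    n_train = max(2, int(round(subsample * n)))
    rng = np.random.default_rng(seed)
    sample_ids = np.asarray(dataset.sample_ids)

    models = []
    for i in range(n_models):
        if n_train >= n:
            train_idx = np.arange(n)
        else:
            train_idx = np.sort(rng.choice(n, size=n_train, replace=False))
        hold_idx = np.setdiff1d(np.arange(n), train_idx)
        seeds = rng.integers(0, 2**31 - 1, size=len(dataset.layers) + 2)
        sub = _fit_submodel(
            dataset,
            i,
            sample_ids[train_idx].tolist(),
            sample_ids[hold_idx].tolist(),
            K,
            config,
            seeds,
        )
        logger.info(
            "model %d: %s", i, "retained" if sub.valid else f"dropped ({sub.reason})"
        )
        models.append(sub)

    retained = filter_models(models)
    if not retained:
        raise EnsembleFailedError([f"model {m.index}: {m.reason}" for m in models])

    ensemble = Ensemble(
        models=models,
        n_requested=n_models,
        subsample=subsample,
        K=K,
        seed=seed,
        config=config,
        survival=dataset.survival,
    )
    if config.weight_by_cindex:
        w = np.array([np.nan_to_num(m.holdout_c_index, nan=0.5) for m in retained])
        ensemble.weights = w / w.sum()
    ensemble.metrics = evaluate_holdout(ensemble, dataset)
    return ensemble


def _model_weights(ensemble: Ensemble) -> np.ndarray:
    retained = ensemble.retained
    if ensemble.weights is not None:
        return ensemble.weights
    return np.full(len(retained), 1.0 / len(retained))


def predict_ensemble(
    ensemble: Ensemble,
    layers: dict[str, OmicsMatrix] | MultiOmicsDataset,
    available_omics=None,
) -> EnsemblePrediction:
    """Aggregate member probabilities (matched on the survival-ordered label
    index) into per-sample probabilities, a final label and a risk score.

    Members unable to score the samples (insufficient shared features) are
    skipped with a warning; at least one must apply.
    """
    if isinstance(layers, MultiOmicsDataset):
        layers = layers.layers
    retained = ensemble.retained
    weights = _model_weights(ensemble)
    acc = None
    used_w = 0.0
    n_used = 0
    sample_ids = None
    for m, w in zip(retained, weights):
        try:
            probs, _ = predict_subtype(m.classifier, layers, available_omics)
        except (ClassifierError, InsufficientFeaturesError) as exc:
            logger.warning("model %d cannot predict these samples: %s", m.index, exc)
            continue
        if sample_ids is None:
            first = next(iter(layers.values()))
            sample_ids = list(first.sample_ids)
        acc = probs * w if acc is None else acc + probs * w
        used_w += w
        n_used += 1
    if acc is None:
        raise EnsembleFailedError(["no retained model applicable to these samples"])
    probabilities = acc / used_w
    risk = probabilities[:, 0]
    if ensemble.K == 2:
        labels = (risk <= 0.5).astype(int)  # label 0 (worst) iff its probability > 1/2
    else:
        labels = np.argmax(probabilities, axis=1)
    return EnsemblePrediction(
        sample_ids=sample_ids,
        probabilities=probabilities,
        labels=labels,
        risk_score=risk,
        n_models_used=n_used,
    )


def oob_predictions(ensemble: Ensemble) -> tuple[list[str], np.ndarray]:
    """Pooled out-of-bag predictions: each sample's probability vector
    averaged over the retained members that held it out. Returns the
    covered sample ids and their probabilities (empty when no member had a
    hold-out split)."""
    surv = ensemble.survival
    pos = {s: i for i, s in enumerate(surv.sample_ids)}
    acc = np.zeros((len(surv), ensemble.K))
    counts = np.zeros(len(surv))
    for m in ensemble.retained:
        if m.holdout_probs is None:
            continue
        idx = [pos[s] for s in m.holdout_ids]
        acc[idx] += m.holdout_probs
        counts[idx] += 1
    covered = counts > 0
    ids = [s for s, c in zip(surv.sample_ids, covered) if c]
    if not ids:
        return [], np.zeros((0, ensemble.K))
    return ids, acc[covered] / counts[covered, None]


def evaluate_holdout(
    ensemble: Ensemble, dataset: MultiOmicsDataset | None = None
) -> MetricsReport:
    """Hold-out quality of the ensemble.

    Emits both the mean of per-member hold-out metrics and the pooled
    out-of-bag view: each sample's probabilities averaged over the members
    that held it out, scored once against the cohort survival. Label
    stability (mean pairwise ARI of full-cohort member labelings) is
    included when the member count and a dataset allow it.
    """
    retained = ensemble.retained
    surv = ensemble.survival
    report = MetricsReport(K=ensemble.K, n_retained_models=len(retained))
    report.silhouette = float(np.nanmean([m.silhouette for m in retained]))
    per_c = [m.holdout_c_index for m in retained if np.isfinite(m.holdout_c_index)]
    per_p = [m.holdout_logrank_p for m in retained if np.isfinite(m.holdout_logrank_p)]
    report.extra["mean_model_c_index"] = float(np.mean(per_c)) if per_c else np.nan
    report.extra["mean_model_logrank_p"] = float(np.mean(per_p)) if per_p else np.nan

    oob_ids, probs = oob_predictions(ensemble)
    if oob_ids:
        risk = probs[:, 0]
        sub_surv = surv.subset(oob_ids)
        try:
            report.c_index = concordance_index(risk, sub_surv)
        except MetricUnavailableError:
            pass
        if ensemble.K == 2:
            pooled_labels = (risk <= 0.5).astype(int)
        else:
            pooled_labels = np.argmax(probs, axis=1)
        if len(np.unique(pooled_labels)) >= 2 and sub_surv.n_events > 0:
            report.logrank_p = logrank_test(pooled_labels, sub_surv).p_value
        report.extra["n_oob_samples"] = len(oob_ids)

    if dataset is not None and len(retained) >= 2:
        labelings = []
        for m in retained:
            try:
                _, labels = predict_subtype(m.classifier, dataset.layers)
                labelings.append(labels)
            except (ClassifierError, InsufficientFeaturesError):
                continue
        if len(labelings) >= 2:
            report.stability_ari = clustering_stability(labelings)
    return report


def cross_cohort_predict(
    ensemble: Ensemble, other: MultiOmicsDataset, available_omics=None
) -> tuple[EnsemblePrediction, MetricsReport]:
    """Transfer the fitted ensemble to an external cohort sharing (part of)
    the feature universe, and score the predicted labels and risk against
    the external cohort's own survival."""
    prediction = predict_ensemble(ensemble, other, available_omics)
    report = MetricsReport(K=ensemble.K, n_retained_models=len(ensemble.retained))
    report.extra["n_predicted_samples"] = len(prediction.sample_ids)
    try:
        report.c_index = concordance_index(prediction.risk_score, other.survival)
    except MetricUnavailableError:
        pass
    if len(np.unique(prediction.labels)) >= 2 and other.survival.n_events > 0:
        report.logrank_p = logrank_test(prediction.labels, other.survival).p_value
    return prediction, report
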