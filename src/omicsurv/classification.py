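"""Supervised subtype classification over normalized omics features.

Once a boosting member has labeled its training samples, the labeling is
turned into a classifier that can score *new* samples, including samples
measured on only some of the omics or a subset of features:

1. per omic, a Kruskal-Wallis test ranks every feature (of the normalizer's
   top-variance set) by how well it discriminates the subtypes; the
   ``per_omic`` best (default 50) are kept and concatenated into the
   training matrix M (each sample's entries are its within-omic ranks over
   the kept set, scaled to (0, 1]);
2. a support-vector classifier is chosen by 5-fold cross-validated grid
   search over kernel/regularization, with Platt-calibrated probabilities;
3. a new sample sharing only a subset of omics or features triggers a
   reduced classifier re-fit on the training data restricted to the shared
   columns (cached per subset signature), mirroring how the full model was
   built rather than imputing the missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kruskal, rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .data_model import OmicsMatrix
from .errors import ClassifierError

logger = logging.getLogger(__name__)

DEFAULT_PER_OMIC = 50
SVC_C_GRID = (0.1, 1.0, 10.0, 100.0)
SVC_GAMMA_FACTORS = (0.1, 1.0, 10.0)


@dataclass
class ClassifierState:
    """Fitted subtype classifier plus everything needed to re-fit reduced
    versions for partially observed new samples."""

    selected: dict[str, list[tuple[str, float]]]  # omic -> [(feature_id, kw_p)]
    training_values: dict[str, np.ndarray]  # omic -> |selected| x n normalized values
    training_labels: np.ndarray
    classes: np.ndarray
    model: object  # calibrated SVM
    best_params: dict
    grid_record: list[dict] = field(default_factory=list)
    seed: int = 0
    _reduced_cache: dict = field(default_factory=dict, repr=False)

    @property
    def omic_tags(self) -> list[str]:
        return list(self.selected.keys())


def _rank_block(values: np.ndarray) -> np.ndarray:
    """Per-sample ranks over one omic's kept features: (features x samples)
    -> (samples x features) with entries rank/k in (0, 1]."""
    k = values.shape[0]
    return rankdata(values.T, axis=1) / k


def select_discriminative_features(
    layers: dict[str, OmicsMatrix],
    labels: np.ndarray,
    per_omic: int = DEFAULT_PER_OMIC,
) -> dict[str, list[tuple[str, float]]]:
    """Per omic, the ``per_omic`` features with smallest Kruskal-Wallis
    p-value against the subtype labels (ties broken by feature id)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ClassifierError("feature selection needs >= 2 classes")
    if counts.min() < 2:
        raise ClassifierError("every class needs >= 2 samples")
    out: dict[str, list[tuple[str, float]]] = {}
    for tag, matrix in layers.items():
        pvals = []
        for i, fid in enumerate(matrix.feature_ids):
            row = matrix.values[i]
            groups = [row[labels == c] for c in classes]
            if all(np.ptp(g) == 0 for g in groups) and np.ptp(row) == 0:
                p = 1.0  # constant feature carries no signal
            else:
                p = float(kruskal(*groups).pvalue)
            pvals.append((p, fid))
        pvals.sort(key=lambda t: (t[0], t[1]))
        out[tag] = [(fid, p) for p, fid in pvals[: min(per_omic, len(pvals))]]
    return out


def _grid(M: np.ndarray) -> list[dict]:
    scale = 1.0 / (M.shape[1] * M.var()) if M.var() > 0 else 1.0
    return [
        {"kernel": ["linear"], "C": list(SVC_C_GRID)},
        {
            "kernel": ["rbf"],
            "C": list(SVC_C_GRID),
            "gamma": [scale * f for f in SVC_GAMMA_FACTORS],
        },
    ]


def _fit_svc(M: np.ndarray, labels: np.ndarray, seed: int):
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    counts = counts[counts > 0]
    if len(counts) < 2:
        raise ClassifierError("cannot train a classifier on a single class")
    n_splits = min(5, int(counts.min()))
    if n_splits < 5:
        logger.warning("reducing CV folds to %d (smallest class)", n_splits)
    if n_splits < 2:
        raise ClassifierError("smallest class has < 2 samples; cannot cross-validate")
    search = GridSearchCV(
        SVC(),
        param_grid=_grid(M),
        scoring="accuracy",
        cv=StratifiedKFold(n_splits=n_splits),
        refit=False,
    )
    search.fit(M, labels)
    best = search.cv_results_["params"][int(np.argmax(search.cv_results_["mean_test_score"]))]
    record = [
        {"params": p, "mean_cv_accuracy": float(s)}
        for p, s in zip(search.cv_results_["params"], search.cv_results_["mean_test_score"])
    ]
    # Platt calibration: per-class sigmoid fitted on cross-validated SVM
    # decision scores, renormalized across classes
    model = CalibratedClassifierCV(
        SVC(**best),
        method="sigmoid",
        cv=StratifiedKFold(n_splits=n_splits),
        ensemble=False,
    )
    model.fit(M, labels)
    return model, best, record


def fit_subtype_classifier(
    layers: dict[str, OmicsMatrix],
    labels: np.ndarray,
    per_omic: int = DEFAULT_PER_OMIC,
    seed: int = 0,
) -> ClassifierState:
    """Select discriminative features and train the calibrated SVM.

    ``layers`` holds each omic's *normalized* top-variance feature block
    (features x samples) on the training samples, label-aligned.
    """
    labels = np.asarray(labels)
    selected = select_discriminative_features(layers, labels, per_omic=per_omic)
    training_values: dict[str, np.ndarray] = {}
    blocks = []
    for tag, feats in selected.items():
        matrix = layers[tag]
        pos = {f: i for i, f in enumerate(matrix.feature_ids)}
        idx = [pos[fid] for fid, _ in feats]
        vals = matrix.values[idx, :]
        training_values[tag] = vals
        blocks.append(_rank_block(vals))
    M = np.hstack(blocks)
    model, best, record = _fit_svc(M, labels, seed)
    return ClassifierState(
        selected=selected,
        training_values=training_values,
        training_labels=labels,
        classes=model.classes_,
        model=model,
        best_params=best,
        grid_record=record,
        seed=seed,
    )


def _resolve_subset(
    state: ClassifierState,
    new_layers: dict[str, OmicsMatrix],
    available_omics=None,
    min_common: int = 2,
):
    """Which omics/features of the training model the new samples support."""
    tags = [t for t in state.omic_tags if t in new_layers]
    if available_omics is not None:
        tags = [t for t in tags if t in set(available_omics)]
    subset = []
    for tag in tags:
        new_feats = set(new_layers[tag].feature_ids)
        kept = [
            (i, fid)
            for i, (fid, _) in enumerate(state.selected[tag])
            if fid in new_feats
        ]
        if len(kept) >= min_common:
            subset.append((tag, tuple(kept)))
    if not subset:
        raise ClassifierError(
            "new samples share no usable omic/feature subset with the model"
        )
    return subset


def _classifier_for_subset(state: ClassifierState, subset):
    signature = tuple((tag, tuple(fid for _, fid in kept)) for tag, kept in subset)
    full_signature = tuple(
        (tag, tuple(fid for fid, _ in state.selected[tag])) for tag in state.omic_tags
    )
    if signature == full_signature:
        return state.model, state.classes
    if signature in state._reduced_cache:
        return state._reduced_cache[signature]
    blocks = [
        _rank_block(state.training_values[tag][[i for i, _ in kept], :])
        for tag, kept in subset
    ]
    M = np.hstack(blocks)
    model, _, _ = _fit_svc(M, state.training_labels, state.seed)
    state._reduced_cache[signature] = (model, model.classes_)
    logger.info("fitted reduced classifier for subset %s", [t for t, _ in subset])
    return model, model.classes_


def predict_subtype(
    state: ClassifierState,
    new_layers: dict[str, OmicsMatrix],
    available_omics=None,
    min_common: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability per subtype and argmax label for each new sample.

    Returns ``(probabilities, labels)`` with probability columns ordered by
    the survival-ordered class index (0 = worst survival first).
    """
    subset = _resolve_subset(state, new_layers, available_omics, min_common)
    model, classes = _classifier_for_subset(state, subset)
    sample_ids = None
    blocks = []
    for tag, kept in subset:
        matrix = new_layers[tag]
        if sample_ids is None:
            sample_ids = list(matrix.sample_ids)
        elif list(matrix.sample_ids) != sample_ids:
            raise ClassifierError("new omic layers must share sample order")
        pos = {f: i for i, f in enumerate(matrix.feature_ids)}
        idx = [pos[fid] for _, fid in kept]
        blocks.append(_rank_block(matrix.values[idx, :]))
    M = np.hstack(blocks)
    raw = model.predict_proba(M)
    # align probability columns to the ordered subtype index 0..K-1
    n_classes = len(state.classes)
    probs = np.zeros((M.shape[0], n_classes))
    col_of = {c: j for j, c in enumerate(state.classes)}
    for j, c in enumerate(classes):
        probs[:, col_of[c]] = raw[:, j]
    labels = state.classes[np.argmax(probs, axis=1)]
    return probs, labels
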