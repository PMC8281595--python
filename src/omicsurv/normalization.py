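"""Two-stage rank / correlation-distance normalization of one omic layer.

Cross-platform comparability is achieved not by scaling raw values but by
re-describing every sample through its distances to the *training* samples:

1. keep the ``top_k`` (default 100) highest-variance training features;
2. within each sample, replace feature values by their within-sample rank
   divided by ``top_k`` (highest value -> 1.0);
3. compute the sample-sample Pearson correlation matrix over these rank
   profiles and turn it into distances ``d = 1 - r``;
4. rank-normalize each sample's distance vector so its nearest training
   sample scores 1.0 and its farthest scores 0.

A new sample measured on any platform — and on only a subset of features —
goes through the same four steps restricted to the features it shares with
the training set, producing a vector directly comparable to training rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data_model import OmicsMatrix
from .errors import InsufficientFeaturesError, NormalizationError

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 100


@dataclass
class NormalizerState:
    """Frozen training-side state of the rank/distance normalizer."""

    omic_tag: str
    selected_features: list[str]
    training_values: np.ndarray  # |selected| x n raw values, for re-ranking on subsets
    training_rank_profiles: np.ndarray  # n x |selected|, values in (0, 1]
    training_sample_ids: list[str]

    @property
    def n_training(self) -> int:
        return len(self.training_sample_ids)


@dataclass
class DistanceFeatureMatrix:
    """Samples described by rank-normalized distances to the training samples."""

    sample_ids: list[str]
    reference_ids: list[str]  # the training samples, one output column each
    values: np.ndarray  # samples x n_training, in [0, 1]


def _inverse_rank_profile(values: np.ndarray) -> np.ndarray:
    """Within-sample scores: rank ascending (average ties) / number of features,
    so the largest value maps to 1.0 and the smallest to 1/k."""
    k = values.shape[-1]
    return rankdata(values, axis=-1) / k


def _rank_unit_scores(distances: np.ndarray) -> np.ndarray:
    """Map a distance vector to [0, 1]: smallest distance -> 1.0, largest -> 0.

    Ties get average ranks before the linear rescale, so tied-nearest samples
    share the top score. A spread-free vector (all distances equal) maps to
    a flat 0.5 with a warning — there is no ordering information to encode.
    """
    ranks = rankdata(distances)
    span = ranks.max() - ranks.min()
    if span == 0:
        logger.warning("all distances tied; emitting flat 0.5 scores")
        return np.full_like(ranks, 0.5, dtype=float)
    return (ranks.max() - ranks) / span


def _profile_correlations(profiles_a: np.ndarray, profiles_b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``profiles_a`` with every row of
    ``profiles_b``; raises if any row has zero variance (correlation undefined)."""
    a = profiles_a - profiles_a.mean(axis=1, keepdims=True)
    b = profiles_b - profiles_b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    if (sa == 0).any() or (sb == 0).any():
        raise NormalizationError("zero-variance rank profile; correlation undefined")
    return (a @ b.T) / np.outer(sa, sb)


def fit_normalizer(
    matrix: OmicsMatrix, top_k: int = DEFAULT_TOP_K
) -> NormalizerState:
    """Select the ``top_k`` highest-variance features and store per-sample
    inverse-rank profiles over them.

    Variance ties are broken by feature id so the selection is reproducible.
    Raises :class:`NormalizationError` on single-sample input (variance
    undefined).
    """
    if matrix.n_samples < 2:
        raise NormalizationError(
            f"{matrix.omic_tag}: need >= 2 samples to fit a normalizer"
        )
    variances = matrix.values.var(axis=1, ddof=0)
    order = sorted(
        range(matrix.n_features), key=lambda i: (-variances[i], matrix.feature_ids[i])
    )
    keep = order[: min(top_k, matrix.n_features)]
    selected = [matrix.feature_ids[i] for i in keep]
    training_values = matrix.values[keep, :]
    profiles = _inverse_rank_profile(training_values.T)
    return NormalizerState(
        omic_tag=matrix.omic_tag,
        selected_features=selected,
        training_values=training_values,
        training_rank_profiles=profiles,
        training_sample_ids=list(matrix.sample_ids),
    )


def transform_training(state: NormalizerState) -> DistanceFeatureMatrix:
    """Distance features of the training samples themselves (n x n).

    A sample's zero distance to itself is kept and therefore takes the top
    score 1.0 (shared with any exact duplicates through average-rank ties).
    """
    corr = _profile_correlations(
        state.training_rank_profiles, state.training_rank_profiles
    )
    dist = 1.0 - corr
    values = np.vstack([_rank_unit_scores(row) for row in dist])
    return DistanceFeatureMatrix(
        sample_ids=list(state.training_sample_ids),
        reference_ids=list(state.training_sample_ids),
        values=values,
    )


def transform_new(
    state: NormalizerState,
    new_matrix: OmicsMatrix,
    min_common_features: int = 2,
) -> DistanceFeatureMatrix:
    """Distance features of new samples against the training cohort.

    Both the new samples and the stored training values are re-ranked on the
    common feature set, so a sample measured on a strict subset of the
    training features still yields a comparable n-vector.
    """
    pos = {f: i for i, f in enumerate(new_matrix.feature_ids)}
    common = [f for f in state.selected_features if f in pos]
    if len(common) < min_common_features:
        raise InsufficientFeaturesError(
            f"{state.omic_tag}: only {len(common)} of {len(state.selected_features)} "
            f"training features present (need >= {min_common_features})"
        )
    sel_idx = [state.selected_features.index(f) for f in common]
    train_profiles = _inverse_rank_profile(state.training_values[sel_idx, :].T)
    new_idx = [pos[f] for f in common]
    new_profiles = _inverse_rank_profile(new_matrix.values[new_idx, :].T)
    corr = _profile_correlations(new_profiles, train_profiles)
    dist = 1.0 - corr
    values = np.vstack([_rank_unit_scores(row) for row in dist])
    return DistanceFeatureMatrix(
        sample_ids=list(new_matrix.sample_ids),
        reference_ids=list(state.training_sample_ids),
        values=values,
    )
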