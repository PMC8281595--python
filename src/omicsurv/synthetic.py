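"""Synthetic multi-omic cohorts with known subtypes and survival signal.

The generator emulates the structure the pipeline is built to find: K
latent subtypes, per-omic blocks of informative features whose means shift
by ``effect_size`` standard deviations per subtype step, nuisance features
of pure noise, and survival times whose hazard scales multiplicatively with
the subtype (hazard ratio per step). Censoring is independent exponential,
calibrated to a target overall censoring rate. Everything is a pure
function of the spec and its seed, so ground truth is exact and every
pipeline stage can be tested without external data.

A methylation-like layer can be requested by setting ``squash`` on an omic
spec: values are pushed through a logistic map onto (0, 1), exercising the
per-omic rank normalization with beta-value-style data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .data_model import MultiOmicsDataset, OmicsMatrix, SurvivalTable


@dataclass
class OmicSpec:
    """Shape of one simulated omic layer."""

    n_features: int
    n_informative: int
    effect_size: float = 1.0  # mean shift per subtype step, in SD units
    squash: bool = False  # logistic map onto (0, 1), beta-value style

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")


def default_omics() -> dict[str, OmicSpec]:
    """Three layers mirroring a typical RNA + miRNA + methylation design."""
    return {
        "RNA": OmicSpec(n_features=500, n_informative=50, effect_size=1.0),
        "MIR": OmicSpec(n_features=200, n_informative=20, effect_size=1.0),
        "METH": OmicSpec(n_features=300, n_informative=30, effect_size=1.0, squash=True),
    }


@dataclass
class SyntheticCohortSpec:
    n_samples: int = 200
    n_subtypes: int = 2
    omics: dict[str, OmicSpec] = field(default_factory=default_omics)
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    hazard_ratio: float = 3.0  # per subtype step
    censoring_rate: float = 0.2  # target fraction censored
    weibull_shape: float = 1.0  # 1.0 = exponential survival
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio < 1:
            raise ValueError("hazard_ratio must be >= 1")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class SyntheticCohort:
    dataset: MultiOmicsDataset
    subtypes: np.ndarray  # ground-truth subtype per sample (dataset order)
    informative_features: dict[str, list[str]]
    spec: SyntheticCohortSpec


def _censoring_rate_for(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_k c / (r_k + c) = target."""
    if target == 0:
        return 0.0

    def gap(c):
        return float(np.mean(c / (rates + c))) - target

    hi = 1.0
    while gap(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            raise ValueError("infeasible censoring target")
    return brentq(gap, 1e-300, hi)


def _feature_ids(tag: str, n: int, suffix: str = "") -> list[str]:
    return [f"{tag}_F{i:04d}{suffix}" for i in range(n)]


def generate_cohort(
    spec: SyntheticCohortSpec,
    rng: np.random.Generator | None = None,
    feature_ids: dict[str, list[str]] | None = None,
) -> SyntheticCohort:
    """Draw one cohort from the spec (deterministic given spec.seed)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, K = spec.n_samples, spec.n_subtypes
    sample_ids = [f"S{i:05d}" for i in range(n)]
    subtype = rng.integers(0, K, size=n)

    layers: dict[str, OmicsMatrix] = {}
    informative: dict[str, list[str]] = {}
    for tag, ospec in spec.omics.items():
        fids = (
            feature_ids[tag]
            if feature_ids is not None
            else _feature_ids(tag, ospec.n_features)
        )
        values = rng.standard_normal((ospec.n_features, n))
        shift = ospec.effect_size * subtype  # informative rows only
        values[: ospec.n_informative, :] += shift[None, :]
        if ospec.squash:
            values = 1.0 / (1.0 + np.exp(-values))
        layers[tag] = OmicsMatrix(tag, fids, sample_ids, values)
        informative[tag] = fids[: ospec.n_informative]

    rates = spec.baseline_hazard * spec.hazard_ratio**subtype
    if spec.weibull_shape == 1.0:
        event_time = rng.exponential(1.0 / rates)
    else:
        event_time = rng.weibull(spec.weibull_shape, size=n) / rates
    c_rate = _censoring_rate_for(
        spec.baseline_hazard * spec.hazard_ratio ** np.arange(K), spec.censoring_rate
    )
    if c_rate > 0:
        censor_time = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    survival = SurvivalTable(sample_ids, np.maximum(observed, 1e-9), event)

    dataset = MultiOmicsDataset(layers, survival)
    return SyntheticCohort(dataset, subtype, informative, spec)


def generate_paired_cohorts(
    spec: SyntheticCohortSpec, shared_feature_fraction: float = 1.0
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Two independent cohorts from the same generative process that share
    a fixed fraction of feature identifiers per omic (the shared block comes
    first, so informative features are shared whenever the fraction allows).
    Used to exercise cross-cohort (transfer) prediction."""
    if not 0 < shared_feature_fraction <= 1:
        raise ValueError("shared_feature_fraction must be in (0, 1]")
    rng = np.random.default_rng(spec.seed)
    ids_a, ids_b = {}, {}
    for tag, ospec in spec.omics.items():
        n_shared = int(np.floor(shared_feature_fraction * ospec.n_features))
        shared = _feature_ids(tag, ospec.n_features)[:n_shared]
        n_private = ospec.n_features - n_shared
        ids_a[tag] = shared + _feature_ids(tag, n_private, suffix="a")
        ids_b[tag] = shared + _feature_ids(tag, n_private, suffix="b")
    cohort_a = generate_cohort(spec, rng=rng, feature_ids=ids_a)
    cohort_b = generate_cohort(spec, rng=rng, feature_ids=ids_b)
    return cohort_a, cohort_b


def null_spec(n_samples: int = 200, seed: int = 0, **kwargs) -> SyntheticCohortSpec:
    """A cohort with no survival or subtype signal: HR = 1, no informative
    features. Convenience for negative-control experiments."""
    omics = {
        tag: replace(o, n_informative=0, effect_size=0.0)
        for tag, o in default_omics().items()
    }
    return SyntheticCohortSpec(
        n_samples=n_samples, hazard_ratio=1.0, omics=omics, seed=seed, **kwargs
    )


def write_cohort_tsv(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write the standard TSV files (one matrix per omic, survival table,
    ground-truth subtypes); returns the paths written."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for tag, matrix in cohort.dataset.layers.items():
        p = os.path.join(out_dir, f"{tag}.tsv")
        matrix.to_tsv(p)
        paths[tag] = p
    p = os.path.join(out_dir, "survival.tsv")
    cohort.dataset.survival.to_tsv(p)
    paths["survival"] = p
    p = os.path.join(out_dir, "ground_truth.tsv")
    with open(p, "w") as fh:
        fh.write("sample\tsubtype\n")
        for s, k in zip(cohort.dataset.sample_ids, cohort.subtypes):
            fh.write(f"{s}\t{k}\n")
    paths["ground_truth"] = p
    return paths
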