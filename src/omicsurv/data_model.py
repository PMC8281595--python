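"""Core data containers, TSV I/O, sample alignment and model serialization.

The package works on three kinds of objects:

* :class:`OmicsMatrix` — one omic layer (mRNA, miRNA, methylation, ...) as a
  real-valued feature-by-sample matrix,
* :class:`SurvivalTable` — per-sample follow-up time (days) and event
  indicator (1 = death observed, 0 = censored),
* :class:`MultiOmicsDataset` — a set of layers sharing one sample universe
  plus the survival table; the unit every pipeline stage consumes.

Matrices are stored features x samples (the on-disk TSV orientation);
samples are kept in a canonical sorted order after alignment so repeated
runs see identical inputs.
"""

from __future__ import annotations

import gzip
import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    MatrixLoadError,
    SerializationError,
    SurvivalLoadError,
)

logger = logging.getLogger(__name__)

ARCHIVE_SCHEMA_VERSION = 1

_TRUTHY = {"1", "true", "t", "yes", "dead", "deceased"}
_FALSY = {"0", "false", "f", "no", "alive", "censored"}


@dataclass
class OmicsMatrix:
    """One omic layer: features x samples with identifiers and an omic tag."""

    omic_tag: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # features x samples, float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise MatrixLoadError(f"{self.omic_tag}: matrix must be 2-D")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise MatrixLoadError(
                f"{self.omic_tag}: shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise MatrixLoadError(f"{self.omic_tag}: duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise MatrixLoadError(f"{self.omic_tag}: duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise MatrixLoadError(f"{self.omic_tag}: non-finite values present")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        """Restrict (and reorder) to the given samples."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"{self.omic_tag}: unknown samples {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return OmicsMatrix(
            self.omic_tag, list(self.feature_ids), list(sample_ids), self.values[:, idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="feature")


@dataclass
class SurvivalTable:
    """Per-sample observation time (days, > 0) and event indicator (0/1)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SurvivalLoadError("duplicate sample ids in survival table")
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise SurvivalLoadError("survival columns have unequal lengths")
        bad = [s for s, t in zip(self.sample_ids, self.time) if not t > 0]
        if bad:
            raise SurvivalLoadError(f"non-positive observation time for samples {bad}")
        if not np.isin(self.event, (0, 1)).all():
            raise SurvivalLoadError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, sample_ids: list[str]) -> "SurvivalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return SurvivalTable(list(sample_ids), self.time[idx], self.event[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.sample_ids, "days": self.time, "event": self.event}
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class MultiOmicsDataset:
    """Aligned omic layers plus survival, all on an identical sample order."""

    layers: dict[str, OmicsMatrix]
    survival: SurvivalTable
    dropped_samples: dict[str, list[str]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.survival.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.survival)

    def subset_samples(self, sample_ids: list[str]) -> "MultiOmicsDataset":
        return MultiOmicsDataset(
            {tag: m.subset_samples(sample_ids) for tag, m in self.layers.items()},
            self.survival.subset(sample_ids),
        )


def load_omics_matrix(path, omic_tag: str, impute_missing: bool = False) -> OmicsMatrix:
    """Read a feature-by-sample TSV (first row sample ids, first column feature ids).

    Duplicate feature rows keep the first occurrence (a warning is logged).
    Missing / non-numeric cells are rejected with the offending cell named,
    unless ``impute_missing`` is set, in which case missing entries are
    replaced by the per-feature median.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = sorted({s for s in header if header.count(s) > 1})
    if dup:
        raise MatrixLoadError(f"{path}: duplicate sample ids {dup}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        logger.warning(
            "%s: duplicate feature ids %s — keeping first occurrence", path, dup
        )
        raw = raw[~raw.index.duplicated(keep="first")]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        if impute_missing:
            med = np.nanmedian(np.where(bad, np.nan, values), axis=1)
            rows, cols = np.nonzero(bad)
            values[rows, cols] = med[rows]
            if not np.all(np.isfinite(values)):
                raise MatrixLoadError(f"{path}: features with no finite value")
        else:
            r, c = np.argwhere(bad)[0]
            raise MatrixLoadError(
                f"{path}: non-numeric or missing value at feature "
                f"'{raw.index[r]}', sample '{raw.columns[c]}'"
            )
    return OmicsMatrix(omic_tag, raw.index.tolist(), raw.columns.tolist(), values)


def load_survival(
    path,
    sample_col: str = "sample",
    time_col: str = "days",
    event_col: str = "event",
) -> SurvivalTable:
    """Read a survival TSV; the event column accepts 0/1 or TRUE/FALSE spellings."""
    df = pd.read_csv(path, sep="\t")
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise SurvivalLoadError(f"{path}: missing column '{col}'")

    def coerce_event(x) -> int:
        s = str(x).strip().lower()
        if s in _TRUTHY:
            return 1
        if s in _FALSY:
            return 0
        raise SurvivalLoadError(f"{path}: unrecognized event value '{x}'")

    events = np.array([coerce_event(x) for x in df[event_col]])
    times = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=float)
    if np.isnan(times).any():
        bad = df[sample_col][np.isnan(times)].tolist()
        raise SurvivalLoadError(f"{path}: non-numeric times for samples {bad}")
    return SurvivalTable(df[sample_col].astype(str).tolist(), times, events)


def align_dataset(
    layers: list[OmicsMatrix] | dict[str, OmicsMatrix], survival: SurvivalTable
) -> MultiOmicsDataset:
    """Restrict all layers and the survival table to their common samples.

    The common samples are placed in sorted order everywhere, which makes
    downstream fits independent of the input file ordering. Samples dropped
    from each layer are recorded on the returned dataset. Raises
    :class:`AlignmentError` when the intersection is empty.
    """
    if isinstance(layers, dict):
        layers = list(layers.values())
    if not layers:
        raise AlignmentError("at least one omic layer is required")
    common = set(survival.sample_ids)
    for m in layers:
        common &= set(m.sample_ids)
    if not common:
        raise AlignmentError("no samples shared by all layers and survival")
    order = sorted(common)
    dropped = {m.omic_tag: sorted(set(m.sample_ids) - common) for m in layers}
    dropped["survival"] = sorted(set(survival.sample_ids) - common)
    for tag, lost in dropped.items():
        if lost:
            logger.info("alignment dropped %d samples from %s", len(lost), tag)
    return MultiOmicsDataset(
        {m.omic_tag: m.subset_samples(order) for m in layers},
        survival.subset(order),
        dropped_samples=dropped,
    )


def save_ensemble(ensemble, path) -> None:
    """Serialize a fitted ensemble to a gzip archive with a schema version."""
    payload = {"schema_version": ARCHIVE_SCHEMA_VERSION, "ensemble": ensemble}
    with gzip.open(path, "wb") as fh:
        pickle.dump(payload, fh, protocol=pickle.HIGHEST_PROTOCOL)


def load_ensemble(path):
    """Load an ensemble archive; truncated files and version mismatches raise
    :class:`SerializationError` rather than propagating raw decoder errors."""
    try:
        with gzip.open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (OSError, EOFError, pickle.UnpicklingError, AttributeError) as exc:
        raise SerializationError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise SerializationError(f"{path}: not an omicsurv model archive")
    version = payload["schema_version"]
    if version != ARCHIVE_SCHEMA_VERSION:
        raise SerializationError(
            f"{path}: archive schema version {version} != supported "
            f"{ARCHIVE_SCHEMA_VERSION}"
        )
    return payload["ensemble"]
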