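"""Core data containers, the radiomics feature-name grammar, and file I/O.

Feature tables are plain numeric matrices (samples x features) carried
together with per-sample metadata: the acquisition environment (the
contributing center) and a binary outcome label (IDH1/2 mutant vs
wild-type).  Feature names follow the radiomics convention

    <image_filter>_<feature_class>_<feature_name>_<sequence>_<region>

where the filter token may contain dots (``wavelet.HL``,
``log.sigma.2.mm.3D``) but never underscores, the sequence is one of the
four structural MRI series and the region suffix L1/L2/L3 encodes the
segmentation label (enhancing tumor, nonenhancing tumor/necrosis, edema).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_REGIONS = ("L1", "L2", "L3")
VALID_SEQUENCES = ("T1", "cT1", "T2", "FLAIR")
FEATURE_CLASSES = ("shape", "firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")


class FeatureNameError(ValueError):
    """Raised when a feature name does not follow the naming grammar."""


@dataclass(frozen=True)
class ParsedFeatureName:
    """The five components of a radiomics feature name."""

    image_filter: str
    feature_class: str
    feature_name: str
    sequence: str
    region: str

    def unparse(self) -> str:
        return "_".join(
            (self.image_filter, self.feature_class, self.feature_name,
             self.sequence, self.region)
        )


def parse_feature_name(name: str) -> ParsedFeatureName:
    """Split a feature name into filter, class, name, sequence and region.

    Only the first field may contain dots; splitting on ``_`` must yield
    exactly five fields.  The region and sequence tokens are validated
    against their closed vocabularies; the filter and feature-name tokens
    are opaque.

    Raises
    ------
    FeatureNameError
        If the name does not have five underscore-delimited fields or the
        region/sequence token is unknown.  The message names the offending
        field.
    """
    parts = name.split("_")
    if len(parts) != 5:
        raise FeatureNameError(
            f"feature name {name!r}: expected 5 underscore-delimited fields, "
            f"got {len(parts)}"
        )
    image_filter, feature_class, feature_name, sequence, region = parts
    if region not in VALID_REGIONS:
        raise FeatureNameError(
            f"feature name {name!r}: unknown region {region!r} "
            f"(expected one of {VALID_REGIONS})"
        )
    if sequence not in VALID_SEQUENCES:
        raise FeatureNameError(
            f"feature name {name!r}: unknown sequence {sequence!r} "
            f"(expected one of {VALID_SEQUENCES})"
        )
    return ParsedFeatureName(image_filter, feature_class, feature_name, sequence, region)


@dataclass
class FeatureTable:
    """Numeric samples x features matrix with unique sample and feature names."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"matrix has {n} rows but {len(self.sample_ids)} sample IDs"
            )
        if p != len(self.feature_names):
            raise ValueError(
                f"matrix has {p} columns but {len(self.feature_names)} feature names"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_names[bad[1]]!r}; missing values are "
                "rejected, not imputed"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(list(self.sample_ids), list(names), self.values[:, idx])

    def subset_samples(self, mask: np.ndarray) -> "FeatureTable":
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        return FeatureTable(ids, list(self.feature_names), self.values[mask])


@dataclass
class CohortMetadata:
    """Per-sample environment (center) label and binary outcome.

    ``positive_class`` designates which outcome label is treated as the
    positive class in every downstream metric.  The default convention in
    this package is wild-type-positive.
    """

    sample_ids: list[str]
    environment: list[str]
    outcome: list[str]
    positive_class: str

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.environment) != n or len(self.outcome) != n:
            raise ValueError("environment/outcome length does not match sample_ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs in metadata")
        classes = sorted(set(self.outcome))
        if len(classes) > 2:
            raise ValueError(
                f"outcome must be binary; found {len(classes)} distinct labels: {classes}"
            )
        # a single-class subset (e.g. a held-out center) is tolerated; a
        # two-class cohort must name one of its labels as positive
        if len(classes) == 2 and self.positive_class not in classes:
            raise ValueError(
                f"positive class {self.positive_class!r} not among outcome labels {classes}"
            )
        envs = set(self.environment)
        if len(envs) < 1 or any(self.environment.count(e) == 0 for e in envs):
            raise ValueError("each environment must be non-empty")

    @property
    def environments(self) -> list[str]:
        """Distinct environment labels in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.environment:
            seen.setdefault(e)
        return list(seen)

    @property
    def y(self) -> np.ndarray:
        """Binary outcome vector, 1 = positive class."""
        return np.array([1 if o == self.positive_class else 0 for o in self.outcome])

    @property
    def env_array(self) -> np.ndarray:
        return np.asarray(self.environment, dtype=object)

    def subset(self, mask: np.ndarray) -> "CohortMetadata":
        keep = np.asarray(mask, dtype=bool)
        return CohortMetadata(
            [s for s, m in zip(self.sample_ids, keep) if m],
            [e for e, m in zip(self.environment, keep) if m],
            [o for o, m in zip(self.outcome, keep) if m],
            self.positive_class,
        )


@dataclass
class IOConfig:
    """Column names and conventions for reading feature/metadata files."""

    environment_column: str = "center"
    outcome_column: str = "idh_status"
    positive_class: str = "wild-type"
    delimiter: str = ","


def _load_io_config(config: "IOConfig | Mapping[str, Any] | str | Path | None") -> IOConfig:
    if config is None:
        return IOConfig()
    if isinstance(config, IOConfig):
        return config
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    return IOConfig(**dict(config))


def read_feature_table(
    path: str | Path,
    metadata_path: str | Path,
    config: "IOConfig | Mapping[str, Any] | str | Path | None" = None,
) -> tuple[FeatureTable, CohortMetadata]:
    """Read a delimited feature table and its metadata, aligned by sample ID.

    Both files are delimited text with a header row and the sample ID in the
    first column.  Samples present in only one of the two files are dropped,
    with the count logged.  Non-numeric feature cells and duplicate sample
    IDs are errors.
    """
    cfg = _load_io_config(config)
    feats = pd.read_csv(path, sep=cfg.delimiter, index_col=0,
                        float_precision="round_trip")
    meta = pd.read_csv(metadata_path, sep=cfg.delimiter, index_col=0)
    feats.index = feats.index.astype(str)
    meta.index = meta.index.astype(str)

    if feats.index.duplicated().any():
        dup = feats.index[feats.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID in feature table: {dup!r}")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID in metadata: {dup!r}")

    for col in (cfg.environment_column, cfg.outcome_column):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")

    common = feats.index.intersection(meta.index)
    dropped = (len(feats) - len(common)) + (len(meta) - len(common))
    if dropped:
        logger.warning(
            "dropped %d sample(s) present in only one of the two files", dropped
        )
    feats = feats.loc[common]
    meta = meta.loc[common]

    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().values & feats.notna().values)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-numeric feature value at sample {feats.index[r]!r}, "
            f"column {feats.columns[c]!r}: {feats.iat[r, c]!r}"
        )

    table = FeatureTable(
        sample_ids=list(feats.index),
        feature_names=list(feats.columns),
        values=numeric.values,
    )
    metadata = CohortMetadata(
        sample_ids=list(meta.index),
        environment=[str(v) for v in meta[cfg.environment_column]],
        outcome=[str(v) for v in meta[cfg.outcome_column]],
        positive_class=cfg.positive_class,
    )
    return table, metadata


def write_feature_table(
    table: FeatureTable,
    metadata: CohortMetadata,
    path: str | Path,
    metadata_path: str | Path,
    config: "IOConfig | None" = None,
) -> None:
    """Write a feature table and metadata as CSV, inverse of read_feature_table."""
    cfg = config or IOConfig()
    # %.17g guarantees float64 round-trip through text
    table.to_frame().rename_axis("sample_id").to_csv(
        path, sep=cfg.delimiter, float_format="%.17g"
    )
    pd.DataFrame(
        {
            cfg.environment_column: metadata.environment,
            cfg.outcome_column: metadata.outcome,
        },
        index=pd.Index(metadata.sample_ids, name="sample_id"),
    ).to_csv(metadata_path, sep=cfg.delimiter)


def write_report(report: Mapping[str, Any] | Any, path: str | Path) -> None:
    """Serialize an evaluation report to JSON with stable key order.

    Accepts either a plain mapping or any object exposing ``to_dict()``
    (e.g. :class:`radicp.evaluation.EvaluationReport`).  Two runs with the
    same seed and configuration produce byte-identical files.
    """
    if hasattr(report, "to_dict"):
        report = report.to_dict()
    payload = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    Path(path).write_text(payload + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
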