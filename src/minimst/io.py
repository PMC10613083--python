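"""CSV reading/writing and run manifests.

The canonical on-disk format is a header CSV whose feature columns are all
numeric; an optional label column holds ground truth (``0``/``1`` or
``normal``/``outlier``).  Detection output is written as
``id,outlier,cluster_id`` (1 = outlier; cluster_id -1 for outliers), and
every run can be snapshotted into a :class:`RunManifest` from which it is
exactly reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DetectionResult, MmodConfig
from .mst import PointSet

__all__ = ["read_dataset", "write_dataset", "write_labels", "RunManifest"]

_LABEL_STRINGS = {"0": 0, "1": 1, "normal": 0, "outlier": 1}


def read_dataset(path, label_column: str | None = None) -> PointSet:
    """Load a header CSV into a :class:`PointSet`.

    All non-label columns must be numeric; offending cells are reported by
    row and column.  The label column, if named, accepts {0, 1} or
    {"normal", "outlier"} and is split into ``truth_labels``.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: no data rows")

    truth = None
    if label_column is not None:
        if label_column not in frame.columns:
            raise ValueError(f"{path}: unknown label column {label_column!r}")
        raw = frame.pop(label_column)
        truth = np.empty(len(raw), dtype=int)
        for i, value in enumerate(raw):
            key = str(value).strip().lower()
            if key.endswith(".0"):
                key = key[:-2]
            if key not in _LABEL_STRINGS:
                raise ValueError(
                    f"{path}: row {i}, column {label_column!r}: "
                    f"unrecognized label {value!r}"
                )
            truth[i] = _LABEL_STRINGS[key]

    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: row {row}, column {col!r}: non-numeric value {frame[col].iloc[row]!r}"
            )
        frame[col] = converted
    if frame.isna().any().any():
        row = int(np.flatnonzero(frame.isna().any(axis=1))[0])
        raise ValueError(f"{path}: row {row}: missing value")

    return PointSet(coordinates=frame.to_numpy(dtype=float), truth_labels=truth)


def write_dataset(points: PointSet, path) -> None:
    """Write the canonical CSV: ``x1..xn`` plus a ``label`` column if present."""
    n = points.n_features
    frame = pd.DataFrame(points.coordinates, columns=[f"x{i + 1}" for i in range(n)])
    if points.truth_labels is not None:
        frame["label"] = points.truth_labels
    _write_csv(frame, path)


def write_labels(result: DetectionResult, path, ids=None) -> None:
    """Write per-point detection output: ``id,outlier,cluster_id``."""
    n = len(result.outlier_mask)
    frame = pd.DataFrame(
        {
            "id": ids if ids is not None else np.arange(n),
            "outlier": result.outlier_mask.astype(int),
            "cluster_id": result.cluster_id,
        }
    )
    _write_csv(frame, path)


def _write_csv(frame: pd.DataFrame, path) -> None:
    import sys

    if str(path) == "-":
        frame.to_csv(sys.stdout, index=False)
    else:
        frame.to_csv(path, index=False)


@dataclass
class RunManifest:
    """Everything needed to reproduce one detection run exactly."""

    input_path: str
    config: dict
    seed: int | None
    package_version: str
    n_points: int
    n_features: int
    t_t: float
    least_number: int
    n_outliers: int
    n_clusters: int
    cluster_sizes: dict
    elapsed_seconds: float
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    @classmethod
    def from_run(
        cls,
        input_path,
        config: MmodConfig,
        result: DetectionResult,
        n_points: int,
        n_features: int,
        elapsed: float,
    ) -> "RunManifest":
        from . import __version__

        return cls(
            input_path=str(input_path),
            config=asdict(config),
            seed=config.random_state,
            package_version=__version__,
            n_points=n_points,
            n_features=n_features,
            t_t=result.t_t,
            least_number=result.least_number,
            n_outliers=result.n_outliers,
            n_clusters=len(result.cluster_sizes()),
            cluster_sizes={str(k): v for k, v in result.cluster_sizes().items()},
            elapsed_seconds=round(elapsed, 4),
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def to_config(self) -> MmodConfig:
        return MmodConfig(**self.config)
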