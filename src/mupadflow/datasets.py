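"""Dataset assembly: raw, replicate-averaged and normalized profile matrices.

The classification study uses four dataset variants built from the same
height profiles:

* **raw** -- one row per profile, one column per retained frame
  (126 x 1800 under the default design);
* **mean** -- the three simultaneously acquired replicates of each
  concentration within a session averaged elementwise (42 x 1800);
* **fit coefficient** (60 s and 15 s) -- a single fitted square-root-slope
  per mean profile, built by :mod:`mupadflow.washburn`.

Frame-feature datasets are min-max normalized per feature (each frame
index scaled by its own min/max across samples) before classification;
averaging always operates on un-normalized pixel heights so that the
quantity fitted downstream keeps its units.  Normalization parameters are
computed once on the full dataset, as the study protocol implies -- the
resulting train/test leakage under cross-validation is reproduced
deliberately and documented, not silently fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .frontextract import HeightSeries

__all__ = [
    "ProfileDataset",
    "build_raw_dataset",
    "average_replicates",
    "minmax_normalize",
    "truncate_window",
]


@dataclass
class ProfileDataset:
    """A labeled samples-x-features matrix of flow profiles or coefficients.

    ``labels`` hold the concentration class (g/L) and ``groups`` the session
    id for each row.  ``feature_kind`` is ``frame_height`` (columns are
    frames) or ``fit_coefficient`` (single column).  ``norm_params`` records
    the min/max used by normalization for audit.
    """

    matrix: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    feature_kind: str = "frame_height"
    normalization: str = "none"
    norm_params: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        if not (len(self.labels) == len(self.groups) == self.matrix.shape[0]):
            raise ValueError("labels, groups and matrix rows must align")
        if self.feature_kind == "fit_coefficient" and self.matrix.shape[1] != 1:
            raise ValueError("fit_coefficient datasets have exactly one column")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def class_counts(self) -> dict:
        values, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        if self.feature_kind == "fit_coefficient":
            cols = ["a"]
        else:
            cols = [f"h_{i}" for i in range(self.n_features)]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "class_gL", self.labels)
        df.insert(0, "session", self.groups)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, feature_kind: str = "frame_height") -> "ProfileDataset":
        df = pd.read_csv(path)
        feature_cols = [c for c in df.columns if c not in ("session", "class_gL")]
        return cls(
            matrix=df[feature_cols].to_numpy(dtype=float),
            labels=df["class_gL"].to_numpy(),
            groups=df["session"].to_numpy(),
            feature_kind=feature_kind,
        )


def build_raw_dataset(
    profiles: Sequence[HeightSeries] | Sequence[np.ndarray],
    labels: Sequence,
    sessions: Sequence,
) -> ProfileDataset:
    """Stack equal-length profiles into a samples x frames matrix.

    Row order follows input order; under the default design this is the
    126 x 1800 "raw dataset".
    """
    arrays = [
        np.asarray(p.heights if isinstance(p, HeightSeries) else p, dtype=float)
        for p in profiles
    ]
    if not arrays:
        raise ValueError("no profiles given")
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"profiles have ragged lengths: {sorted(lengths)}")
    if not (len(labels) == len(sessions) == len(arrays)):
        raise ValueError("labels and sessions must align with profiles")
    return ProfileDataset(
        matrix=np.vstack(arrays),
        labels=np.asarray(labels),
        groups=np.asarray(sessions),
        feature_kind="frame_height",
    )


def average_replicates(dataset: ProfileDataset) -> ProfileDataset:
    """Average the replicate rows of each (session, class) group elementwise.

    Collapses the three simultaneously acquired replicates per
    concentration to one mean profile; 126 rows become 42 under the default
    design.  Group order follows the first occurrence in the input.
    """
    keys = list(zip(dataset.groups.tolist(), dataset.labels.tolist()))
    seen: dict = {}
    for key in keys:
        seen.setdefault(key, len(seen))
    order = sorted(seen, key=seen.get)
    rows, labels, groups = [], [], []
    for session, label in order:
        mask = (dataset.groups == session) & (dataset.labels == label)
        rows.append(dataset.matrix[mask].mean(axis=0))
        labels.append(label)
        groups.append(session)
    return ProfileDataset(
        matrix=np.vstack(rows),
        labels=np.asarray(labels),
        groups=np.asarray(groups),
        feature_kind=dataset.feature_kind,
        normalization=dataset.normalization,
    )


def minmax_normalize(dataset: ProfileDataset, mode: str = "per_feature") -> ProfileDataset:
    """Min-max scale to [0, 1].

    ``per_feature`` scales each column by its own min/max across samples
    (each frame index normalized over the cohort); ``per_profile`` scales
    each row by its own min/max across columns.  A constant column/row maps
    to all zeros.  Idempotent: re-normalizing changes nothing.
    """
    if dataset.n_samples == 0:
        raise ValueError("empty dataset")
    if mode not in ("per_feature", "per_profile"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    x = dataset.matrix
    axis = 0 if mode == "per_feature" else 1
    lo = x.min(axis=axis, keepdims=True)
    hi = x.max(axis=axis, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    return replace(
        dataset,
        matrix=scaled,
        normalization=mode,
        norm_params={"mode": mode, "min": np.squeeze(lo, axis=axis), "max": np.squeeze(hi, axis=axis)},
    )


def truncate_window(dataset: ProfileDataset, seconds: float, fps: float) -> ProfileDataset:
    """Keep only the first ``seconds * fps`` frame columns.

    Used to fit the square-root model on the initial 15 s of flow instead
    of the full 60 s.
    """
    if dataset.feature_kind != "frame_height":
        raise ValueError("can only truncate frame-height datasets")
    n_keep = int(round(seconds * fps))
    if n_keep > dataset.n_features:
        raise ValueError(
            f"window of {n_keep} frames exceeds the {dataset.n_features} available"
        )
    if n_keep < 1:
        raise ValueError("window must keep at least one frame")
    return replace(dataset, matrix=dataset.matrix[:, :n_keep])
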