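"""Shared in-memory containers used across the pipeline.

The central object is :class:`FeatureMatrix`, a thin validated wrapper around
a ``(n_molecules, n_features)`` numpy array with molecule ids and feature
names, tagged with the representation kind it holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

FEATURE_KINDS = ("descriptor_panel", "maccs", "ecfp4", "custom_fragment", "synthetic")
_BINARY_KINDS = ("maccs", "ecfp4", "custom_fragment")


@dataclass
class FeatureMatrix:
    """Molecules x named features for one representation kind.

    Parameters
    ----------
    molecule_ids : sequence of str
        One id per row.
    feature_names : sequence of str
        Unique column names.
    values : ndarray of shape (n_molecules, n_features)
        Fingerprint kinds must contain only {0, 1}.
    kind : str
        One of ``descriptor_panel``, ``maccs``, ``ecfp4``, ``custom_fragment``
        or ``synthetic`` (abstract numeric worlds).
    metadata : dict
        Optional per-column annotation (descriptor category, bit provenance).
    """

    molecule_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    kind: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.molecule_ids = [str(i) for i in self.molecule_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.molecule_ids), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.molecule_ids)} ids x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicated feature names")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind in _BINARY_KINDS:
            finite = self.values[np.isfinite(self.values)]
            if not np.isin(finite, (0.0, 1.0)).all():
                raise ValueError(f"{self.kind} matrices must be binary")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.molecule_ids, columns=self.feature_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "synthetic", metadata: dict | None = None) -> "FeatureMatrix":
        return cls(
            molecule_ids=list(df.index.astype(str)),
            feature_names=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            kind=kind,
            metadata=metadata or {},
        )

    def subset_features(self, names: Sequence[str]) -> "FeatureMatrix":
        """Return a copy restricted to ``names`` (order follows ``names``)."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            molecule_ids=list(self.molecule_ids),
            feature_names=[self.feature_names[i] for i in idx],
            values=self.values[:, idx].copy(),
            kind=self.kind,
            metadata=self.metadata,
        )

    def subset_molecules(self, ids: Sequence[str]) -> "FeatureMatrix":
        pos = {m: i for i, m in enumerate(self.molecule_ids)}
        idx = [pos[str(i)] for i in ids]
        return FeatureMatrix(
            molecule_ids=[self.molecule_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            values=self.values[idx].copy(),
            kind=self.kind,
            metadata=self.metadata,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="molecule_id")

    @classmethod
    def read_csv(cls, path, kind: str = "synthetic") -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="molecule_id")
        df.index = df.index.astype(str)
        return cls.from_dataframe(df, kind=kind)
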