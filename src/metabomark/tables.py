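"""Core in-memory containers shared by every pipeline stage.

The universal currency is the :class:`FeatureTable`: a samples × features
intensity matrix (``NaN`` marks a missing/undetected peak) together with the
per-sample metadata the workflow needs — a group label (e.g. ``HC``, ``PA`` …)
and a flag marking pooled quality-control injections — and optional per-feature
annotations (m/z, retention time, putative identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "ScaledMatrix"]


@dataclass
class FeatureTable:
    """Samples × features intensity table with sample and feature metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per feature.
        Intensities must be ``>= 0`` where present; ``NaN`` means missing.
    groups
        Per-sample group label, aligned with ``values.index``.
    is_qc
        Per-sample boolean flag marking pooled-QC injections.
    feature_meta
        Optional per-feature annotations (index aligned with
        ``values.columns``); conventional columns are ``mz`` (Da),
        ``rt`` (min) and ``name``.
    """

    values: pd.DataFrame
    groups: pd.Series
    is_qc: pd.Series
    feature_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature ids: {dupes}")
        self.groups = pd.Series(self.groups, index=self.values.index).astype(str)
        self.is_qc = pd.Series(self.is_qc, index=self.values.index).astype(bool)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("intensities must be nonnegative where present")
        if self.feature_meta is not None:
            self.feature_meta = self.feature_meta.reindex(self.values.columns)

    # -- basic views ---------------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def biological(self) -> "FeatureTable":
        """Subtable of non-QC (biological) samples."""
        return self.subset_samples(~self.is_qc)

    def qc(self) -> "FeatureTable":
        """Subtable of pooled-QC injections."""
        return self.subset_samples(self.is_qc)

    def subset_samples(self, mask) -> "FeatureTable":
        mask = np.asarray(mask)
        return FeatureTable(
            self.values.loc[mask],
            self.groups.loc[mask],
            self.is_qc.loc[mask],
            self.feature_meta,
        )

    def subset_features(self, feature_ids) -> "FeatureTable":
        meta = None if self.feature_meta is None else self.feature_meta.loc[feature_ids]
        return FeatureTable(
            self.values.loc[:, feature_ids], self.groups, self.is_qc, meta
        )

    def group(self, label: str, biological_only: bool = True) -> pd.DataFrame:
        """Intensity rows of one group (QC rows excluded by default)."""
        mask = self.groups == label
        if biological_only:
            mask &= ~self.is_qc
        return self.values.loc[np.asarray(mask)]

    def pair(self, group_a: str, group_b: str) -> "FeatureTable":
        """Biological samples of two groups, in original row order."""
        for g in (group_a, group_b):
            if g not in set(self.groups):
                raise KeyError(f"group {g!r} not present in table")
        mask = self.groups.isin([group_a, group_b]) & ~self.is_qc
        return self.subset_samples(np.asarray(mask))

    def copy(self) -> "FeatureTable":
        meta = None if self.feature_meta is None else self.feature_meta.copy()
        return FeatureTable(
            self.values.copy(), self.groups.copy(), self.is_qc.copy(), meta
        )


@dataclass
class ScaledMatrix:
    """Result of centring/scaling a (log-transformed) feature matrix.

    Stores per-feature centres and scale factors so the transform is
    invertible, plus provenance flags recording what was applied.
    """

    values: pd.DataFrame
    center: pd.Series
    scale: pd.Series
    log2_applied: bool = False
    pareto_applied: bool = True

    def inverse(self) -> pd.DataFrame:
        """Undo scaling and centring (not the log transform)."""
        return self.values * self.scale + self.center
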