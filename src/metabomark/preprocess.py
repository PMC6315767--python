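"""Feature-table pre-processing: QC-RSD and missingness filters, log2, Pareto.

The canonical order, matching the workflow this package implements, is

    filter_by_rsd  →  filter_by_missingness  →  log2_transform  →  pareto_scale

with half-minimum imputation (:func:`impute_half_minimum`) inserted before
scaling when a complete matrix is required for modelling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tables import FeatureTable, ScaledMatrix

__all__ = [
    "compute_rsd",
    "filter_by_rsd",
    "filter_by_missingness",
    "log2_transform",
    "pareto_scale",
    "impute_half_minimum",
]


def compute_rsd(values) -> float:
    """Relative standard deviation, percent: ``100 * sd(n-1) / mean``.

    Missing entries are ignored.  Requires at least two non-missing values
    and a strictly positive mean; scale-invariant by construction.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("RSD needs at least two non-missing values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("RSD undefined for nonpositive mean")
    return float(100.0 * v.std(ddof=1) / mean)


def _report(feature_ids, metric_name, metric, passed, reason) -> pd.DataFrame:
    return pd.DataFrame(
        {metric_name: metric, "passed": passed, "reason": reason},
        index=pd.Index(feature_ids, name="feature_id"),
    )


def filter_by_rsd(
    table: FeatureTable, threshold: float = 30.0
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop features whose pooled-QC RSD is strictly above ``threshold`` %.

    The RSD is computed on the QC injections only (technical repeatability);
    features whose QC RSD is undefined (fewer than two QC values present, or
    nonpositive QC mean) are also dropped, with the reason recorded.
    Returns the filtered table and a per-feature report.
    """
    qc = table.qc()
    if qc.n_samples < 2:
        raise ValueError("RSD filtering needs at least two QC samples")
    rsd = np.full(table.n_features, np.nan)
    passed = np.zeros(table.n_features, dtype=bool)
    reason = np.array([""] * table.n_features, dtype=object)
    for j, col in enumerate(table.feature_ids):
        try:
            rsd[j] = compute_rsd(qc.values[col])
        except ValueError:
            reason[j] = "undefined QC RSD"
            continue
        if rsd[j] > threshold:
            reason[j] = f"QC RSD {rsd[j]:.1f}% > {threshold:g}%"
        else:
            passed[j] = True
    report = _report(table.feature_ids, "rsd_percent", rsd, passed, reason)
    return table.subset_features(table.feature_ids[passed]), report


def filter_by_missingness(
    table: FeatureTable, max_fraction: float = 0.20
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop features missing in strictly more than ``max_fraction`` of the
    biological samples (QC injections are not counted)."""
    bio = table.biological()
    if bio.n_samples < 1:
        raise ValueError("missingness filtering needs at least one biological sample")
    frac = bio.values.isna().mean(axis=0).to_numpy()
    passed = frac <= max_fraction
    reason = np.where(
        passed, "", [f"missing fraction {f:.2f} > {max_fraction:g}" for f in frac]
    ).astype(object)
    report = _report(table.feature_ids, "missing_fraction", frac, passed, reason)
    return table.subset_features(table.feature_ids[passed]), report


def log2_transform(table: FeatureTable, zeros: str = "raise") -> FeatureTable:
    """Elementwise log2 of the intensities; missing stays missing.

    ``zeros='raise'`` (default) rejects zero intensities, naming the
    offending cells; ``zeros='missing'`` converts them to missing with a
    warning (the pipeline's behaviour).  Negative intensities are always an
    error (and cannot occur in a validated :class:`FeatureTable`).
    """
    values = table.values.copy()
    zero_mask = values == 0
    if zero_mask.to_numpy().any():
        cells = [
            f"{values.index[i]}/{values.columns[int(c)]}"
            for i, c in zip(*np.nonzero(zero_mask.to_numpy()))
        ]
        if zeros == "missing":
            warnings.warn(
                f"{len(cells)} zero intensities converted to missing before log2",
                stacklevel=2,
            )
            values[zero_mask] = np.nan
        else:
            raise ValueError(
                "log2 undefined for zero intensity at cells: " + ", ".join(cells[:10])
            )
    out = table.copy()
    out.values = np.log2(values)
    return out


def impute_half_minimum(values: pd.DataFrame, log_scale: bool = True) -> pd.DataFrame:
    """Replace missing entries by half the feature's minimum observed value.

    On log2 data (``log_scale=True``) half-minimum is ``column min − 1``;
    on raw data it is ``column min / 2``.  Standard low-abundance imputation
    for LC-MS tables where missingness is predominantly below-LOD.
    """
    fill = values.min(axis=0, skipna=True)
    fill = fill - 1.0 if log_scale else fill / 2.0
    return values.fillna(fill)


def pareto_scale(values: pd.DataFrame) -> ScaledMatrix:
    """Mean-centre each feature then divide by the square root of its SD.

    Pareto scaling is intermediate between no scaling and unit-variance
    scaling: a scaled column keeps variance equal to the original column's
    SD, so abundant-but-variable features are shrunk without being flattened.
    Missing values are excluded pairwise from the centre/scale estimates and
    stay missing.  Features with zero SD (or fewer than two values) are
    rejected, listing the offenders.
    """
    center = values.mean(axis=0, skipna=True)
    sd = values.std(axis=0, ddof=1, skipna=True)
    bad = values.columns[(sd.isna()) | (sd <= 0)].tolist()
    if bad:
        raise ValueError(f"cannot Pareto-scale zero-variance features: {bad}")
    scale = np.sqrt(sd)
    scaled = (values - center) / scale
    return ScaledMatrix(scaled, center, scale, log2_applied=False, pareto_applied=True)
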