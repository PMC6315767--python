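"""Synthetic untargeted-metabolomics feature tables with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: feature intensities log-normal on the log2 scale, multiplicative
group effects on a subset of "differential" features, pooled-QC injections
carrying purely technical (multiplicative) noise at a requested RSD, and two
missingness mechanisms — completely-at-random dropout plus low-intensity
censoring that mimics below-limit-of-detection losses in LC-MS peak picking.

Defaults mirror the study design this package targets: ~600 features over six
groups (healthy controls ``HC`` plus Crohn's-disease timepoints ``PA``–``PE``
of 10–11 children each), five pooled QC injections at 14% technical RSD, and
eight differential features whose fold changes (0.15× to 20×) match the
magnitudes reported for faecal marker metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = ["SyntheticConfig", "generate_dataset", "generate_qc_pools", "DEFAULT_GROUPS"]

DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("HC", 11),
    ("PA", 11),
    ("PB", 10),
    ("PC", 11),
    ("PD", 11),
    ("PE", 11),
)

#: Marker-magnitude fold changes reported for the pre-treatment vs control
#: comparison (down-regulated amino-acid markers, up-regulated lipids).
DEFAULT_FOLD_CHANGES: tuple[float, ...] = (0.15, 6.54, 0.37, 14.52, 16.18, 20.32, 18.05, 11.88)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    ``fold_changes`` are linear-scale multiplicative effects applied to the
    ``affected_group`` samples of the first ``n_differential`` features; a
    value below 1 plants a down-regulated marker.  ``censor_quantile`` sets a
    per-feature low-intensity cutoff below which biological values are
    dropped, emulating below-LOD missingness; ``missing_rate_mcar`` adds
    uniform random dropout on top.
    """

    n_features: int = 600
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    n_differential: int = 8
    fold_changes: tuple[float, ...] = DEFAULT_FOLD_CHANGES
    affected_group: str = "PA"
    base_log2_mean_range: tuple[float, float] = (10.0, 24.0)
    biological_log2_sd: float = 1.0
    technical_rsd_percent: float = 14.0
    n_qc_pools: int = 5
    missing_rate_mcar: float = 0.02
    censor_quantile: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not self.groups or any(n < 1 for _, n in self.groups):
            raise ValueError("every group needs at least one sample")
        if not 0 <= self.n_differential <= self.n_features:
            raise ValueError("n_differential must lie in [0, n_features]")
        if self.n_differential and len(self.fold_changes) < self.n_differential:
            raise ValueError("need one fold change per differential feature")
        if any(fc <= 0 for fc in self.fold_changes):
            raise ValueError("fold changes must be > 0")
        for name, frac in (
            ("missing_rate_mcar", self.missing_rate_mcar),
            ("censor_quantile", self.censor_quantile),
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.biological_log2_sd < 0 or self.technical_rsd_percent < 0:
            raise ValueError("dispersion parameters must be nonnegative")
        if self.n_differential and self.affected_group not in {g for g, _ in self.groups}:
            raise ValueError(f"affected_group {self.affected_group!r} not among groups")


def generate_dataset(config: SyntheticConfig) -> tuple[FeatureTable, pd.DataFrame]:
    """Draw a feature table plus the ground-truth marker list.

    Biological intensities are drawn on the log2 scale — a per-feature base
    mean from ``base_log2_mean_range`` plus Gaussian noise of SD
    ``biological_log2_sd`` — with ``log2(fold_change)`` added to the affected
    group of each differential feature, then exponentiated.  MCAR dropout and
    low-quantile censoring are applied to biological rows only; pooled-QC rows
    (appended via :func:`generate_qc_pools`) stay complete.

    Returns
    -------
    (table, truth)
        ``truth`` has one row per differential feature with columns
        ``feature_id``, ``affected_group``, ``planted_fold_change``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    feature_ids = [f"F{j:04d}" for j in range(config.n_features)]
    sample_ids: list[str] = []
    labels: list[str] = []
    for g, n in config.groups:
        sample_ids.extend(f"{g}{i + 1:02d}" for i in range(n))
        labels.extend([g] * n)
    n_bio = len(sample_ids)

    base = rng.uniform(*config.base_log2_mean_range, size=config.n_features)
    log2x = base[None, :] + rng.normal(0.0, config.biological_log2_sd, size=(n_bio, config.n_features))

    affected = np.array([lab == config.affected_group for lab in labels])
    truth_rows = []
    for j in range(config.n_differential):
        fc = config.fold_changes[j]
        log2x[affected, j] += np.log2(fc)
        truth_rows.append(
            {"feature_id": feature_ids[j], "affected_group": config.affected_group,
             "planted_fold_change": fc}
        )
    truth = pd.DataFrame(truth_rows, columns=["feature_id", "affected_group", "planted_fold_change"])

    x = np.exp2(log2x)

    # missingness: MCAR first, then per-feature low-quantile censoring
    missing = rng.random(x.shape) < config.missing_rate_mcar
    if config.censor_quantile > 0:
        cutoffs = np.nanquantile(x, config.censor_quantile, axis=0)
        missing |= x < cutoffs[None, :]
    x[missing] = np.nan

    values = pd.DataFrame(x, index=sample_ids, columns=feature_ids)
    table = FeatureTable(
        values,
        pd.Series(labels, index=sample_ids),
        pd.Series(False, index=sample_ids),
    )
    if config.n_qc_pools > 0:
        qc_seed = int(rng.integers(2**31))
        table = generate_qc_pools(
            table, config.n_qc_pools, config.technical_rsd_percent, qc_seed
        )
    return table, truth


def generate_qc_pools(
    table: FeatureTable, n_pools: int, technical_rsd_percent: float, seed: int
) -> FeatureTable:
    """Append pooled-QC injections to a table of biological samples.

    A pooled QC emulates an injection of a mixture of every biological
    sample: each value is the feature-wise mean of the biological intensities
    times multiplicative log-normal noise whose coefficient of variation
    equals ``technical_rsd_percent`` (σ on the natural-log scale is
    ``sqrt(log(1 + cv²))`` with mean corrected to 1, so the requested RSD is
    matched in expectation, and ``technical_rsd_percent = 0`` reproduces the
    mean exactly).
    """
    bio = table.biological()
    if bio.n_samples < 1:
        raise ValueError("need at least one biological sample to pool")
    rng = np.random.default_rng(seed)
    pool_mean = bio.values.mean(axis=0, skipna=True).to_numpy()

    cv = technical_rsd_percent / 100.0
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=(n_pools, len(pool_mean))))
    else:
        noise = np.ones((n_pools, len(pool_mean)))
    qc_values = pool_mean[None, :] * noise

    qc_ids = [f"QC{i + 1:02d}" for i in range(n_pools)]
    values = pd.concat(
        [table.values, pd.DataFrame(qc_values, index=qc_ids, columns=table.feature_ids)]
    )
    groups = pd.concat([table.groups, pd.Series("QC", index=qc_ids)])
    is_qc = pd.concat([table.is_qc, pd.Series(True, index=qc_ids)])
    return FeatureTable(values, groups, is_qc, table.feature_meta)
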