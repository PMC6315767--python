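"""Marker filtration cascade and ranking for a validated pairwise model.

Candidate features are screened in a fixed order, each stage only seeing the
survivors of the previous one:

1. Student's t-test on log2 intensities (keep p ≤ 0.05);
2. jack-knife 95% CI of the model coefficient from the cross-validation
   sub-models (drop features whose CI spans zero);
3. Benjamini–Hochberg FDR on the surviving p-values (keep q ≤ 0.05);
4. ROC AUC (keep ≥ 0.7 — anything below is at best a "poor" classifier);
5. VIP (keep VIP total > 1; a feature with VIPortho > VIPpred is flagged as
   not biomarker-relevant, and dropped only in strict mode);
6. Q-Q normality per group (straightness R² of the normal quantile plot).

Survivors are ranked by VIP total, descending.  Every feature keeps a record
of its evidence and the stage (if any) at which it was dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .opls import ModelFit, OplsModel, compute_vip
from .tables import FeatureTable

__all__ = [
    "CascadeConfig",
    "MarkerRecord",
    "MarkerReport",
    "ttest_feature",
    "jackknife_ci",
    "bh_fdr",
    "roc_auc",
    "auc_band",
    "qq_normality",
    "qq_critical_r2",
    "fold_change",
    "correlate_with_covariate",
    "select_markers",
]

STAGES = ("t_test", "jackknife", "bh_fdr", "auc", "vip", "qq")


@dataclass
class CascadeConfig:
    """Thresholds of the filtration cascade.

    ``require_pred_ge_ortho=True`` (strict mode) turns the
    VIPortho > VIPpred flag into a drop.  ``qq_r2_min=None`` (default) uses
    the sample-size-calibrated Q-Q critical value; a fixed cutoff may be
    supplied instead.
    """

    alpha_t: float = 0.05
    alpha_q: float = 0.05
    auc_min: float = 0.7
    vip_total_min: float = 1.0
    require_pred_ge_ortho: bool = False
    qq_r2_min: float | None = None
    ttest_variant: str = "student"

    def validate(self) -> None:
        for name in ("alpha_t", "alpha_q", "auc_min", "qq_r2_min"):
            v = getattr(self, name)
            if v is None and name == "qq_r2_min":
                continue
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.vip_total_min < 0:
            raise ValueError("vip_total_min must be >= 0")
        if self.ttest_variant not in ("student", "welch"):
            raise ValueError("ttest_variant must be 'student' or 'welch'")


@dataclass
class MarkerRecord:
    """Per-feature evidence accumulated through the cascade."""

    feature_id: str
    p_value: float
    q_value: float
    auc: float
    auc_band: str
    ci_low: float
    ci_high: float
    spans_zero: bool
    vip_pred: float
    vip_ortho: float
    vip_total: float
    vip_ratio: float
    ratio: float
    log2_ratio: float
    qq_r2: float
    qq_normal: bool
    not_biomarker_relevant: bool
    passed: dict = field(default_factory=dict)
    drop_stage: str = ""
    selected: bool = False
    rank: int | None = None


@dataclass
class MarkerReport:
    """All per-feature records plus the ranked selection."""

    records: list[MarkerRecord]
    group_a: str
    group_b: str

    @property
    def selected(self) -> list[MarkerRecord]:
        chosen = [r for r in self.records if r.selected]
        return sorted(chosen, key=lambda r: r.rank)

    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "feature_id": r.feature_id,
                "ratio": r.ratio,
                "log2_ratio": r.log2_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "auc": r.auc,
                "auc_band": r.auc_band,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "vip_total": r.vip_total,
                "vip_pred": r.vip_pred,
                "vip_ortho": r.vip_ortho,
                "vip_ratio": r.vip_ratio,
                "qq_r2": r.qq_r2,
                "qq_normal": r.qq_normal,
                "not_biomarker_relevant": r.not_biomarker_relevant,
                "selected": r.selected,
                "rank": r.rank,
                "drop_stage": r.drop_stage,
            }
            rows.append(row)
        return pd.DataFrame(rows).set_index("feature_id")


# ---------------------------------------------------------------------------
# Individual statistics
# ---------------------------------------------------------------------------

def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[~np.isnan(v)]


def ttest_feature(group_a, group_b, variant: str = "student") -> float:
    """Two-sided two-sample t-test p-value on (already log2) values.

    ``variant='student'`` pools variances (the default for marker screening);
    ``'welch'`` drops the equal-variance assumption.  Missing values are
    excluded.  A fully degenerate comparison (zero variance in both groups)
    returns p = 1 for equal means and p = 0 otherwise.
    """
    a, b = _clean(group_a), _clean(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two non-missing values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.pvalue)


def jackknife_ci(
    full_coefficients, fold_coefficients, level: float = 0.95
) -> pd.DataFrame:
    """Jack-knife confidence intervals for model coefficients.

    The standard error of each coefficient is estimated from its variation
    across the K cross-validation sub-models,
    ``SE = sqrt((K−1)/K · Σₖ (bₖ − b̄)²)``, and the CI is the full-model
    coefficient ± t(K−1) quantile × SE.  A CI covering zero marks the
    coefficient (hence the feature) as unreliable.
    """
    b = np.asarray(full_coefficients, dtype=float)
    bk = np.atleast_2d(np.asarray(fold_coefficients, dtype=float))
    K = bk.shape[0]
    if K < 2:
        raise ValueError("jack-knife needs at least two sub-model coefficient vectors")
    se = np.sqrt((K - 1) / K * ((bk - bk.mean(axis=0)) ** 2).sum(axis=0))
    tcrit = stats.t.ppf(0.5 + level / 2, K - 1)
    low, high = b - tcrit * se, b + tcrit * se
    return pd.DataFrame(
        {"ci_low": low, "ci_high": high, "spans_zero": (low <= 0) & (high >= 0)}
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values: ``q_(i) = min_{j≥i} m·p_(j)/j``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def auc_band(auc: float) -> str:
    """Classifier-quality label for an ROC area (orientation-folded)."""
    if auc >= 0.9:
        return "excellent"
    if auc >= 0.8:
        return "good"
    if auc >= 0.7:
        return "fair"
    if auc >= 0.6:
        return "poor"
    return "failed"


def roc_auc(group_a, group_b) -> tuple[float, str]:
    """ROC area for one feature separating two groups, with quality band.

    The AUC is the rank-sum probability that a random sample of one group
    exceeds one of the other (ties count ½), folded to ≥ 0.5 so up- and
    down-regulated markers are treated alike.
    """
    a, b = _clean(group_a), _clean(group_b)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one non-missing value")
    u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    auc = float(u) / (a.size * b.size)
    auc = max(auc, 1.0 - auc)
    return auc, auc_band(auc)


def qq_critical_r2(n: int, alpha: float = 0.05) -> float:
    """Null 5%-level critical value for the normal Q-Q correlation at sample
    size n (squared), via the Ryan–Joiner approximation.

    The straightness R² of a Q-Q plot drops with sample size even for
    perfectly normal data (its null median at n = 11 is about 0.94), so a
    fixed cutoff conflates non-normality with small n; the correlation test
    of normality calibrates the cutoff to n instead.  Only the conventional
    levels 0.10, 0.05 and 0.01 are tabulated.
    """
    coef = {
        0.10: (1.0071, -0.1371, -0.3682, 0.7780),
        0.05: (1.0063, -0.1288, -0.6118, 1.3505),
        0.01: (0.9963, -0.0211, -1.4106, 3.1791),
    }
    if alpha not in coef:
        raise ValueError("alpha must be one of 0.10, 0.05, 0.01")
    b0, b1, b2, b3 = coef[alpha]
    r = b0 + b1 / np.sqrt(n) + b2 / n + b3 / n**2
    return float(min(r, 1.0) ** 2)


def qq_normality(values, r2_min: float | None = None) -> tuple[float, bool]:
    """Straightness (R²) of the normal quantile–quantile plot.

    Ordered sample values are regressed on standard normal quantiles at
    plotting positions (i − 0.5)/n; a high R² is consistent with normality.
    With ``r2_min=None`` (default) the pass threshold is the sample-size-
    calibrated 5% critical value of :func:`qq_critical_r2`; a fixed cutoff
    may be supplied instead.
    """
    v = np.sort(_clean(values))
    n = v.size
    if n < 3:
        raise ValueError("Q-Q check needs at least three non-missing values")
    if v[0] == v[-1]:
        raise ValueError("Q-Q check undefined for a constant sample")
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    r = np.corrcoef(q, v)[0, 1]
    r2 = float(r**2)
    threshold = qq_critical_r2(n) if r2_min is None else r2_min
    return r2, r2 >= threshold


def fold_change(group_a, group_b) -> tuple[float, float]:
    """Raw-scale group-mean ratio mean(A)/mean(B) and its log2."""
    a, b = _clean(group_a), _clean(group_b)
    if a.size == 0 or b.size == 0 or a.mean() <= 0 or b.mean() <= 0:
        raise ValueError("fold change needs positive group means")
    ratio = float(a.mean() / b.mean())
    return ratio, float(np.log2(ratio))


def correlate_with_covariate(
    marker_values, covariate, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation (and two-sided p) between a marker and a clinical
    covariate such as faecal calprotectin; pairs with a missing member are
    dropped."""
    x = np.asarray(marker_values, dtype=float)
    y = np.asarray(covariate, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least three paired non-missing observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def select_markers(
    table: FeatureTable,
    model: OplsModel,
    fit: ModelFit,
    config: CascadeConfig | None = None,
    group_a: str | None = None,
    group_b: str | None = None,
    raw_values: pd.DataFrame | None = None,
) -> MarkerReport:
    """Run the six-stage filtration cascade on a log2-scale feature table.

    ``table`` carries log2 intensities (missing allowed — univariate stages
    exclude missing pairwise); ``model``/``fit`` must come from the same
    group pair, whose labels default to the model's.  ``raw_values``
    optionally supplies untransformed intensities for fold changes; by
    default they are recovered as ``2**log2``.
    """
    cfg = config or CascadeConfig()
    cfg.validate()
    if group_a is None or group_b is None:
        if model.class_labels is None:
            raise ValueError("pass group_a/group_b or fit the model with labels")
        group_b, group_a = model.class_labels  # positive class first by convention
    a_rows = table.group(group_a)
    b_rows = table.group(group_b)
    raw = raw_values if raw_values is not None else np.exp2(table.values)

    vip = compute_vip(model)
    ci = jackknife_ci(model.coefficients, fit.fold_coefficients)
    ci.index = table.feature_ids

    records: list[MarkerRecord] = []
    for fid in table.feature_ids:
        a, b = a_rows[fid], b_rows[fid]
        try:
            p = ttest_feature(a, b, variant=cfg.ttest_variant)
            auc, band = roc_auc(a, b)
            ratio, log2_ratio = fold_change(
                raw.loc[a_rows.index, fid], raw.loc[b_rows.index, fid]
            )
        except ValueError:  # too few non-missing values in a group
            p, auc, band = float("nan"), float("nan"), ""
            ratio, log2_ratio = float("nan"), float("nan")
        try:
            qq_a, ok_a = qq_normality(a, cfg.qq_r2_min)
            qq_b, ok_b = qq_normality(b, cfg.qq_r2_min)
            qq_r2, qq_ok = min(qq_a, qq_b), ok_a and ok_b
        except ValueError:
            qq_r2, qq_ok = float("nan"), False
        records.append(
            MarkerRecord(
                feature_id=str(fid),
                p_value=p,
                q_value=float("nan"),
                auc=auc,
                auc_band=band,
                ci_low=float(ci.loc[fid, "ci_low"]),
                ci_high=float(ci.loc[fid, "ci_high"]),
                spans_zero=bool(ci.loc[fid, "spans_zero"]),
                vip_pred=float(vip.vip_pred[fid]),
                vip_ortho=float(vip.vip_ortho[fid]),
                vip_total=float(vip.vip_total[fid]),
                vip_ratio=float(vip.ratio[fid]),
                ratio=ratio,
                log2_ratio=log2_ratio,
                qq_r2=qq_r2,
                qq_normal=qq_ok,
                not_biomarker_relevant=bool(vip.vip_ortho[fid] > vip.vip_pred[fid]),
            )
        )

    def fail(rec: MarkerRecord, stage: str) -> None:
        rec.passed[stage] = False
        if not rec.drop_stage:
            rec.drop_stage = stage

    # stage 1: t-test
    alive = []
    for rec in records:
        if rec.p_value <= cfg.alpha_t:
            rec.passed["t_test"] = True
            alive.append(rec)
        else:
            fail(rec, "t_test")

    # stage 2: jack-knife CI
    survivors = []
    for rec in alive:
        if rec.spans_zero:
            fail(rec, "jackknife")
        else:
            rec.passed["jackknife"] = True
            survivors.append(rec)
    alive = survivors

    # stage 3: BH FDR on surviving p-values
    if alive:
        qs = bh_fdr([rec.p_value for rec in alive])
        survivors = []
        for rec, q in zip(alive, qs):
            rec.q_value = float(q)
            if q <= cfg.alpha_q:
                rec.passed["bh_fdr"] = True
                survivors.append(rec)
            else:
                fail(rec, "bh_fdr")
        alive = survivors

    # stage 4: AUC
    survivors = []
    for rec in alive:
        if rec.auc >= cfg.auc_min:
            rec.passed["auc"] = True
            survivors.append(rec)
        else:
            fail(rec, "auc")
    alive = survivors

    # stage 5: VIP
    survivors = []
    for rec in alive:
        if rec.vip_total <= cfg.vip_total_min:
            fail(rec, "vip")
        elif cfg.require_pred_ge_ortho and rec.not_biomarker_relevant:
            fail(rec, "vip")
        else:
            rec.passed["vip"] = True
            survivors.append(rec)
    alive = survivors

    # stage 6: per-group Q-Q normality
    survivors = []
    for rec in alive:
        if not rec.qq_normal:
            fail(rec, "qq")
        else:
            rec.passed["qq"] = True
            survivors.append(rec)

    for rank, rec in enumerate(
        sorted(survivors, key=lambda r: -r.vip_total), start=1
    ):
        rec.selected = True
        rec.rank = rank

    return MarkerReport(records=records, group_a=group_a, group_b=group_b)
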