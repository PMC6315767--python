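"""Three-part OPLS-DA model validation.

A pairwise model is accepted in two steps:

* **valid** — the label-permutation test passes *and* the overfitting gap
  R2 − Q2 is at most 0.3;
* **significant** — the model is valid *and* the CV-ANOVA p-value is below
  0.05.

The permutation test refits the model under shuffled class labels (999 times
by default) and records permuted (R2, Q2) against the absolute correlation of
the shuffled labels with the originals.  The model passes if the regression
line of permuted Q2 on that correlation extrapolates to ≤ 0 at correlation
zero, or if no permuted Q2 reaches the original Q2 (a tie counts against the
model).

CV-ANOVA attaches an F-test p-value to the cross-validated model by comparing
the drop from total to predictive residual variation:
F = ((SS − PRESS)/d1) / (PRESS/d2), d1 = number of fitted components,
d2 = n − d1 − 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .opls import ModelFit, evaluate_fit

__all__ = [
    "PermutationReport",
    "CvAnovaResult",
    "ModelVerdict",
    "permutation_test",
    "cv_anova",
    "assess_model",
]


@dataclass
class PermutationReport:
    n_permutations: int
    permuted_r2: np.ndarray
    permuted_q2: np.ndarray
    label_correlations: np.ndarray  # |corr(y_perm, y)| per permutation
    original_r2: float
    original_q2: float
    r2_intercept: float
    q2_intercept: float
    q2_line_crosses_zero: bool
    no_perm_q2_exceeds_original: bool
    seed: int

    @property
    def passed(self) -> bool:
        return self.q2_line_crosses_zero or self.no_perm_q2_exceeds_original


@dataclass
class CvAnovaResult:
    f_statistic: float
    df1: float
    df2: float
    p_value: float


@dataclass
class ModelVerdict:
    """One row of a model-validation summary table."""

    r2x_cum: float
    r2: float
    q2: float
    permutation_pass: bool
    r2_minus_q2: float
    valid: bool
    p_cv_anova: float
    significant: bool
    model_name: str = ""


def _intercept(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept)


def permutation_test(
    X,
    y,
    n_ortho: int = 1,
    n_perm: int = 999,
    seed: int = 0,
    n_folds: int = 7,
) -> PermutationReport:
    """Label-permutation validation of an OPLS-DA model.

    For each of ``n_perm`` permutations the class vector is shuffled, the
    model refit (including cross-validation for Q2), and (R2, Q2) recorded
    together with the absolute correlation between permuted and original
    labels.  Regression lines of permuted R2 and Q2 on that correlation —
    anchored by the original model at correlation 1 — are extrapolated to
    correlation 0; a Q2 intercept ≤ 0 passes, as does an original Q2
    strictly above every permuted Q2.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)

    original = evaluate_fit(Xa, y, n_ortho=n_ortho, n_folds=n_folds)
    ynum = np.where(y == np.unique(y)[1], 1.0, -1.0)

    r2s = np.empty(n_perm)
    q2s = np.empty(n_perm)
    corrs = np.empty(n_perm)
    for i in range(n_perm):
        while True:
            yp = rng.permutation(ynum)
            if np.unique(yp).size == 2:  # always true for a two-class vector
                break
        fit = evaluate_fit(Xa, yp, n_ortho=n_ortho, n_folds=n_folds)
        r2s[i] = fit.r2y
        q2s[i] = fit.q2
        corrs[i] = abs(float(np.corrcoef(yp, ynum)[0, 1]))

    xs = np.append(corrs, 1.0)
    q2_icpt = _intercept(xs, np.append(q2s, original.q2))
    r2_icpt = _intercept(xs, np.append(r2s, original.r2y))
    crosses = q2_icpt <= 0.0
    none_exceed = bool(np.all(q2s < original.q2))  # tie counts as exceeding
    return PermutationReport(
        n_permutations=n_perm,
        permuted_r2=r2s,
        permuted_q2=q2s,
        label_correlations=corrs,
        original_r2=original.r2y,
        original_q2=original.q2,
        r2_intercept=r2_icpt,
        q2_intercept=q2_icpt,
        q2_line_crosses_zero=crosses,
        no_perm_q2_exceeds_original=none_exceed,
        seed=seed,
    )


def cv_anova(fit: ModelFit, model_dof: float | None = None) -> CvAnovaResult:
    """F-test p-value from the cross-validated residuals of a fitted model.

    ``model_dof`` defaults to the number of fitted components (predictive +
    orthogonal).  A PRESS above SS (negative numerator) clamps to F = 0,
    p = 1.
    """
    if model_dof is None:
        model_dof = fit.n_components
    n = int(fit.fold_assignment.size)
    df1 = float(model_dof)
    df2 = float(n - model_dof - 1)
    if df2 <= 0:
        raise ValueError("nonpositive residual degrees of freedom")
    if fit.ss_total <= 0 or fit.press < 0:
        raise ValueError("need positive SS_total and nonnegative PRESS")
    num = fit.ss_total - fit.press
    if num <= 0:
        return CvAnovaResult(0.0, df1, df2, 1.0)
    f = (num / df1) / (fit.press / df2)
    p = float(stats.f.sf(f, df1, df2))
    return CvAnovaResult(float(f), df1, df2, p)


def assess_model(
    fit: ModelFit | None = None,
    perm: PermutationReport | bool | None = None,
    anova: CvAnovaResult | float | None = None,
    *,
    r2: float | None = None,
    q2: float | None = None,
    r2x_cum: float = float("nan"),
    model_name: str = "",
    max_r2_minus_q2: float = 0.3,
    alpha: float = 0.05,
) -> ModelVerdict:
    """Combine fit, permutation and CV-ANOVA evidence into a verdict.

    ``valid`` requires the permutation test to pass and R2 − Q2 ≤ 0.3
    (a larger gap flags overfitting); ``significant`` additionally requires
    the CV-ANOVA p-value below ``alpha``.  Accepts either the full result
    objects or bare numbers (``perm`` as a bool, ``anova`` as a p-value,
    ``r2``/``q2`` overriding ``fit``), so published summary rows can be
    re-assessed directly.
    """
    if fit is not None:
        r2 = fit.r2y if r2 is None else r2
        q2 = fit.q2 if q2 is None else q2
        r2x_cum = fit.r2x_cum if np.isnan(r2x_cum) else r2x_cum
    if r2 is None or q2 is None:
        raise ValueError("need R2 and Q2, via `fit` or keywords")
    perm_pass = perm.passed if isinstance(perm, PermutationReport) else bool(perm)
    p = anova.p_value if isinstance(anova, CvAnovaResult) else float(anova)
    gap = r2 - q2
    valid = perm_pass and gap <= max_r2_minus_q2
    significant = valid and p < alpha
    return ModelVerdict(
        r2x_cum=r2x_cum,
        r2=r2,
        q2=q2,
        permutation_pass=perm_pass,
        r2_minus_q2=gap,
        valid=valid,
        p_cv_anova=p,
        significant=significant,
        model_name=model_name,
    )
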