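"""PCA and the OPLS-DA engine: orthogonal projections to latent structures.

OPLS-DA splits the variation of a (centred, scaled) data matrix ``X`` into a
single *predictive* component — the direction correlated with the two-class
response ``y`` (between-group variation) — and ``n_ortho`` *orthogonal*
components that capture systematic within-group variation uncorrelated with
``y``.  The decomposition is

    X = t pᵀ + Σₖ tₒₖ pₒₖᵀ + E

with the predictive score ``t`` orthogonal to every ``tₒₖ`` by construction,
so explained-variation bookkeeping (R2X split into predictive and orthogonal
parts) is exact.

The algorithm is the standard orthogonal-projections scheme for a single
response, started deterministically from ``y`` (no random initialisation):

    w ∝ Xᵀy                                   predictive weight (unit norm)
    repeat for each orthogonal component:
        p  = Xᵀt / tᵀt          with t = Xw
        wₒ ∝ p − (wᵀp) w        (unit norm)
        tₒ = X wₒ ;  pₒ = Xᵀtₒ / tₒᵀtₒ
        X ← X − tₒ pₒᵀ
    final predictive component from the deflated X.

Model quality is summarised by R2Y (goodness of fit) and Q2 = 1 − PRESS/SS
(goodness of prediction), where PRESS accumulates squared held-out prediction
error over K-fold cross-validation with the full model refit per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "PcaModel",
    "OplsModel",
    "ModelFit",
    "VipScores",
    "fit_pca",
    "fit_oplsda",
    "evaluate_fit",
    "compute_vip",
    "select_n_ortho",
    "hotelling_outliers",
]


# ---------------------------------------------------------------------------
# PCA (QC assessment)
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    scores: np.ndarray          # (n, k)
    loadings: np.ndarray        # (p, k)
    explained_ratio: np.ndarray  # per component, nonincreasing
    mean: np.ndarray

    @property
    def r2x_cum(self) -> float:
        return float(self.explained_ratio.sum())


def fit_pca(values, n_components: int) -> PcaModel:
    """Principal components of a feature matrix (used to check that pooled-QC
    injections cluster tightly relative to biological samples).

    Requires a complete matrix; ``n_components`` must not exceed its rank.
    """
    X = np.asarray(values, dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete matrix; impute missing values first")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PcaModel(scores, pca.components_.T, pca.explained_variance_ratio_, pca.mean_)


def hotelling_outliers(scores: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Flag samples outside the (1−alpha) Hotelling T² ellipse of a score
    matrix.  An optional, clearly-labelled convention for outlier screening —
    not a substitute for inspecting the score plot."""
    t = np.asarray(scores, dtype=float)
    n, k = t.shape
    var = t.var(axis=0, ddof=1)
    t2 = ((t - t.mean(axis=0)) ** 2 / var).sum(axis=1)
    crit = k * (n - 1) / (n - k) * stats.f.ppf(1 - alpha, k, n - k)
    return t2 > crit


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

def _encode_classes(y) -> tuple[np.ndarray, tuple]:
    """Map a two-class vector (labels or numbers) to ±1, lower class → −1."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(
            f"OPLS-DA here is strictly two-class (pairwise models); got {classes.size}"
        )
    ynum = np.where(y == classes[1], 1.0, -1.0)
    if min((ynum == 1).sum(), (ynum == -1).sum()) < 2:
        raise ValueError("each class needs at least two samples")
    return ynum, (classes[0], classes[1])


@dataclass
class OplsModel:
    """Fitted OPLS-DA decomposition (one predictive + ``n_ortho`` orthogonal
    components), with training centres retained for prediction."""

    w: np.ndarray                # predictive weight, unit norm (p,)
    p: np.ndarray                # predictive loading (p,)
    t: np.ndarray                # predictive scores t[1] (n,)
    c: float                     # y-loading
    w_ortho: np.ndarray          # (k, p), unit-norm rows
    p_ortho: np.ndarray          # (k, p)
    t_ortho: np.ndarray          # (k, n), scores to[k]
    x_mean: np.ndarray
    y_mean: float
    ss_x: float                  # total SS of centred X
    ss_y: float                  # total SS of centred y
    r2y: float
    class_labels: tuple | None = None
    feature_ids: pd.Index | None = None

    @property
    def n_ortho(self) -> int:
        return self.w_ortho.shape[0]

    @property
    def n_components(self) -> int:
        return 1 + self.n_ortho

    @property
    def r2x_pred(self) -> float:
        return float(self.t @ self.t * (self.p @ self.p) / self.ss_x)

    @property
    def r2x_ortho(self) -> np.ndarray:
        return np.array(
            [
                self.t_ortho[k] @ self.t_ortho[k] * (self.p_ortho[k] @ self.p_ortho[k])
                / self.ss_x
                for k in range(self.n_ortho)
            ]
        )

    @property
    def r2x_cum(self) -> float:
        return self.r2x_pred + float(self.r2x_ortho.sum())

    @property
    def coefficients(self) -> np.ndarray:
        """Regression vector b with ŷ − ȳ = (x − x̄) · b (orthogonal filtering
        folded in), used for jack-knife marker confidence intervals."""
        v = self.w.copy()
        for k in range(self.n_ortho - 1, -1, -1):
            v = v - self.w_ortho[k] * (self.p_ortho[k] @ v)
        return v * self.c

    def transform(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Predictive and orthogonal scores for new observations."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        t_o = np.empty((self.n_ortho, Xc.shape[0]))
        for k in range(self.n_ortho):
            t_o[k] = Xc @ self.w_ortho[k]
            Xc = Xc - np.outer(t_o[k], self.p_ortho[k])
        return Xc @ self.w, t_o

    def predict(self, X) -> np.ndarray:
        """Continuous class prediction (±1 scale); sign gives the class."""
        t, _ = self.transform(X)
        return t * self.c + self.y_mean

    def to_dict(self) -> dict:
        """JSON-serialisable dump of weights, scores and diagnostics."""
        return {
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "t": self.t.tolist(),
            "c": self.c,
            "w_ortho": self.w_ortho.tolist(),
            "p_ortho": self.p_ortho.tolist(),
            "t_ortho": self.t_ortho.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "ss_x": self.ss_x,
            "ss_y": self.ss_y,
            "r2y": self.r2y,
            "r2x_cum": self.r2x_cum,
            "class_labels": list(self.class_labels) if self.class_labels else None,
            "feature_ids": list(self.feature_ids) if self.feature_ids is not None else None,
        }


def fit_oplsda(X, y, n_ortho: int = 1) -> OplsModel:
    """Fit a two-class OPLS-DA model.

    Parameters
    ----------
    X
        Samples × features matrix (DataFrame or array), already scaled;
        centring is (re)applied internally and is a no-op on centred data.
    y
        Two-class vector: labels or any two distinct numbers.  Encoded as a
        centred ±1 dummy, so the model is invariant to affine recoding.
    n_ortho
        Number of orthogonal components to strip before the predictive one.
    """
    feature_ids = X.columns if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    if np.isnan(Xa).any():
        raise ValueError("OPLS-DA requires a complete matrix; impute missing values first")
    ynum, labels = _encode_classes(y)
    if Xa.shape[0] != ynum.size:
        raise ValueError("X and y disagree on the number of samples")

    x_mean = Xa.mean(axis=0)
    Xc = Xa - x_mean
    y_mean = ynum.mean()
    yc = ynum - y_mean
    ss_x = float((Xc**2).sum())
    ss_y = float((yc**2).sum())

    w = Xc.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate fit: Xᵀy vanishes")
    w = w / norm

    Xd = Xc
    w_os, p_os, t_os = [], [], []
    for _ in range(n_ortho):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12 * max(1.0, np.linalg.norm(p)):
            break  # no orthogonal variation left
        w_o = w_o / n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)

    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    resid = yc - t * c
    r2y = 1.0 - float(resid @ resid) / ss_y

    k = len(w_os)
    return OplsModel(
        w=w,
        p=p,
        t=t,
        c=c,
        w_ortho=np.array(w_os).reshape(k, Xa.shape[1]),
        p_ortho=np.array(p_os).reshape(k, Xa.shape[1]),
        t_ortho=np.array(t_os).reshape(k, Xa.shape[0]),
        x_mean=x_mean,
        y_mean=y_mean,
        ss_x=ss_x,
        ss_y=ss_y,
        r2y=r2y,
        class_labels=labels,
        feature_ids=feature_ids,
    )


# ---------------------------------------------------------------------------
# Cross-validated fit quality
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Fit summary: R2Y on the full fit, Q2 = 1 − PRESS/SS from K-fold CV
    (full refit per fold), plus the per-fold coefficient vectors reused by
    the jack-knife marker filter."""

    r2y: float
    q2: float
    r2x_cum: float
    press: float
    ss_total: float
    n_folds: int
    n_ortho: int
    fold_coefficients: np.ndarray = field(repr=False)  # (K, p)
    fold_assignment: np.ndarray = field(repr=False)    # (n,)

    @property
    def n_components(self) -> int:
        return 1 + self.n_ortho

    @property
    def r2_minus_q2(self) -> float:
        return self.r2y - self.q2


def _fold_assignment(ynum: np.ndarray, n_folds: int) -> np.ndarray:
    """Deterministic round-robin folds by sample order; falls back to
    round-robin within each class when plain assignment would leave a
    training split single-class."""
    n = ynum.size
    folds = np.arange(n) % n_folds
    for f in range(n_folds):
        train = ynum[folds != f]
        if np.unique(train).size < 2:
            break
    else:
        return folds
    folds = np.empty(n, dtype=int)
    for cls in np.unique(ynum):
        idx = np.flatnonzero(ynum == cls)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def evaluate_fit(X, y, n_ortho: int = 1, n_folds: int = 7) -> ModelFit:
    """R2Y, Q2 and per-fold coefficients for an OPLS-DA model.

    PRESS accumulates squared prediction error of held-out samples over
    ``n_folds``-fold cross-validation; the whole model (orthogonal and
    predictive components, centres included) is refit on each training split.
    """
    Xa = np.asarray(X, dtype=float)
    ynum, _ = _encode_classes(y)
    n = ynum.size
    if not 2 <= n_folds <= n:
        raise ValueError("n_folds must lie in [2, n_samples]")

    full = fit_oplsda(Xa, ynum, n_ortho=n_ortho)
    folds = _fold_assignment(ynum, n_folds)
    press = 0.0
    fold_coefs = []
    for f in range(n_folds):
        test = folds == f
        sub = fit_oplsda(Xa[~test], ynum[~test], n_ortho=n_ortho)
        yhat = sub.predict(Xa[test])
        press += float(((ynum[test] - yhat) ** 2).sum())
        fold_coefs.append(sub.coefficients)
    ss_total = float(((ynum - ynum.mean()) ** 2).sum())
    q2 = 1.0 - press / ss_total
    return ModelFit(
        r2y=full.r2y,
        q2=q2,
        r2x_cum=full.r2x_cum,
        press=press,
        ss_total=ss_total,
        n_folds=n_folds,
        n_ortho=n_ortho,
        fold_coefficients=np.vstack(fold_coefs),
        fold_assignment=folds,
    )


def select_n_ortho(X, y, max_ortho: int = 3, n_folds: int = 7) -> int:
    """Smallest number of orthogonal components before cross-validated Q2
    stops improving (stop-when-Q2-drops rule)."""
    best_k, best_q2 = 0, evaluate_fit(X, y, n_ortho=0, n_folds=n_folds).q2
    for k in range(1, max_ortho + 1):
        q2 = evaluate_fit(X, y, n_ortho=k, n_folds=n_folds).q2
        if q2 <= best_q2:
            break
        best_k, best_q2 = k, q2
    return best_k


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

@dataclass
class VipScores:
    """Per-feature variable importance in projection, split into the
    contribution to between-group separation (``vip_pred``) and to
    within-group orthogonal variation (``vip_ortho``).

    Each part is normalised so its mean square over features is 1; a feature
    with VIP total > 1 contributes more than the average feature.  The ratio
    ``vip_pred / vip_ortho`` (``inf`` where ``vip_ortho`` is 0) flags
    features whose importance is dominated by within-group structure:
    ``vip_ortho > vip_pred`` marks a feature as not biomarker-relevant.
    """

    vip_pred: pd.Series
    vip_ortho: pd.Series
    vip_total: pd.Series
    ratio: pd.Series

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vip_pred": self.vip_pred,
                "vip_ortho": self.vip_ortho,
                "vip_total": self.vip_total,
                "vip_ratio": self.ratio,
            }
        )


def compute_vip(model: OplsModel) -> VipScores:
    """VIP decomposition of a fitted OPLS-DA model.

    With normalised weights ``w`` (predictive) and ``wₒₖ`` (orthogonal),

        VIPpred,j  = √(K · w_j²)                       (single predictive comp.)
        VIPortho,j = √(K · Σₖ wₒₖⱼ² SSXₒₖ / Σₖ SSXₒₖ)
        VIPtotal,j = √(K · [w_j² SSXₚ + Σₖ wₒₖⱼ² SSXₒₖ] / [SSXₚ + Σₖ SSXₒₖ])

    where K is the feature count and SSXₚ / SSXₒₖ the X-variation captured
    by the predictive / k-th orthogonal component.  Both parts of the total
    are weighted by explained X-variation so they are commensurable (the
    y-block sum of squares lives on a different scale entirely).  Each block
    is a convex combination of unit-norm squared weight vectors, so
    mean(VIP²) = 1 holds exactly for every part.
    """
    K = model.w.size
    ssx_pred = float(model.t @ model.t) * float(model.p @ model.p)
    w2 = model.w**2

    if model.n_ortho:
        ssx_o = np.array(
            [
                model.t_ortho[k] @ model.t_ortho[k] * (model.p_ortho[k] @ model.p_ortho[k])
                for k in range(model.n_ortho)
            ]
        )
        wo2 = (model.w_ortho**2 * ssx_o[:, None]).sum(axis=0) / ssx_o.sum()
        vip_ortho = np.sqrt(K * wo2)
        total2 = K * (w2 * ssx_pred + wo2 * ssx_o.sum()) / (ssx_pred + ssx_o.sum())
    else:
        vip_ortho = np.zeros(K)
        total2 = K * w2
    vip_pred = np.sqrt(K * w2)
    vip_total = np.sqrt(total2)
    with np.errstate(divide="ignore"):
        ratio = np.where(vip_ortho > 0, vip_pred / np.where(vip_ortho > 0, vip_ortho, 1), np.inf)

    idx = model.feature_ids if model.feature_ids is not None else pd.RangeIndex(K)
    return VipScores(
        pd.Series(vip_pred, index=idx),
        pd.Series(vip_ortho, index=idx),
        pd.Series(vip_total, index=idx),
        pd.Series(ratio, index=idx),
    )
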