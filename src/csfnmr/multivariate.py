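"""PCA with confidence-ellipse outlier exclusion, and two-class PLS-DA.

PCA is a column-centred singular value decomposition; samples whose
first two component scores fall outside the Hotelling T-squared 95%
confidence ellipse are flagged and, in the pipeline, excluded in a
single pass before the model is refit.

PLS-DA is implemented from first principles as PLS1-NIPALS on
column-centred X against a centred +/-1 class coding: per component a,

    w_a = X'y / ||X'y||,  t_a = X w_a,  p_a = X't_a / t_a't_a,
    q_a = y't_a / t_a't_a,  X <- X - t_a p_a'   (y is not deflated)

with prediction yhat = sum_a q_a t_a and class = sign(yhat).  Variable
importance in projection (VIP) summarises each variable's contribution:

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ),
    SS_a = q_a^2 t_a't_a,

whose squares average to 1 over the p variables.  Model performance is
assessed by stratified k-fold cross-validation: Q2 = 1 - PRESS/TSS on
pooled out-of-fold predictions, R2 = 1 - RSS/TSS from the full-data
fit, the component count chosen as the smallest ncomp maximising Q2,
and confusion-matrix summaries (sensitivity, specificity, balanced
accuracy) averaged over seeded repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .errors import (
    DegenerateScoresError,
    InvalidParameterError,
    RankExhaustedError,
    StratificationError,
    ValidationError,
)

_EPS = np.finfo(float).eps


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, list(range(X.shape[1]))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    scores: np.ndarray                       # samples x ncomp
    loadings: np.ndarray                     # variables x ncomp, orthonormal
    explained_variance_fraction: np.ndarray  # full-rank fractions
    mean: np.ndarray
    ncomp: int
    sample_ids: list = field(default_factory=list)


def pca(X, ncomp: int) -> PCAModel:
    """Column-centred SVD principal component analysis."""
    x, _ = _as_matrix(X)
    ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(x)))
    n, p = x.shape
    if not 1 <= ncomp <= min(n - 1, p):
        raise ValidationError(
            f"ncomp must be in [1, {min(n - 1, p)}], got {ncomp}")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for a in range(s.size):
        k = np.argmax(np.abs(vt[a]))
        if vt[a, k] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    frac = s**2 / np.sum(s**2)
    return PCAModel(scores=u[:, :ncomp] * s[:ncomp],
                    loadings=vt[:ncomp].T,
                    explained_variance_fraction=frac,
                    mean=mean, ncomp=ncomp, sample_ids=ids)


def ellipse_outliers(scores: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Hotelling T-squared confidence-ellipse outlier flags on 2-D scores.

    Flags sample i when z_i' S^-1 z_i > 2(n-1)/(n-2) F_{2,n-2}(1-alpha),
    with S the 2x2 score covariance.  ``alpha`` must lie in (0, 0.5].
    """
    if not 0 < alpha <= 0.5:
        raise InvalidParameterError("alpha must lie in (0, 0.5]")
    z = np.asarray(scores, dtype=float)
    if z.ndim != 2 or z.shape[1] != 2:
        raise ValidationError("scores must be samples x 2")
    n = z.shape[0]
    if n < 4:
        raise ValidationError("need >= 4 samples for the confidence ellipse")
    zc = z - z.mean(axis=0)
    s_cov = zc.T @ zc / (n - 1)
    det = np.linalg.det(s_cov)
    if not np.isfinite(det) or det <= _EPS * np.trace(s_cov) ** 2:
        raise DegenerateScoresError("singular score covariance")
    inv = np.linalg.inv(s_cov)
    t2 = np.einsum("ij,jk,ik->i", zc, inv, zc)
    crit = 2 * (n - 1) / (n - 2) * stats.f.ppf(1 - alpha, 2, n - 2)
    return t2 > crit


def pca_outlier_pass(X, ncomp: int = 2, alpha: float = 0.05):
    """Fit PCA, flag 95%-ellipse outliers on PC1/PC2, refit once without them.

    Returns ``(model, outlier_ids)``; the refit uses the same ncomp
    (capped by the reduced sample count).  Single pass by design.
    """
    model = pca(X, max(2, ncomp))
    flags = ellipse_outliers(model.scores[:, :2], alpha=alpha)
    outliers = [sid for sid, f in zip(model.sample_ids, flags) if f]
    if not outliers:
        return model, []
    keep = [sid for sid in model.sample_ids if sid not in set(outliers)]
    Xk = X.loc[keep] if isinstance(X, pd.DataFrame) else np.asarray(X)[~flags]
    refit = pca(Xk, min(max(2, ncomp), len(keep) - 1))
    return refit, outliers


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def encode_labels(y, positive_class: str | None = None):
    """Map two class labels to +/-1 (positive class -> +1).

    Default positive class: first label in alphabetical order.
    """
    y = pd.Series(list(y))
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValidationError(f"PLS-DA needs exactly 2 classes, got {classes}")
    pos = positive_class if positive_class is not None else classes[0]
    if pos not in classes:
        raise ValidationError(f"positive class {pos!r} not among {classes}")
    neg = classes[0] if pos == classes[1] else classes[1]
    coding = {pos: 1.0, neg: -1.0}
    return y.map(coding).to_numpy(dtype=float), coding


@dataclass
class PLSDAModel:
    ncomp: int
    weights: np.ndarray      # p x ncomp, unit-norm columns
    x_scores: np.ndarray     # n x ncomp, mutually orthogonal
    x_loadings: np.ndarray   # p x ncomp
    y_loadings: np.ndarray   # ncomp scalars
    x_mean: np.ndarray
    y_mean: float
    class_coding: dict
    variables: list
    fitted: np.ndarray       # training yhat on the +/-1 scale

    @property
    def r2(self) -> float:
        """Explained variation of the class coding on the training data."""
        y = self.y_numeric
        rss = float(np.sum((y - self.fitted) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - rss / tss

    @property
    def y_numeric(self) -> np.ndarray:
        return self._y_numeric

    def predict(self, X, ncomp: int | None = None) -> np.ndarray:
        """Continuous prediction on the +/-1 scale."""
        comps = self.predict_components(X)
        a = self.ncomp if ncomp is None else ncomp
        return comps[:, min(a, self.ncomp) - 1]

    def predict_components(self, X) -> np.ndarray:
        """Cumulative predictions for 1..ncomp components (n x ncomp)."""
        x, _ = _as_matrix(X)
        xc = x - self.x_mean
        out = np.empty((x.shape[0], self.ncomp))
        yhat = np.zeros(x.shape[0])
        for a in range(self.ncomp):
            t = xc @ self.weights[:, a]
            yhat = yhat + self.y_loadings[a] * t
            xc = xc - np.outer(t, self.x_loadings[:, a])
            out[:, a] = yhat + self.y_mean
        return out

    def classify(self, X, ncomp: int | None = None) -> list:
        """Predicted class labels (sign rule; exact zero -> negative class)."""
        yhat = self.predict(X, ncomp=ncomp)
        inv = {v: k for k, v in self.class_coding.items()}
        return [inv[1.0] if v > 0 else inv[-1.0] for v in yhat]


def _nipals_pls1(xc: np.ndarray, yc: np.ndarray, ncomp: int, strict: bool):
    """Core NIPALS loop; returns (W, T, P, q, achieved)."""
    n, p = xc.shape
    W = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    xa = xc.copy()
    scale = max(float(np.abs(xc).max()), 1.0)
    achieved = 0
    for a in range(ncomp):
        w = xa.T @ yc
        nw = float(np.linalg.norm(w))
        if nw <= 1e-12 * scale * np.sqrt(n):
            if strict:
                raise RankExhaustedError(
                    f"rank exhausted after {a} components; request ncomp <= {a}")
            break
        w /= nw
        t = xa @ w
        tt = float(t @ t)
        if tt <= (1e-12 * scale) ** 2 * n:
            if strict:
                raise RankExhaustedError(
                    f"rank exhausted after {a} components; request ncomp <= {a}")
            break
        W[:, a] = w
        T[:, a] = t
        P[:, a] = xa.T @ t / tt
        q[a] = float(yc @ t) / tt
        xa = xa - np.outer(t, P[:, a])
        achieved = a + 1
    return W[:, :achieved], T[:, :achieved], P[:, :achieved], q[:achieved], achieved


def plsda_fit(X, y, ncomp: int, positive_class: str | None = None,
              strict: bool = True) -> PLSDAModel:
    """Fit a two-class PLS-DA model by PLS1-NIPALS.

    ``y`` holds the two class labels; ``ncomp`` latent components are
    extracted.  With ``strict=False`` the model silently stops at the
    achievable rank instead of raising :class:`RankExhaustedError`.
    """
    x, variables = _as_matrix(X)
    if ncomp < 1:
        raise ValidationError("ncomp must be >= 1")
    y_num, coding = encode_labels(y, positive_class)
    if len(y_num) != x.shape[0]:
        raise ValidationError("X and y length mismatch")
    x_mean = x.mean(axis=0)
    y_mean = float(y_num.mean())
    W, T, P, q, achieved = _nipals_pls1(x - x_mean, y_num - y_mean, ncomp,
                                        strict=strict)
    fitted = T @ q + y_mean
    model = PLSDAModel(ncomp=achieved, weights=W, x_scores=T, x_loadings=P,
                       y_loadings=q, x_mean=x_mean, y_mean=y_mean,
                       class_coding=coding, variables=variables, fitted=fitted)
    model._y_numeric = y_num
    return model


@dataclass
class VIPVector:
    """Per-variable importance-in-projection scores (mean square = 1)."""

    scores: pd.Series           # index: variable names, VIP >= 0
    threshold: float = 1.0

    @property
    def above_threshold(self) -> list:
        return list(self.scores.index[self.scores > self.threshold])

    @property
    def ranked(self) -> pd.Series:
        return self.scores.sort_values(ascending=False)

    def to_csv(self, path) -> None:
        df = self.ranked.rename_axis("metabolite").reset_index(name="vip")
        df["above_threshold"] = df["vip"] > self.threshold
        with open(path, "w") as fh:
            fh.write("# csfnmr VIP scores; dialect: csv\n")
            df.to_csv(fh, index=False)


def vip(model: PLSDAModel, threshold: float = 1.0) -> VIPVector:
    """VIP_j = sqrt(p * sum_a SS_a w_ja^2 / sum_a SS_a), SS_a = q_a^2 t_a't_a."""
    p = model.weights.shape[0]
    tt = np.einsum("ia,ia->a", model.x_scores, model.x_scores)
    ss = model.y_loadings**2 * tt
    denom = float(ss.sum())
    if denom <= 0:
        scores = np.zeros(p)
    else:
        scores = np.sqrt(p * (model.weights**2 @ ss) / denom)
    return VIPVector(pd.Series(scores, index=model.variables, name="vip"),
                     threshold=threshold)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVMetrics:
    """Cross-validated PLS-DA performance summary."""

    r2: np.ndarray            # per ncomp, full-data fit
    q2: np.ndarray            # per ncomp, mean over repeats
    chosen_ncomp: int
    confusion: pd.DataFrame   # per repeat: TP, FP, TN, FN
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    positive_class: str
    q2_per_repeat: np.ndarray = None  # repeats x ncomp

    def to_json(self, path) -> None:
        import json
        payload = {
            "r2": [float(v) for v in self.r2],
            "q2": [float(v) for v in self.q2],
            "chosen_ncomp": int(self.chosen_ncomp),
            "r2_chosen": float(self.r2[self.chosen_ncomp - 1]),
            "q2_chosen": float(self.q2[self.chosen_ncomp - 1]),
            "confusion_per_repeat": self.confusion.to_dict(orient="records"),
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "balanced_accuracy": float(self.balanced_accuracy),
            "positive_class": self.positive_class,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def confusion_summary(tp: int, fp: int, tn: int, fn: int):
    """Sensitivity, specificity and balanced accuracy from counts."""
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return sens, spec, (sens + spec) / 2.0


def cross_validate(X, y, max_ncomp: int = 8, k: int = 5, repeats: int = 10,
                   seed: int = 0, positive_class: str | None = None) -> CVMetrics:
    """Stratified k-fold cross-validation of a two-class PLS-DA model.

    Per component count, Q2 = 1 - PRESS/TSS over pooled out-of-fold
    predictions (averaged over repeats) and R2 from the full-data fit.
    The component count is the smallest ncomp attaining the maximal Q2;
    out-of-fold class predictions at that ncomp form one confusion
    matrix per repeat, and sensitivity / specificity / balanced accuracy
    are averaged over repeats.
    """
    x, _ = _as_matrix(X)
    y = pd.Series(list(y))
    if k < 2:
        raise ValidationError("k must be >= 2")
    y_num, coding = encode_labels(y, positive_class)
    counts = y.value_counts()
    if counts.min() < k:
        raise StratificationError(
            f"class counts {dict(counts)} too small for {k} folds")
    n, p = x.shape
    max_ncomp = min(max_ncomp, p, n - int(np.ceil(n / k)) - 1)
    if max_ncomp < 1:
        raise ValidationError("no admissible component count")
    pos_label = [lbl for lbl, v in coding.items() if v == 1.0][0]

    tss = float(np.sum((y_num - y_num.mean()) ** 2))
    rng = np.random.default_rng(seed)
    q2_rep = np.full((repeats, max_ncomp), np.nan)
    oof_by_rep = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        oof = np.zeros((n, max_ncomp))
        for train, test in skf.split(x, y_num):
            model = plsda_fit(x[train], y.iloc[train], max_ncomp,
                              positive_class=pos_label, strict=False)
            if model.ncomp == 0:          # fully degenerate training fold
                oof[test] = model.y_mean
                continue
            comps = model.predict_components(x[test])
            if model.ncomp < max_ncomp:   # rank-limited fold: carry last
                pad = np.repeat(comps[:, -1:], max_ncomp - model.ncomp, axis=1)
                comps = np.hstack([comps, pad])
            oof[test] = comps
        press = np.sum((y_num[:, None] - oof) ** 2, axis=0)
        q2_rep[rep] = 1.0 - press / tss
        oof_by_rep.append(oof)

    q2 = q2_rep.mean(axis=0)
    chosen = int(np.argmax(q2)) + 1   # first occurrence = smallest ncomp

    full = plsda_fit(x, y, max_ncomp, positive_class=pos_label, strict=False)
    comps_full = full.predict_components(x)
    rss = np.sum((y_num[:, None] - comps_full) ** 2, axis=0)
    r2 = 1.0 - rss / tss
    if full.ncomp < max_ncomp:
        r2 = np.concatenate([r2, np.repeat(r2[-1], max_ncomp - full.ncomp)])

    rows = []
    sens_l, spec_l, ba_l = [], [], []
    for rep in range(repeats):
        pred = oof_by_rep[rep][:, chosen - 1]
        pred_pos = pred > 0
        true_pos = y_num > 0
        tp = int(np.sum(pred_pos & true_pos))
        fp = int(np.sum(pred_pos & ~true_pos))
        tn = int(np.sum(~pred_pos & ~true_pos))
        fn = int(np.sum(~pred_pos & true_pos))
        sens, spec, ba = confusion_summary(tp, fp, tn, fn)
        rows.append({"repeat": rep, "TP": tp, "FP": fp, "TN": tn, "FN": fn})
        sens_l.append(sens)
        spec_l.append(spec)
        ba_l.append(ba)

    return CVMetrics(r2=r2[:max_ncomp], q2=q2, chosen_ncomp=chosen,
                     confusion=pd.DataFrame(rows),
                     sensitivity=float(np.mean(sens_l)),
                     specificity=float(np.mean(spec_l)),
                     balanced_accuracy=float(np.mean(ba_l)),
                     positive_class=pos_label,
                     q2_per_repeat=q2_rep)
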