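"""L1-penalised (multinomial) logistic regression with cross-validated
penalty selection.

The model is the softmax regression

    Pr(G = k | x) = exp(b_0k + b_k' x) / sum_l exp(b_0l + b_l' x)

fitted by minimising the penalised average negative log-likelihood

    -(1/N) sum_i log Pr(g_i | x_i) + lambda * sum_jk |b_jk|

with unpenalised intercepts.  The penalty weight lambda is chosen by
stratified K-fold cross-validation, scoring each grid point by mean
held-out macro one-vs-rest auROC and taking the smallest lambda among the
best scorers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .metrics import roc_curve_auc

logger = logging.getLogger(__name__)

COEF_TOL = 1e-8  # |coef| above this counts as selected


class ModelError(ValueError):
    pass


@dataclass
class SparseLinearModel:
    classes: list                      # ordered K class labels
    coefficients: pd.DataFrame         # features x K
    intercepts: pd.Series              # K
    lam: float
    feature_names: list

    def __post_init__(self) -> None:
        if list(self.coefficients.columns) != list(self.classes):
            raise ModelError("coefficient columns must match classes")
        if list(self.coefficients.index) != list(self.feature_names):
            raise ModelError("coefficient rows must match feature names")

    def to_json(self, path=None) -> str:
        coef = self.coefficients.to_numpy()
        nz = np.nonzero(np.abs(coef) > 0)
        payload = {
            "format_version": 1,
            "classes": [str(c) for c in self.classes],
            "lambda": self.lam,
            "intercepts": self.intercepts.tolist(),
            "n_features": len(self.feature_names),
            "feature_names": list(map(str, self.feature_names)),
            "coef_triplets": [[int(i), int(j), float(coef[i, j])]
                              for i, j in zip(*nz)],
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SparseLinearModel":
        if isinstance(text_or_path, str) and text_or_path.lstrip().startswith("{"):
            payload = json.loads(text_or_path)
        else:
            with open(text_or_path) as fh:
                payload = json.load(fh)
        coef = np.zeros((payload["n_features"], len(payload["classes"])))
        for i, j, v in payload["coef_triplets"]:
            coef[i, j] = v
        features = payload["feature_names"]
        return cls(classes=payload["classes"],
                   coefficients=pd.DataFrame(coef, index=features,
                                             columns=payload["classes"]),
                   intercepts=pd.Series(payload["intercepts"],
                                        index=payload["classes"]),
                   lam=payload["lambda"], feature_names=features)


@dataclass
class CvResult:
    grid: np.ndarray                   # descending lambda values
    scores: np.ndarray                 # mean CV macro OVR auROC per lambda
    chosen: float
    seed: int

    def __post_init__(self) -> None:
        if self.chosen not in self.grid:
            raise ModelError("chosen lambda must come from the grid")


def _objective(X: np.ndarray, Y: np.ndarray, intercepts: np.ndarray,
               coef: np.ndarray, lam: float) -> float:
    """Penalised average negative log-likelihood (the quantity minimised)."""
    scores = intercepts[None, :] + X @ coef
    scores -= scores.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(scores).sum(axis=1))
    ll = (scores[Y.astype(bool)] - log_z).mean()
    return float(-ll + lam * np.abs(coef).sum())


def _softmax(scores: np.ndarray) -> np.ndarray:
    scores = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def _spectral_norm_sq(X: np.ndarray, n_iter: int = 15, seed: int = 0) -> float:
    """Upper estimate of sigma_max(X)^2 by power iteration on X'X.

    The result is inflated by 5% so a slightly unconverged estimate still
    yields a safe (Lipschitz-valid) step size downstream.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=X.shape[1]).astype(X.dtype, copy=False)
    v /= np.linalg.norm(v)
    s = 1.0
    for _ in range(n_iter):
        w = X.T @ (X @ v)
        s = np.linalg.norm(w)
        if s == 0:
            return 1.0
        v = w / s
    return float(s) * 1.05


def _fista_binary_lasso(X: np.ndarray, y1: np.ndarray, lam: float,
                        tol: float, max_iter: int, warm=None,
                        aug_norm_sq: Optional[float] = None
                        ) -> tuple[float, np.ndarray]:
    """Binary logistic lasso by FISTA; returns (intercept, weights).

    Equivalent to the K=2 softmax problem: the symmetric two-column optimum
    (-w/2, +w/2) carries the same probabilities and the same total penalty.
    """
    n, p = X.shape
    dt = X.dtype
    y1 = y1.astype(dt, copy=False)
    if warm is None:
        b = 0.0
        w = np.zeros(p, dtype=dt)
    else:
        b, w = float(warm[0]), warm[1].astype(dt).copy()
    if aug_norm_sq is None:
        aug_norm_sq = _spectral_norm_sq(X) + n
    step = (4.0 * n) / aug_norm_sq            # logistic Hessian bound sigma^2/(4N)

    def _f(b_, w_):
        s = b_ + X @ w_
        # average logistic NLL, numerically stable
        nll = np.logaddexp(0.0, s).mean() - (y1 * s).mean()
        return float(nll + lam * np.abs(w_).sum())

    yb, yw = b, w.copy()
    t = 1.0
    f_prev = np.inf
    for it in range(max_iter):
        s = yb + X @ yw
        pr = 1.0 / (1.0 + np.exp(-s))
        r = (pr - y1) / n
        b_new = yb - step * float(r.sum())
        w_new = yw - step * (X.T @ r)
        if lam > 0:
            w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * lam, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        mom = (t - 1.0) / t_new
        yb = b_new + mom * (b_new - b)
        yw = w_new + mom * (w_new - w)
        b, w, t = b_new, w_new, t_new
        if (it + 1) % 8 == 0 or it == max_iter - 1:
            f = _f(b, w)
            if f > f_prev:
                yb, yw, t = b, w.copy(), 1.0
            elif f_prev - f < tol * max(1.0, abs(f)):
                break
            f_prev = f
    return b, w


def _fista_softmax_lasso(X: np.ndarray, Y: np.ndarray, lam: float,
                         tol: float, max_iter: int, warm=None,
                         aug_norm_sq: Optional[float] = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Minimise the penalised average NLL by accelerated proximal gradient.

    Intercepts are unpenalised.  Step size comes from the softmax Hessian
    bound L = sigma_max([1 X])^2 / (2N); Nesterov momentum restarts on an
    objective increase.  Returns (intercepts, coef).  K=2 dispatches to the
    equivalent single-weight binary form.
    """
    n, p = X.shape
    k = Y.shape[1]
    if k == 2:
        warm_b = None
        if warm is not None:
            warm_b = (warm[0][1] - warm[0][0], warm[1][:, 1] - warm[1][:, 0])
        b, w = _fista_binary_lasso(X, Y[:, 1], lam, tol, max_iter,
                                   warm=warm_b, aug_norm_sq=aug_norm_sq)
        return (np.array([-b / 2.0, b / 2.0]),
                np.column_stack([-w / 2.0, w / 2.0]))
    dt = X.dtype
    Y = Y.astype(dt, copy=False)
    if warm is None:
        b0 = np.zeros(k, dtype=dt)
        B = np.zeros((p, k), dtype=dt)
    else:
        b0, B = warm[0].astype(dt).copy(), warm[1].astype(dt).copy()
    if aug_norm_sq is None:
        # sigma([1 X])^2 <= sigma(X)^2 + n
        aug_norm_sq = _spectral_norm_sq(X) + n
    step = (2.0 * n) / aug_norm_sq

    yb0, yB = b0.copy(), B.copy()
    t = 1.0
    f_prev = np.inf
    check_every = 5
    for it in range(max_iter):
        P = _softmax(yb0[None, :] + X @ yB)
        R = (P - Y) / n                       # gradient of the NLL in the scores
        g0 = R.sum(axis=0)
        G = X.T @ R
        b0_new = yb0 - step * g0
        B_new = yB - step * G
        if lam > 0:                           # soft-threshold the penalised part
            B_new = np.sign(B_new) * np.maximum(np.abs(B_new) - step * lam, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        mom = (t - 1.0) / t_new
        yb0 = b0_new + mom * (b0_new - b0)
        yB = B_new + mom * (B_new - B)
        b0, B, t = b0_new, B_new, t_new
        if (it + 1) % check_every == 0 or it == max_iter - 1:
            f = _objective(X, Y, b0, B, lam)
            if f > f_prev:                    # restart momentum
                yb0, yB, t = b0.copy(), B.copy(), 1.0
            elif f_prev - f < tol * max(1.0, abs(f)):
                break
            f_prev = f
    return b0, B


def fit_lasso_logistic(X: pd.DataFrame, y: Sequence, lam: float,
                       tol: float = 1e-7, max_iter: int = 2000,
                       dtype=np.float64, _warm=None) -> SparseLinearModel:
    """Fit the L1-penalised softmax model at a fixed penalty weight.

    The solver is accelerated proximal gradient (FISTA) on the penalised
    average negative log-likelihood, with unpenalised intercepts; ``tol`` is
    the relative objective-decrease stopping threshold.  ``dtype`` controls
    the working precision (float32 is adequate for prediction-oriented fits
    on large matrices).
    """
    Xv = np.ascontiguousarray(X, dtype=dtype)
    if not np.isfinite(Xv).all():
        raise ModelError("non-finite feature values")
    y = pd.Series(list(y))
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ModelError("need at least two classes")
    if lam < 0:
        raise ModelError("lambda must be >= 0")
    Y = np.column_stack([(y == c).to_numpy(float) for c in classes])
    b0, B = _fista_softmax_lasso(Xv, Y, lam, tol=tol, max_iter=max_iter,
                                 warm=_warm)
    b0 = b0 - b0.mean()                       # fix the softmax shift invariance
    return SparseLinearModel(
        classes=classes,
        coefficients=pd.DataFrame(B.astype(np.float64), index=list(X.columns),
                                  columns=classes),
        intercepts=pd.Series(b0.astype(np.float64), index=classes),
        lam=float(lam), feature_names=list(X.columns))


def predict_proba(model: SparseLinearModel, X: pd.DataFrame) -> pd.DataFrame:
    """Class probabilities by softmax of the linear scores."""
    if list(X.columns) != list(model.feature_names):
        raise ModelError("feature names do not align with the model")
    scores = (model.intercepts.to_numpy()[None, :]
              + np.asarray(X, dtype=float) @ model.coefficients.to_numpy())
    scores -= scores.max(axis=1, keepdims=True)
    exps = np.exp(scores)
    proba = exps / exps.sum(axis=1, keepdims=True)
    return pd.DataFrame(proba, index=X.index, columns=model.classes)


def lambda_max(X: pd.DataFrame, y: Sequence) -> float:
    """Smallest penalty that zeroes every coefficient (KKT bound at the
    intercept-only solution with class-frequency probabilities)."""
    Xv = np.asarray(X, dtype=float)
    y = pd.Series(list(y))
    classes = sorted(y.unique())
    n = len(y)
    Y = np.column_stack([(y == c).to_numpy(float) for c in classes])
    pbar = Y.mean(axis=0)
    grad = Xv.T @ (Y - pbar[None, :]) / n    # features x K
    return float(np.abs(grad).max())


def default_grid(X: pd.DataFrame, y: Sequence, n_points: int = 50,
                 decades: float = 4.0) -> np.ndarray:
    """Descending log-spaced lambda grid from lambda_max down ``decades``."""
    lmax = max(lambda_max(X, y), 1e-12)
    return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_points)


def _macro_ovr_auroc(y_true: pd.Series, proba: pd.DataFrame) -> float:
    aucs = []
    for cls in proba.columns:
        truth = (y_true == cls).astype(int).to_numpy()
        if truth.sum() in (0, truth.size):
            continue
        _, auc = roc_curve_auc(truth, proba[cls].to_numpy())
        aucs.append(auc)
    return float(np.mean(aucs)) if aucs else np.nan


def cv_select_lambda(X: pd.DataFrame, y: Sequence,
                     grid: Optional[Sequence[float]] = None, folds: int = 5,
                     seed: int = 0, tol: float = 1e-5, max_iter: int = 300,
                     balance_k: Optional[int] = None,
                     balance_labels: Optional[pd.Series] = None) -> CvResult:
    """Select lambda by stratified K-fold CV on macro OVR auROC.

    Per fold the grid is fitted as a warm-started path from the largest
    lambda down.  The chosen lambda is the smallest among those attaining
    the maximal mean CV score.  When ``balance_k`` is given, each fold's
    training part is SMOTE-balanced (with that neighbour count) before
    fitting, so class balancing never leaks synthetic points into the
    held-out fold; ``balance_labels`` (default: ``y``) gives the classes to
    balance by — e.g. subtype labels when ``y`` holds coarser group labels —
    so fold fits see the same class geometry as the final fit.
    """
    y = pd.Series(list(y), index=X.index)
    if balance_labels is not None:
        balance_labels = pd.Series(list(balance_labels), index=X.index)
    if grid is None:
        grid = default_grid(X, y)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if grid.size == 0:
        raise ModelError("empty lambda grid")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros((folds, grid.size))
    classes = sorted(y.unique())
    # held-out ranking tolerates reduced precision; fold fits run in float32
    Xv = np.ascontiguousarray(X, dtype=np.float32)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        X_tr, X_te = Xv[tr], Xv[te]
        y_tr, y_te = y.iloc[tr], y.iloc[te]
        if y_te.nunique() < y.nunique() or y_tr.nunique() < y.nunique():
            raise ModelError("a CV fold is missing a class; reduce folds")
        if balance_k is not None:
            from .balancing import smote_balance
            lab = (y_tr if balance_labels is None
                   else balance_labels.iloc[tr])
            bal = smote_balance(
                pd.DataFrame(X_tr, columns=range(X_tr.shape[1])),
                pd.Series(lab.to_numpy()), k=balance_k, seed=seed + f)
            X_tr = np.ascontiguousarray(bal.features, dtype=np.float32)
            if balance_labels is None:
                y_tr = bal.labels
            else:   # each balance class maps to exactly one y group
                to_group = dict(zip(lab, y_tr))
                y_tr = bal.labels.map(to_group)
        Y_tr = np.column_stack([(y_tr == c).to_numpy(np.float32)
                                for c in classes])
        aug_norm_sq = _spectral_norm_sq(X_tr) + X_tr.shape[0]
        warm = None
        for g, lam in enumerate(grid):
            b0, B = _fista_softmax_lasso(X_tr, Y_tr, lam, tol=tol,
                                         max_iter=max_iter, warm=warm,
                                         aug_norm_sq=aug_norm_sq)
            warm = (b0, B)
            proba = pd.DataFrame(_softmax(b0[None, :] + X_te @ B),
                                 columns=classes)
            scores[f, g] = _macro_ovr_auroc(y_te.reset_index(drop=True), proba)
    mean_scores = scores.mean(axis=0)
    best = mean_scores.max()
    # smallest lambda among the argmax set; grid is descending
    chosen = float(min(grid[mean_scores >= best - 1e-12]))
    return CvResult(grid=grid, scores=mean_scores, chosen=chosen, seed=seed)


def selected_features(model: SparseLinearModel, tol: float = COEF_TOL) -> list:
    """Features with any coefficient of magnitude above ``tol``."""
    mask = (model.coefficients.abs() > tol).any(axis=1)
    return list(model.coefficients.index[mask])
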