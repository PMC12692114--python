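"""Calibration/validation splitting, PLS1 regression and evaluation metrics.

PLSR here is the single-response NIPALS algorithm with deflation of X only:
each component extracts a weight vector proportional to X'y, scores t = Xw,
loadings p = X't/(t't), q = y't/(t't), then deflates X ← X − t p'.  The
aggregate regression vector B = W (P'W)⁻¹ q reproduces the fit as
ŷ = ȳ + (x − x̄)·B, and with a full set of components on full-rank tall X the
fit coincides with ordinary least squares — the main correctness oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class ModelError(ValueError):
    """Raised on contract violations in splitting, fitting or scoring."""


# ---------------------------------------------------------------------------
# Kennard–Stone splitting
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    calibration_ids: list[int]
    validation_ids: list[int]


def kennard_stone(X: np.ndarray, n_cal: int) -> DatasetSplit:
    """Deterministic max–min Euclidean sample selection.

    The first two picks are the maximally distant pair; each further pick
    maximises its minimum distance to the already-chosen set.  Ties break
    toward the lowest sample index, which makes the split reproducible.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[0]
    if not 2 <= n_cal <= n - 1:
        raise ModelError(f"n_cal must be in [2, {n - 1}], got {n_cal}")
    sq = (X ** 2).sum(axis=1)
    D = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0))
    # farthest pair, lexicographically smallest on ties
    iu = np.triu_indices(n, k=1)
    flat = D[iu]
    k = int(np.argmax(flat))          # argmax returns the first maximiser
    chosen = [int(iu[0][k]), int(iu[1][k])]
    mind = np.minimum(D[chosen[0]], D[chosen[1]])
    mind[chosen] = -np.inf
    for _ in range(n_cal - 2):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, D[nxt])
        mind[nxt] = -np.inf
    cal = sorted(chosen)
    val = [i for i in range(n) if i not in set(cal)]
    return DatasetSplit(cal, val)


# ---------------------------------------------------------------------------
# PLS1 / NIPALS
# ---------------------------------------------------------------------------

@dataclass
class PLSRModel:
    x_means: np.ndarray
    y_mean: float
    weights: np.ndarray        # (p, a) weight vectors, unit norm
    x_loadings: np.ndarray     # (p, a)
    y_loadings: np.ndarray     # (a,)
    coefficients: np.ndarray   # (p,) centered-form regression vector
    n_components: int
    wavelength_ids: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "x_means": self.x_means.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "n_components": self.n_components,
            "wavelength_ids": list(self.wavelength_ids),
        })

    @classmethod
    def from_json(cls, text: str) -> "PLSRModel":
        d = json.loads(text)
        return cls(
            x_means=np.array(d["x_means"], float),
            y_mean=float(d["y_mean"]),
            weights=np.array(d["weights"], float),
            x_loadings=np.array(d["x_loadings"], float),
            y_loadings=np.array(d["y_loadings"], float),
            coefficients=np.array(d["coefficients"], float),
            n_components=int(d["n_components"]),
            wavelength_ids=list(d["wavelength_ids"]),
        )


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int,
             wavelength_ids: list | None = None) -> PLSRModel:
    """Fit single-response PLSR by NIPALS with X-deflation.

    Extraction stops early (recording the achieved rank) when the weight
    vector norm drops below 1e−12, i.e. when X carries no further covariance
    with y.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ModelError("X and y have different sample counts")
    if np.ptp(y) == 0:
        raise ModelError("y has zero variance")
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise ModelError(f"n_components must be in [1, {max_rank}]")

    x_means = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_means
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    a = 0
    for _ in range(n_components):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        pl = Xc.T @ t / tt
        ql = float(yc @ t / tt)
        W[:, a], P[:, a], q[a] = w, pl, ql
        Xc = Xc - np.outer(t, pl)
        a += 1
    if a == 0:
        raise ModelError("no usable component: X carries no covariance with y")
    W, P, q = W[:, :a], P[:, :a], q[:a]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(x_means, y_mean, W, P, q, coef, a,
                     list(wavelength_ids) if wavelength_ids is not None
                     else list(range(p)))


def predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """ŷ = ȳ + (X − x̄)·B."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.coefficients.size:
        raise ModelError(
            f"X has {X.shape[1]} columns, model expects {model.coefficients.size}")
    return model.y_mean + (X - model.x_means) @ model.coefficients


def scores(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Latent scores T = (X − x̄) W (P'W)⁻¹ (orthogonal on the training set)."""
    Xc = np.atleast_2d(np.asarray(X, float)) - model.x_means
    return Xc @ model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)


# ---------------------------------------------------------------------------
# Cross-validation and metrics
# ---------------------------------------------------------------------------

def venetian_folds(n: int, cv_folds: int) -> list[np.ndarray]:
    """Venetian-blind folds: fold k holds samples k, k+K, k+2K, …"""
    if cv_folds > n:
        raise ModelError(f"cv_folds={cv_folds} exceeds sample count {n}")
    return [np.arange(k, n, cv_folds) for k in range(cv_folds)]


def cv_rmse(X: np.ndarray, y: np.ndarray, n_components: int,
            cv_folds: int = 5) -> float:
    """K-fold (venetian blind) cross-validated RMSE of a PLSR fit."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = X.shape[0]
    press = 0.0
    for test in venetian_folds(n, cv_folds):
        train = np.setdiff1d(np.arange(n), test)
        a = min(n_components, min(train.size - 1, X.shape[1]))
        m = fit_plsr(X[train], y[train], a)
        resid = y[test] - predict(m, X[test])
        press += float(resid @ resid)
    return float(np.sqrt(press / n))


def select_components(X: np.ndarray, y: np.ndarray, max_components: int = 20,
                      cv_folds: int = 5) -> int:
    """Component count minimising venetian-blind CV RMSE; ties → fewest."""
    if max_components < 1:
        raise ModelError("max_components must be >= 1")
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    hi = min(max_components, n - 1 - int(np.ceil(n / cv_folds)), p)
    hi = max(hi, 1)
    best_a, best_rmse = 1, np.inf
    for a in range(1, hi + 1):
        r = cv_rmse(X, y, a, cv_folds)
        if r < best_rmse - 1e-15:
            best_a, best_rmse = a, r
    return best_a


@dataclass
class Metrics:
    r2: float
    rmse: float


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²; RMSE = √(Σ(y−ŷ)²/n)."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ModelError("y_true and y_pred must have equal length >= 2")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ModelError("y_true is constant: R² undefined")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    return Metrics(r2=1.0 - ss_res / ss_tot,
                   rmse=float(np.sqrt(ss_res / y_true.size)))
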