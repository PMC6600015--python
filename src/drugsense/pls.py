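"""Partial least squares regression (NIPALS), single- and multi-response.

PLS builds latent components as linear combinations of the inputs that
maximise covariance with the response, which makes it suitable for the
p ≫ n regime of omics panels where ordinary least squares breaks down.
This module implements the classical NIPALS algorithm with deflation:
deterministic (no random initialisation), with an exact linear-model
representation — prediction is always ``intercept + X·coefficients`` and
reproduces the component-wise prediction to machine precision.

For a single response the NIPALS inner loop converges in one step
(the weight vector is X'y normalised), and the full coefficient *path*
over 1..A components falls out of one deflation pass; nested
cross-validation over the number of components therefore costs a single
fit per fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["PLSModel", "pls_fit", "pls_predict", "pls2_fit", "vip_scores"]

_TOL = 1e-12
_MAX_ITER = 500


@dataclass
class PLSModel:
    """Fitted PLS model.

    Attributes
    ----------
    n_components:
        Number of latent components actually fitted (may be truncated below
        the request when the data rank is exhausted).
    x_weights, x_loadings, x_scores:
        W (p × A), P (p × A), T (n × A) of the NIPALS decomposition, with
        each weight vector normalised to unit length.
    y_loadings:
        Q (m × A); a single response has m = 1.
    coef_path:
        (p × m × A) cumulative regression coefficients: ``coef_path[..., a]``
        is the linear model using components 1..a+1.
    """

    n_components: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    x_scores: np.ndarray
    y_loadings: np.ndarray
    coef_path: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    feature_names: Optional[list[str]] = None

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients of the full model (all fitted components)."""
        coef = self.coef_path[..., self.n_components - 1]
        return coef[:, 0] if coef.shape[1] == 1 else coef

    @property
    def intercept(self) -> np.ndarray:
        """Intercept(s) of the linear model on the training input scale."""
        coef = self.coef_path[..., self.n_components - 1]
        b0 = self.y_mean - self.x_mean @ coef
        return b0[0] if b0.size == 1 else b0

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str) -> None:
        payload = {
            "n_components": int(self.n_components),
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef_path": self.coef_path.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "feature_names": self.feature_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "PLSModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            n_components=payload["n_components"],
            x_weights=np.asarray(payload["x_weights"]),
            x_loadings=np.asarray(payload["x_loadings"]),
            x_scores=np.zeros((0, payload["n_components"])),  # scores are training state
            y_loadings=np.asarray(payload["y_loadings"]),
            coef_path=np.asarray(payload["coef_path"]),
            x_mean=np.asarray(payload["x_mean"]),
            y_mean=np.asarray(payload["y_mean"]),
            feature_names=payload["feature_names"],
        )


def _coef_path_impl(X, y, A):  # pragma: no cover - superseded by the jitted copy
    n, p = X.shape
    xm = np.zeros(p)
    for i in range(n):
        for j in range(p):
            xm[j] += X[i, j]
    for j in range(p):
        xm[j] /= n
    ym = 0.0
    for i in range(n):
        ym += y[i]
    ym /= n
    Xd = np.empty((n, p))
    yc = np.empty(n)
    yss = 0.0
    for i in range(n):
        yc[i] = y[i] - ym
        yss += yc[i] * yc[i]
        for j in range(p):
            Xd[i, j] = X[i, j] - xm[j]
    yscale = np.sqrt(yss) + 1e-300
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    R = np.zeros((p, A))
    B = np.zeros((p, A))
    coef = np.zeros(p)
    t = np.empty(n)
    w = np.empty(p)
    pv = np.empty(p)
    r = np.empty(p)
    nf = 0
    for a in range(A):
        for j in range(p):
            w[j] = 0.0
        for i in range(n):
            yi = yc[i]
            for j in range(p):
                w[j] += Xd[i, j] * yi
        nw = 0.0
        for j in range(p):
            nw += w[j] * w[j]
        nw = np.sqrt(nw)
        if nw <= _TOL * yscale:
            break
        for j in range(p):
            w[j] /= nw
        tt = 0.0
        for i in range(n):
            s = 0.0
            for j in range(p):
                s += Xd[i, j] * w[j]
            t[i] = s
            tt += s * s
        if tt <= _TOL:
            break
        q = 0.0
        for i in range(n):
            q += yc[i] * t[i]
        q /= tt
        for j in range(p):
            pv[j] = 0.0
        for i in range(n):
            ti = t[i]
            for j in range(p):
                pv[j] += Xd[i, j] * ti
        for j in range(p):
            pv[j] /= tt
        for j in range(p):
            r[j] = w[j]
        for b in range(a):
            d = 0.0
            for j in range(p):
                d += P[j, b] * w[j]
            for j in range(p):
                r[j] -= d * R[j, b]
        for j in range(p):
            coef[j] += q * r[j]
            W[j, a] = w[j]
            P[j, a] = pv[j]
            R[j, a] = r[j]
            B[j, a] = coef[j]
        for i in range(n):
            ti = t[i]
            for j in range(p):
                Xd[i, j] -= ti * pv[j]
            yc[i] -= q * ti
        nf = a + 1
    # pad the path: truncations beyond the fitted rank keep the deepest model
    for a in range(nf, A):
        for j in range(p):
            B[j, a] = coef[j]
    return B, xm, ym, nf


try:  # compiled kernel for the nested-CV hot loop; plain Python fallback
    from numba import njit

    _coef_path_fast = njit(cache=True)(_coef_path_impl)
except ImportError:  # pragma: no cover
    def _coef_path_fast(X, y, A):
        m = _nipals(np.ascontiguousarray(X), _as_2d(y), A, warn=False)
        B = np.zeros((X.shape[1], A))
        B[:, : m.n_components] = m.coef_path[:, 0, :]
        B[:, m.n_components :] = m.coef_path[:, 0, -1][:, None]
        return B, m.x_mean, float(m.y_mean[0]), m.n_components


def coef_path_1d(X: np.ndarray, y: np.ndarray, n_components: int):
    """Coefficient path of univariate PLS over 1..n_components components.

    Returns ``(B, x_mean, y_mean, n_fitted)`` where prediction with a
    components is ``(X - x_mean) @ B[:, a-1] + y_mean``; columns beyond the
    fitted rank repeat the deepest model. This is the fast kernel used by
    nested component selection; it computes the same path as
    :func:`pls_fit`.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    return _coef_path_fast(X, y, int(n_components))


def _as_2d(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return y[:, None] if y.ndim == 1 else y


def _nipals_1d(X: np.ndarray, y: np.ndarray, limit: int):
    """Univariate NIPALS fast path (no inner iteration needed).

    Works on pre-centered copies; returns the per-component matrices and
    the cumulative coefficient path. Deflation is performed in place.
    """
    n, p = X.shape
    Xd = X
    yc = y
    y_scale = float(np.sqrt(yc @ yc)) + 1e-300
    W = np.zeros((p, limit))
    P = np.zeros((p, limit))
    T = np.zeros((n, limit))
    Q = np.zeros((1, limit))
    R = np.zeros((p, limit))
    coef_path2 = np.zeros((p, limit))
    coef = np.zeros(p)
    a = 0
    for a in range(limit):
        w = Xd.T @ yc
        nw = float(np.sqrt(w @ w))
        if nw <= _TOL * y_scale:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _TOL:
            break
        p_vec = Xd.T @ t
        p_vec /= tt
        q = float(yc @ t) / tt
        if a == 0:
            r = w
        else:
            r = w - R[:, :a] @ (P[:, :a].T @ w)
        coef = coef + q * r
        W[:, a] = w
        P[:, a] = p_vec
        T[:, a] = t
        Q[0, a] = q
        R[:, a] = r
        coef_path2[:, a] = coef
        Xd -= t[:, None] * p_vec[None, :]
        yc -= q * t
        a += 1
    return W, P, T, Q, R, coef_path2, a


def _nipals(X: np.ndarray, Y: np.ndarray, n_components: int, warn: bool) -> PLSModel:
    n, p = X.shape
    m = Y.shape[1]
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xd = X - x_mean
    Yd = Y - y_mean
    y_scale = np.linalg.norm(Yd) + 1e-300

    limit = min(n_components, n - 1 if n > 1 else 1, p)
    if limit < n_components and warn:
        warnings.warn(
            f"n_components reduced from {n_components} to {limit} (rank limit)",
            stacklevel=3,
        )

    if m == 1:
        W, P, T, Q, R, coef2, n_fitted = _nipals_1d(Xd, Yd[:, 0], limit)
        if n_fitted == 0:
            n_fitted = 1
        W, P, T, Q = W[:, :n_fitted], P[:, :n_fitted], T[:, :n_fitted], Q[:, :n_fitted]
        coef_path = coef2[:, None, :n_fitted]
        return PLSModel(
            n_components=n_fitted,
            x_weights=W,
            x_loadings=P,
            x_scores=T,
            y_loadings=Q,
            coef_path=coef_path,
            x_mean=x_mean,
            y_mean=np.atleast_1d(y_mean),
        )

    W = np.zeros((p, limit))
    P = np.zeros((p, limit))
    T = np.zeros((n, limit))
    Q = np.zeros((m, limit))
    R = np.zeros((p, limit))  # W (P'W)^{-1}, built incrementally
    coef_path = np.zeros((p, m, limit))
    coef = np.zeros((p, m))

    a = 0
    for a in range(limit):
        # iterate on the dominant covariance direction
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))]
        t = np.zeros(n)
        w = np.zeros(p)
        for _ in range(_MAX_ITER):
            w_new = Xd.T @ u
            nw = np.linalg.norm(w_new)
            if nw <= _TOL * y_scale:
                break
            w_new /= nw
            t_new = Xd @ w_new
            tt = t_new @ t_new
            if tt <= _TOL:
                break
            c = Yd.T @ t_new / tt
            u = Yd @ c / (c @ c + 1e-300)
            if np.linalg.norm(t_new - t) <= _TOL * (np.linalg.norm(t_new) + _TOL):
                w, t = w_new, t_new
                break
            w, t = w_new, t_new
        if np.linalg.norm(w) == 0:
            break
        tt = t @ t
        if tt <= _TOL:
            break
        p_vec = Xd.T @ t / tt
        q = Yd.T @ t / tt
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        coef = coef + np.outer(r, q)
        W[:, a], P[:, a], T[:, a], Q[:, a], R[:, a] = w, p_vec, t, q, r
        coef_path[:, :, a] = coef
        Xd = Xd - np.outer(t, p_vec)
        Yd = Yd - np.outer(t, q)
        a += 1

    n_fitted = a
    if n_fitted == 0:
        # degenerate (constant y or X): intercept-only model
        n_fitted = 1
        coef_path = np.zeros((p, m, 1))
        W = np.zeros((p, 1))
        P = np.zeros((p, 1))
        T = np.zeros((n, 1))
        Q = np.zeros((m, 1))
    elif n_fitted < limit:
        if warn:
            warnings.warn(
                f"NIPALS stopped after {n_fitted} components (rank exhausted)",
                stacklevel=3,
            )
        W, P, T, Q = W[:, :n_fitted], P[:, :n_fitted], T[:, :n_fitted], Q[:, :n_fitted]
        coef_path = coef_path[:, :, :n_fitted]

    return PLSModel(
        n_components=n_fitted,
        x_weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=Q,
        coef_path=coef_path,
        x_mean=x_mean,
        y_mean=np.atleast_1d(y_mean),
    )


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    feature_names: Optional[list[str]] = None,
    warn: bool = True,
) -> PLSModel:
    """Fit a single-response PLS model with ``n_components`` latent variables.

    ``X`` is expected standardized (the model still centers internally so
    the intercept is exact); ``y`` is centered internally and left
    unscaled. If ``n_components`` exceeds the data rank the model is
    truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    y2 = _as_2d(y)
    if X.shape[0] != y2.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if np.isnan(X).any() or np.isnan(y2).any():
        raise ValueError("PLS input must not contain missing values")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    model = _nipals(X, y2, n_components, warn)
    model.feature_names = feature_names
    return model


def pls2_fit(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    feature_names: Optional[list[str]] = None,
    warn: bool = True,
) -> PLSModel:
    """Multi-response PLS (PLS2): one shared component set for all outputs."""
    Y = _as_2d(Y)
    return pls_fit(X, Y, n_components, feature_names=feature_names, warn=warn)


def pls_predict(
    model: PLSModel, X_test: np.ndarray, n_components: Optional[int] = None
) -> np.ndarray:
    """Predict responses; linear in ``X_test``.

    ``X_test`` must be on the training input scale (i.e. transformed with
    the training fold's standardizer). ``n_components`` selects a
    truncation of the fitted model (defaults to all fitted components).
    """
    X_test = np.asarray(X_test, dtype=float)
    if X_test.ndim == 1:
        X_test = X_test[None, :]
    p = model.x_weights.shape[0]
    if X_test.shape[1] != p:
        raise ValueError(
            f"feature mismatch: model expects {p} features, got {X_test.shape[1]}"
        )
    a = model.n_components if n_components is None else n_components
    if not (1 <= a <= model.n_components):
        raise ValueError(f"n_components must be in [1, {model.n_components}]")
    coef = model.coef_path[..., a - 1]
    pred = model.y_mean + (X_test - model.x_mean) @ coef
    return pred[:, 0] if pred.shape[1] == 1 else pred


def pls_predict_path(model: PLSModel, X_test: np.ndarray) -> np.ndarray:
    """Predictions for every component truncation at once: (n, m, A)."""
    X_test = np.asarray(X_test, dtype=float)
    Xc = X_test - model.x_mean
    pred = np.einsum("np,pma->nma", Xc, model.coef_path) + model.y_mean[None, :, None]
    return pred


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable Importance in Projection per feature.

    VIP_j = sqrt( p · Σ_a s_a (w_ja)² / Σ_a s_a ) with s_a the variance of
    y explained by component a (q_a²·t_a't_a). The mean of squared VIPs
    over features equals 1 by construction.
    """
    W = model.x_weights
    T = model.x_scores
    Q = model.y_loadings
    if T.shape[0] == 0:
        raise ValueError("VIP requires training scores; model was deserialized without them")
    p, A = W.shape
    ss = (Q**2).sum(axis=0) * (T**2).sum(axis=0)  # (A,)
    total = ss.sum()
    if total <= 0:
        return np.ones(p)
    wnorm2 = W**2 / np.maximum((W**2).sum(axis=0), 1e-300)
    vip = np.sqrt(p * (wnorm2 * ss).sum(axis=1) / total)
    return vip
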