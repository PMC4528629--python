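"""Regularized sparse PCA: alternating penalized least squares.

With the score vector ``u`` fixed, minimizing
``||X - u vt^T||_F^2 + lam * P(vt)`` over the scaled loadings ``vt`` is
a penalized least-squares regression whose unpenalized solution is
``X^T u``.  The algorithm therefore alternates a coefficient-wise
thresholding of ``z = X^T u`` with a re-projection of the samples onto
the current loadings, until the loadings stabilize.  The penalization
strength ``lam`` is chosen over a grid by an information criterion
(GIC by default; BIC available), and subsequent components are fitted
on the deflated residual matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import CenteredMatrix, SparseFit, deflate, rank_one_svd, _fix_sign
from .thresholding import ThresholdSpec, apply_threshold

__all__ = [
    "RspcaConfig",
    "sigma2_hat",
    "lambda_grid",
    "bic",
    "gic",
    "fit_rank_one_penalized",
    "rspca",
]


@dataclass
class RspcaConfig:
    """Settings for the alternating algorithm and its model selection.

    Defaults follow the study conditions: GIC model selection,
    adaptive-lasso exponent ``gamma = 1``, SCAD ``a = 3.7``.
    """

    penalty: str = "lasso"
    lambda_grid_size: int = 50
    criterion: str = "gic"
    max_iter: int = 200
    tol: float = 1e-6
    n_pcs: int = 1
    gamma: float = 1.0
    a: float = 3.7
    alasso_weights: str = "current"  # or "initial"

    def __post_init__(self) -> None:
        if self.lambda_grid_size < 2:
            raise ValueError("lambda grid needs at least 2 points")
        if self.criterion not in ("bic", "gic"):
            raise ValueError("criterion must be 'bic' or 'gic'")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be positive")
        if self.alasso_weights not in ("current", "initial"):
            raise ValueError("alasso_weights must be 'current' or 'initial'")


def sigma2_hat(X: CenteredMatrix, base: SparseFit | None = None) -> float:
    """Error-variance estimate from the unpenalized rank-one residual.

    ``sigma2 = ||X - d1 u1 v1^T||_F^2 / (n p)`` where ``(d1, u1, v1)``
    is the leading singular triplet — the OLS rank-one model.  Returns
    the raw value; an exactly rank-one matrix yields 0 and callers that
    divide by it must apply a floor (see :func:`_safe_sigma2`).
    """
    if base is None:
        base = rank_one_svd(X)
    total = float(np.sum(X.values**2))
    resid = max(total - base.d**2, 0.0)
    return resid / (X.n * X.p)


def _safe_sigma2(X: CenteredMatrix, base: SparseFit | None = None) -> float:
    """``sigma2_hat`` with a machine-epsilon-scaled floor for degenerate input."""
    s2 = sigma2_hat(X, base)
    floor = np.finfo(float).eps * max(1.0, float(np.mean(X.values**2)))
    if s2 < floor:
        warnings.warn(
            "residual variance is numerically zero (rank-one data); "
            "flooring sigma2 at machine epsilon scale",
            stacklevel=2,
        )
        return floor
    return s2


def lambda_grid(X: CenteredMatrix, u0: np.ndarray, size: int = 50) -> np.ndarray:
    """Geometric grid of ``size`` penalties, decreasing from ``lam_max``.

    ``lam_max = max_i |(X^T u0)_i|`` zeroes every coefficient on the
    first thresholding pass; the smallest value, ``0.001 * lam_max``,
    is near-unpenalized.
    """
    if size < 2:
        raise ValueError("grid size must be at least 2")
    lam_max = float(np.max(np.abs(X.values.T @ u0)))
    return np.geomspace(lam_max, 1e-3 * lam_max, size)


def _residual_sq(X: CenteredMatrix, fit: SparseFit) -> float:
    if fit.empty or fit.d == 0:
        return float(np.sum(X.values**2))
    return float(np.sum((X.values - fit.d * np.outer(fit.u, fit.v)) ** 2))


def bic(X: CenteredMatrix, fit: SparseFit, sigma2: float) -> float:
    """Bayesian information criterion for a rank-one sparse fit.

    ``||X - d u v^T||_F^2 / (n p sigma2) + df * log(n p) / (n p)``
    with ``df`` the number of nonzero loadings.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    np_ = X.n * X.p
    return _residual_sq(X, fit) / (np_ * sigma2) + fit.df * np.log(np_) / np_


def gic(X: CenteredMatrix, fit: SparseFit, sigma2: float) -> float:
    """Generalized information criterion; stricter than BIC when p >> n.

    ``||X - d u v^T||_F^2 / (n p sigma2)
    + df * log(log(n p)) * log(p) / (n p)``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    np_ = X.n * X.p
    penalty = fit.df * np.log(np.log(np_)) * np.log(X.p) / np_
    return _residual_sq(X, fit) / (np_ * sigma2) + penalty


_CRITERIA = {"bic": bic, "gic": gic}


def _empty_fit(X: CenteredMatrix, method: str, lam: float | None) -> SparseFit:
    return SparseFit(
        d=0.0,
        u=np.zeros(X.n),
        v=np.zeros(X.p),
        support=np.array([], dtype=int),
        method=method,
        lam=lam,
        empty=True,
    )


def fit_rank_one_penalized(
    X: CenteredMatrix,
    spec: ThresholdSpec,
    u0: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    alasso_weights: str = "current",
) -> SparseFit:
    """Alternating thresholded rank-one fit at a fixed penalty.

    Starting from the score vector ``u0`` (default: the leading
    unpenalized singular triplet), repeat until the loadings change by
    less than ``tol`` (max-norm, after sign alignment):

    1. ``vt = threshold(X^T u)``; if all coefficients vanish, return
       the empty fit;
    2. ``v = vt / ||vt||``;
    3. ``u = X v / ||X v||``.

    Returns unit ``u`` and ``v``, ``d = u^T X v`` and the support.
    """
    A = X.values
    method = {"randomized_lasso": "s4vd"}.get(spec.penalty, f"rspca_{spec.penalty}")
    if spec.penalty == "adaptive_lasso":
        method = "rspca_alasso"
    if u0 is None:
        u0 = rank_one_svd(X).u
    u = np.asarray(u0, dtype=float)
    nrm = np.linalg.norm(u)
    if abs(nrm - 1.0) > 1e-8:
        warnings.warn("u0 is not unit norm; normalizing", stacklevel=2)
        if nrm == 0:
            raise ValueError("u0 must be nonzero")
        u = u / nrm
    z_init = A.T @ u if (spec.penalty == "adaptive_lasso" and alasso_weights == "initial") else None

    v_old: np.ndarray | None = None
    v = np.zeros(X.p)
    for _ in range(max_iter):
        z = A.T @ u
        vt = apply_threshold(z, spec, z_init=z_init)
        nv = np.linalg.norm(vt)
        if nv == 0:
            return _empty_fit(X, method, spec.lam)
        v = vt / nv
        ut = A @ v
        nu = np.linalg.norm(ut)
        if nu == 0:
            return _empty_fit(X, method, spec.lam)
        u = ut / nu
        if v_old is not None:
            s = 1.0 if float(v @ v_old) >= 0 else -1.0
            if float(np.max(np.abs(v - s * v_old))) < tol:
                break
        v_old = v
    u, v = _fix_sign(u, v)
    d = float(u @ A @ v)
    return SparseFit(
        d=d,
        u=u,
        v=v,
        support=np.flatnonzero(v),
        method=method,
        lam=spec.lam,
    )


def rspca(
    X: CenteredMatrix,
    config: RspcaConfig,
    return_paths: bool = False,
):
    """Fit ``config.n_pcs`` sparse components with criterion-selected penalty.

    For each component, every grid penalty is fitted with the full
    alternating algorithm and scored by the configured criterion
    (error variance re-estimated from the current, possibly deflated,
    matrix); the minimizing penalty is kept, ties resolved toward the
    larger (sparser) penalty.  The fitted rank-one approximation is
    subtracted before the next component.

    Returns the list of fits, plus a per-component criterion-path
    DataFrame when ``return_paths`` is set.
    """
    criterion = _CRITERIA[config.criterion]
    fits: list[SparseFit] = []
    paths: list[pd.DataFrame] = []
    current = X
    for _ in range(config.n_pcs):
        base = rank_one_svd(current)
        sigma2 = _safe_sigma2(current, base)
        grid = lambda_grid(current, base.u, config.lambda_grid_size)
        spec0 = ThresholdSpec(
            penalty=config.penalty, lam=0.0, gamma=config.gamma, a=config.a
        )
        best_fit: SparseFit | None = None
        best_val = np.inf
        records = []
        for lam in grid:  # decreasing: strict '<' keeps the sparser tie
            fit = fit_rank_one_penalized(
                current,
                replace(spec0, lam=float(lam)),
                u0=base.u,
                max_iter=config.max_iter,
                tol=config.tol,
                alasso_weights=config.alasso_weights,
            )
            val = criterion(current, fit, sigma2)
            fit.criterion_value = val
            records.append(
                {"lambda": float(lam), "criterion": val, "df": fit.df, "empty": fit.empty}
            )
            if val < best_val:
                best_fit, best_val = fit, val
        assert best_fit is not None
        if best_fit.empty:
            warnings.warn(
                "criterion selected the empty model for this component",
                stacklevel=2,
            )
        fits.append(best_fit)
        paths.append(pd.DataFrame.from_records(records))
        current = deflate(current, best_fit)
    if return_paths:
        return fits, paths
    return fits
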