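"""Coefficient-wise penalized estimators for the alternating algorithm.

Each operator maps the unpenalized regression coefficients
``z = X^T u`` to a (possibly sparse) penalized estimate, elementwise.
All four operators shrink toward zero, never flip signs, reduce to the
identity at ``lambda = 0``, and are monotone non-decreasing in ``z``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdSpec",
    "soft_threshold",
    "adaptive_soft_threshold",
    "scad_threshold",
    "randomized_soft_threshold",
    "apply_threshold",
]

PENALTIES = ("lasso", "adaptive_lasso", "scad", "randomized_lasso")


@dataclass
class ThresholdSpec:
    """Which penalty to apply, and its tuning parameters.

    Parameters
    ----------
    penalty : str
        One of ``lasso``, ``adaptive_lasso``, ``scad``,
        ``randomized_lasso``.
    lam : float
        Penalization strength ``lambda >= 0``.
    gamma : float
        Adaptive-lasso weight exponent (``w_i = 1/|z_i|^gamma``);
        typical values lie in ``(0, 2]``.
    a : float
        SCAD shape parameter, ``a > 2``; 3.7 is the standard choice.
    kappa : float
        Randomized-lasso weakness parameter in ``(0, 1]``; per-feature
        penalty weights are drawn uniformly from ``(kappa, 1)``.
    weights : ndarray or None
        A realized weight vector for the randomized lasso (one draw per
        stability-selection subsample).
    """

    penalty: str
    lam: float
    gamma: float = 1.0
    a: float = 3.7
    kappa: float = 0.2
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.penalty not in PENALTIES:
            raise ValueError(
                f"unknown penalty {self.penalty!r}; choose from {PENALTIES}"
            )
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.a <= 2:
            raise ValueError("SCAD parameter a must exceed 2")
        if not (0 < self.kappa <= 1):
            raise ValueError("kappa must lie in (0, 1]")


def soft_threshold(z: np.ndarray, lam: float) -> np.ndarray:
    """Lasso soft-thresholding: ``sign(z) (|z| - lam)_+``."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def adaptive_soft_threshold(
    z: np.ndarray,
    lam: float,
    gamma: float = 1.0,
    z_init: np.ndarray | None = None,
) -> np.ndarray:
    """Adaptive lasso: ``sign(z) (|z| - w_i lam)_+`` with ``w_i = 1/|z_i|^gamma``.

    Weights default to the current coefficients ``z`` (stateless
    operator); pass ``z_init`` to weight by an initial fit instead.
    Coefficients whose weighting coefficient is zero are set to zero
    without evaluating the (infinite) weight.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    z = np.asarray(z, dtype=float)
    zw = z if z_init is None else np.asarray(z_init, dtype=float)
    abs_zw = np.abs(zw)
    nonzero = abs_zw > 0
    out = np.zeros_like(z)
    with np.errstate(divide="ignore"):
        penalty = np.where(nonzero, lam / np.where(nonzero, abs_zw, 1.0) ** gamma, np.inf)
    out[nonzero] = np.sign(z[nonzero]) * np.maximum(
        np.abs(z[nonzero]) - penalty[nonzero], 0.0
    )
    return out


def scad_threshold(z: np.ndarray, lam: float, a: float = 3.7) -> np.ndarray:
    """SCAD thresholding: soft shrinkage near zero, identity for large ``|z|``.

    The penalty is a quadratic spline with knots at ``lam`` and
    ``a*lam``, so large coefficients are not excessively penalized.
    The induced thresholding rule is continuous in ``z``:

    * ``|z| <= 2*lam``      -> ``sign(z) (|z| - lam)_+``
    * ``2*lam < |z| <= a*lam`` -> ``((a-1) z - sign(z) a lam) / (a - 2)``
    * ``|z| > a*lam``       -> ``z`` (unbiased for large signals)
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if a <= 2:
        raise ValueError("SCAD parameter a must exceed 2")
    z = np.asarray(z, dtype=float)
    abs_z = np.abs(z)
    sgn = np.sign(z)
    soft = sgn * np.maximum(abs_z - lam, 0.0)
    middle = ((a - 1.0) * z - sgn * a * lam) / (a - 2.0)
    return np.where(abs_z <= 2.0 * lam, soft, np.where(abs_z <= a * lam, middle, z))


def randomized_soft_threshold(
    z: np.ndarray, lam: float, weights: np.ndarray
) -> np.ndarray:
    """Randomized lasso: ``sign(z) (|z| - lam * w_i)_+`` with ``w_i in (0, 1]``.

    Each coefficient's effective penalty is ``lam * w_i in [kappa*lam, lam]``
    when ``w ~ U(kappa, 1)``; equivalently, an unweighted lasso whose
    penalty is randomized over ``[lam, lam/kappa]``.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or np.any(w > 1):
        raise ValueError("randomized-lasso weights must lie in (0, 1]")
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - lam * w, 0.0)


def apply_threshold(
    z: np.ndarray, spec: ThresholdSpec, z_init: np.ndarray | None = None
) -> np.ndarray:
    """Dispatch to the operator named by ``spec.penalty``."""
    if spec.penalty == "lasso":
        return soft_threshold(z, spec.lam)
    if spec.penalty == "adaptive_lasso":
        return adaptive_soft_threshold(z, spec.lam, spec.gamma, z_init=z_init)
    if spec.penalty == "scad":
        return scad_threshold(z, spec.lam, spec.a)
    if spec.penalty == "randomized_lasso":
        if spec.weights is None:
            raise ValueError("randomized_lasso requires a realized weight vector")
        return randomized_soft_threshold(z, spec.lam, spec.weights)
    raise ValueError(f"unknown penalty {spec.penalty!r}")  # pragma: no cover
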