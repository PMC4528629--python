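"""S4VDPCA: sparse PCA by stability selection and forward selection.

The lasso alone is not model-selection consistent in high dimensions:
irrelevant features correlated with true signal features slip into the
support.  Stability selection attacks this by refitting the randomized
lasso on many half-size subsamples (drawn without replacement) and
recording, per feature, the proportion of subsamples in which it was
selected.  Truly relevant features dominate this ranking.  A classical
forward selection along the ranking, scored by the generalized
information criterion on unpenalized reduced-matrix SVDs, then yields a
sparse component that is both parameter- and model-selection
consistent.

Randomness contract: every stochastic step consumes a single
``numpy.random.Generator`` in a fixed order — per subsample, first the
row indices, then the per-feature penalty weights — so a fixed seed
reproduces the full analysis bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    CenteredMatrix,
    SparseFit,
    center_columns,
    deflate,
    oracle_pca,
    rank_one_svd,
)
from .rspca import _empty_fit, _safe_sigma2, fit_rank_one_penalized, gic
from .thresholding import ThresholdSpec

__all__ = [
    "S4vdConfig",
    "StabilityProfile",
    "draw_subsample",
    "selection_frequencies",
    "count_ties",
    "select_lambda_pointwise",
    "forward_select",
    "s4vdpca",
]


@dataclass
class S4vdConfig:
    """Stability-selection settings.

    ``B = 500`` subsamples and weakness ``kappa = 0.2`` are the study
    defaults; the pilot scan uses a cheaper ``B_pilot`` per candidate
    penalty, and the full ``B`` is spent only at the chosen penalty.
    """

    B: int = 500
    B_pilot: int = 100
    kappa: float = 0.2
    fraction: float = 0.5
    n_candidates: int = 20
    n_pcs: int = 1
    max_iter: int = 200
    tol: float = 1e-6
    k_max: int | None = None
    max_gic_evals: int = 5000

    def __post_init__(self) -> None:
        if self.B < 1 or self.B_pilot < 1:
            raise ValueError("B and B_pilot must be positive")
        if not (0 < self.kappa <= 1):
            raise ValueError("kappa must lie in (0, 1]")
        if not (0 < self.fraction < 1):
            raise ValueError("subsample fraction must lie in (0, 1)")
        if self.n_candidates < 1:
            raise ValueError("need at least one candidate penalty")


@dataclass
class StabilityProfile:
    """Per-feature selection probabilities at the chosen penalty.

    ``tie_counts[j]`` is ``p`` minus the number of distinct probability
    values observed at candidate ``j`` during the pilot scan; the
    chosen ``lambda_star`` minimizes it.
    """

    probabilities: np.ndarray
    lambda_star: float
    lambda_candidates: np.ndarray
    tie_counts: np.ndarray
    n_subsamples: int
    kappa: float
    subsample_size: int


def draw_subsample(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """``floor(fraction * n)`` distinct sample indices, without replacement."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    size = int(np.floor(fraction * n))
    if size < 2:
        raise ValueError(f"subsample of size {size} is too small (need >= 2)")
    return np.sort(rng.choice(n, size=size, replace=False))


def _subsample_fit(
    X: CenteredMatrix,
    lam: float,
    kappa: float,
    fraction: float,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> SparseFit:
    """One stability-selection iteration: subsample, re-center, randomized fit."""
    rows = draw_subsample(X.n, fraction, rng)
    w = rng.uniform(kappa, 1.0, size=X.p)
    Xb = center_columns(X.values[rows])  # subsampling breaks centering
    spec = ThresholdSpec(
        penalty="randomized_lasso", lam=lam, kappa=kappa, weights=w
    )
    return fit_rank_one_penalized(Xb, spec, max_iter=max_iter, tol=tol)


def selection_frequencies(
    X: CenteredMatrix,
    lam: float,
    kappa: float,
    B: int,
    fraction: float,
    rng: np.random.Generator,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> np.ndarray:
    """Per-feature selection probabilities at a fixed penalty.

    For each of ``B`` subsamples the randomized lasso is run through the
    full alternating algorithm, and the proportion of subsamples whose
    support includes each feature is returned (multiples of ``1/B``).
    Empty fits contribute an empty support.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    counts = np.zeros(X.p)
    for _ in range(B):
        fit = _subsample_fit(X, lam, kappa, fraction, rng, max_iter, tol)
        if not fit.empty:
            counts[fit.support] += 1
    return counts / B


def count_ties(probabilities: np.ndarray) -> int:
    """Number of tied selection probabilities: ``p`` minus #distinct values."""
    probabilities = np.asarray(probabilities)
    return int(probabilities.size - np.unique(probabilities).size)


def select_lambda_pointwise(
    X: CenteredMatrix,
    candidates: np.ndarray,
    kappa: float,
    B_pilot: int,
    fraction: float,
    rng: np.random.Generator,
    B_full: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[float, StabilityProfile]:
    """Point-wise penalty control: pick the candidate with fewest ties.

    Selection probabilities are estimated with ``B_pilot`` subsamples at
    every candidate; the candidate minimizing the tie count wins (ties
    between candidates resolved toward the larger penalty), and its
    profile is re-estimated with ``B_full`` subsamples.
    """
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size == 0:
        raise ValueError("candidate grid must be non-empty")
    order = np.argsort(-candidates)  # scan decreasing so '<' favors larger lambda
    tie_counts = np.empty(candidates.size, dtype=int)
    best_idx = None
    best_ties = np.inf
    for idx in order:
        probs = selection_frequencies(
            X, float(candidates[idx]), kappa, B_pilot, fraction, rng, max_iter, tol
        )
        tie_counts[idx] = count_ties(probs)
        if tie_counts[idx] < best_ties:
            best_idx, best_ties = idx, tie_counts[idx]
    lambda_star = float(candidates[best_idx])
    B_full = B_pilot if B_full is None else B_full
    probabilities = selection_frequencies(
        X, lambda_star, kappa, B_full, fraction, rng, max_iter, tol
    )
    profile = StabilityProfile(
        probabilities=probabilities,
        lambda_star=lambda_star,
        lambda_candidates=candidates,
        tie_counts=tie_counts,
        n_subsamples=B_full,
        kappa=kappa,
        subsample_size=int(np.floor(fraction * X.n)),
    )
    return lambda_star, profile


def forward_select(
    X: CenteredMatrix,
    probabilities: np.ndarray,
    k_max: int | None = None,
    sigma2: float | None = None,
    max_evals: int = 5000,
) -> SparseFit:
    """GIC forward selection along the selection-probability ranking.

    Features are ordered by probability (descending; ties broken by the
    magnitude of the unpenalized full-data coefficient ``|X^T u1|``,
    then by index).  For each prefix of the ranking an unpenalized SVD
    restricted to those columns is scored by the GIC; the minimizing
    prefix is returned (ties toward the smaller model).  ``k_max``
    defaults to the number of features with positive probability,
    capped at ``max_evals`` criterion evaluations.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.shape[0] != X.p:
        raise ValueError("probability vector length must equal p")
    base = rank_one_svd(X)
    if sigma2 is None:
        sigma2 = _safe_sigma2(X, base)
    n_positive = int(np.count_nonzero(probabilities > 0))
    if n_positive == 0:
        warnings.warn(
            "all selection probabilities are zero; returning empty fit",
            stacklevel=2,
        )
        return _empty_fit(X, "s4vd", None)
    if k_max is None:
        k_max = n_positive
    k_max = int(min(k_max, X.p, max_evals))
    if k_max < 1:
        raise ValueError("k_max must be at least 1")

    score = np.abs(X.values.T @ base.u)
    # lexsort: last key dominates -> probability desc, then |X^T u| desc, then index
    order = np.lexsort((np.arange(X.p), -score, -probabilities))

    best_fit: SparseFit | None = None
    best_val = np.inf
    for k in range(1, k_max + 1):
        # unpenalized SVD on the top-k columns, embedded in p dimensions
        fit = oracle_pca(X, order[:k])
        val = gic(X, fit, sigma2)
        fit.criterion_value = val
        if val < best_val:  # strict '<': ties keep the smaller model
            best_fit, best_val = fit, val
    assert best_fit is not None
    best_fit.method = "s4vd"
    return best_fit


def s4vdpca(
    X: CenteredMatrix,
    config: S4vdConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[SparseFit], list[StabilityProfile]]:
    """End-to-end S4VDPCA for ``config.n_pcs`` components.

    Per component: build a candidate penalty grid (geometric, spanning
    the upper half of the full-data penalty range on a log scale),
    choose the penalty by tie minimization, estimate the stability
    profile at the full ``B``, run GIC forward selection, and deflate.

    Returns the fitted components and their stability profiles.
    """
    if config is None:
        config = S4vdConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fits: list[SparseFit] = []
    profiles: list[StabilityProfile] = []
    current = X
    for _ in range(config.n_pcs):
        base = rank_one_svd(current)
        lam_max = float(np.max(np.abs(current.values.T @ base.u)))
        # upper half of the full grid's three log-decades: [10^-1.5, 1] * lam_max
        candidates = np.geomspace(lam_max, 10**-1.5 * lam_max, config.n_candidates)
        lambda_star, profile = select_lambda_pointwise(
            current,
            candidates,
            config.kappa,
            config.B_pilot,
            config.fraction,
            rng,
            B_full=config.B,
            max_iter=config.max_iter,
            tol=config.tol,
        )
        sigma2 = _safe_sigma2(current, base)
        fit = forward_select(
            current,
            profile.probabilities,
            k_max=config.k_max,
            sigma2=sigma2,
            max_evals=config.max_gic_evals,
        )
        fit.lam = lambda_star
        fits.append(fit)
        profiles.append(profile)
        current = deflate(current, fit)
    return fits, profiles
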