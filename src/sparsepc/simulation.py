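"""Spiked-covariance simulator and benchmark grid.

The single-spike model plants one dominant sparse eigenvector in an
otherwise isotropic covariance:

    Sigma = (d - 1) v v^T + I_p,   d = p^alpha,

where ``alpha >= 0`` (spike index) sets the dominance of the leading
eigenvalue and ``beta in [0, 1]`` (sparsity index) sets the support
size ``floor(p^beta)`` of the true loadings vector ``v``, whose
nonzero entries are all equal to ``1/sqrt(floor(p^beta))`` so that
``||v|| = 1``.  Data are ``n`` i.i.d. draws from ``N(0, Sigma)``.

Sampling never materializes the ``p x p`` covariance: with ``E`` an
``n x p`` standard-normal matrix and ``z`` a standard-normal
``n``-vector,

    X = E + sqrt(d - 1) * z v^T

has covariance exactly ``Sigma``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CenteredMatrix, center_columns, oracle_pca, rank_one_svd
from .evaluation import score_fit
from .rspca import RspcaConfig, rspca
from .s4vd import S4vdConfig, s4vdpca

__all__ = ["SpikeModel", "make_spike_model", "sample_data", "run_grid", "METHODS"]

logger = logging.getLogger(__name__)

METHODS = ("pca", "oracle", "rspca_lasso", "rspca_alasso", "rspca_scad", "s4vd")


@dataclass
class SpikeModel:
    """Ground truth for one simulation cell."""

    p: int
    alpha: float
    beta: float
    d: float
    v_true: np.ndarray
    support_true: np.ndarray


def make_spike_model(
    p: int,
    alpha: float,
    beta: float,
    support_placement: str = "first",
    rng: np.random.Generator | None = None,
) -> SpikeModel:
    """Construct the planted eigenpair ``(d, v)``.

    ``support_placement='first'`` puts the ``floor(p^beta)`` nonzero
    loadings on the leading indices (the estimators are
    permutation-equivariant, so placement is immaterial);
    ``'random'`` draws the support with the supplied ``rng``.
    """
    if p < 2:
        raise ValueError("p must be at least 2")
    if alpha < 0:
        raise ValueError("spike index alpha must be nonnegative")
    if not (0 <= beta <= 1):
        raise ValueError("sparsity index beta must lie in [0, 1]")
    m = int(np.floor(p**beta))
    if m < 1:
        raise ValueError("floor(p^beta) must be at least 1")
    if support_placement == "first":
        support = np.arange(m)
    elif support_placement == "random":
        if rng is None:
            raise ValueError("random placement requires an rng")
        support = np.sort(rng.choice(p, size=m, replace=False))
    else:
        raise ValueError("support_placement must be 'first' or 'random'")
    v = np.zeros(p)
    v[support] = 1.0 / np.sqrt(m)
    return SpikeModel(
        p=p, alpha=alpha, beta=beta, d=float(p**alpha), v_true=v, support_true=support
    )


def sample_data(model: SpikeModel, n: int, rng: np.random.Generator) -> CenteredMatrix:
    """Draw ``n`` samples from ``N(0, Sigma)`` and column-center them.

    RNG order: the ``n x p`` noise matrix first, then the ``n`` spike
    scores.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    E = rng.standard_normal((n, model.p))
    z = rng.standard_normal(n)
    X = E + np.sqrt(max(model.d - 1.0, 0.0)) * np.outer(z, model.v_true)
    return center_columns(X)


def _fit_method(
    name: str,
    X: CenteredMatrix,
    model: SpikeModel,
    method_seed: np.random.SeedSequence,
    rspca_kwargs: dict | None,
    s4vd_config: S4vdConfig | None,
):
    if name == "pca":
        return rank_one_svd(X)
    if name == "oracle":
        return oracle_pca(X, model.support_true)
    if name in ("rspca_lasso", "rspca_alasso", "rspca_scad"):
        penalty = {
            "rspca_lasso": "lasso",
            "rspca_alasso": "adaptive_lasso",
            "rspca_scad": "scad",
        }[name]
        config = RspcaConfig(penalty=penalty, **(rspca_kwargs or {}))
        return rspca(X, config)[0]
    if name == "s4vd":
        fits, _ = s4vdpca(
            X, s4vd_config or S4vdConfig(), rng=np.random.default_rng(method_seed)
        )
        return fits[0]
    raise ValueError(f"unknown method {name!r}; choose from {METHODS}")


def run_grid(
    alphas,
    betas,
    methods,
    n: int = 50,
    p: int = 300,
    nsim: int = 20,
    seed: int = 0,
    rspca_kwargs: dict | None = None,
    s4vd_config: S4vdConfig | None = None,
) -> pd.DataFrame:
    """Benchmark every method on every ``(alpha, beta)`` cell.

    Each replicate draws its data from a child seed derived from the
    master ``seed`` and the cell coordinates
    (``SeedSequence(seed, spawn_key=(i_alpha, i_beta, rep))``), so the
    table is reproducible and methods are compared on identical
    (paired) matrices.  A method failure on one replicate is recorded
    as missing values, not raised.

    Returns one row per (alpha, beta, method, replicate) with the
    angle to the true eigenvector (degrees), FDR, TPR and support size.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    rows = []
    for ia, alpha in enumerate(alphas):
        for ib, beta in enumerate(betas):
            model = make_spike_model(p, float(alpha), float(beta))
            for rep in range(nsim):
                data_rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(ia, ib, rep))
                )
                X = sample_data(model, n, data_rng)
                for im, name in enumerate(methods):
                    method_seed = np.random.SeedSequence(
                        seed, spawn_key=(ia, ib, rep, 1000 + im)
                    )
                    try:
                        fit = _fit_method(
                            name, X, model, method_seed, rspca_kwargs, s4vd_config
                        )
                        angle, fdr_val, tpr_val, size = score_fit(fit, model)
                    except Exception:
                        logger.warning(
                            "method %s failed at alpha=%s beta=%s rep=%d",
                            name, alpha, beta, rep, exc_info=True,
                        )
                        angle = fdr_val = tpr_val = np.nan
                        size = np.nan
                    rows.append(
                        {
                            "alpha": float(alpha),
                            "beta": float(beta),
                            "method": name,
                            "replicate": rep,
                            "angle_deg": angle,
                            "fdr": fdr_val,
                            "tpr": tpr_val,
                            "support_size": size,
                        }
                    )
    return pd.DataFrame.from_records(rows)
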