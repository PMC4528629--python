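"""Shared linear-algebra substrate for sparse PCA.

Centering, rank-one SVD fitting, deflation, the oracle PCA baseline and
score projection.  Conventions used throughout the package:

* data matrices are ``n`` samples (rows) by ``p`` features (columns);
* ``u`` is a unit-norm score vector of length ``n``;
* ``v`` is a unit-norm loadings vector of length ``p``;
* the sign of every fitted component is fixed by forcing the
  largest-magnitude loading positive (ties broken by lowest index), so
  repeated fits on identical input are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CenteredMatrix",
    "SparseFit",
    "center_columns",
    "rank_one_svd",
    "deflate",
    "oracle_pca",
    "project_scores",
]

#: column means must vanish to this tolerance after centering
CENTER_TOL = 1e-10


@dataclass
class CenteredMatrix:
    """An ``n x p`` data matrix with feature/sample identifiers.

    ``centered`` records whether the columns have been mean-centered;
    the fitting routines require it.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("data matrix must be two-dimensional")
        n, p = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got n={n}")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if len(self.feature_ids) != p:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for p={p} columns"
            )
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for n={n} rows"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class SparseFit:
    """One rank-one component: ``X ~ d * u @ v.T``.

    ``support`` is exactly the set of indices with nonzero loading.
    An *empty* fit (the penalty zeroed every coefficient) carries
    ``d = 0``, all-zero ``u``/``v`` and ``empty=True``.
    """

    d: float
    u: np.ndarray
    v: np.ndarray
    support: np.ndarray
    method: str
    lam: float | None = None
    criterion_value: float | None = None
    empty: bool = False

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.support = np.asarray(self.support, dtype=int)

    @property
    def df(self) -> int:
        """Degree of sparsity: the number of nonzero loadings."""
        return int(self.support.size)


def _make_ids(prefix: str, count: int) -> list[str]:
    width = max(1, len(str(count - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(count)]


def center_columns(
    raw: np.ndarray,
    feature_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> CenteredMatrix:
    """Subtract the column means; idempotent on already-centered input.

    Raises
    ------
    ValueError
        If any entry is non-finite; the message names the offending
        row and column.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a two-dimensional matrix")
    bad = ~np.isfinite(arr)
    if bad.any():
        j, i = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite entry at row {j}, column {i}: {arr[j, i]!r}"
        )
    centered = arr - arr.mean(axis=0, keepdims=True)
    n, p = centered.shape
    return CenteredMatrix(
        values=centered,
        feature_ids=list(feature_ids) if feature_ids is not None else _make_ids("f", p),
        sample_ids=list(sample_ids) if sample_ids is not None else _make_ids("s", n),
        centered=True,
    )


def _fix_sign(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Force the largest-magnitude loading positive (tie -> lowest index)."""
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        return -u, -v
    return u, v


def _require_centered(X: CenteredMatrix) -> None:
    if not X.centered:
        raise ValueError("matrix must be column-centered; call center_columns first")


def rank_one_svd(X: CenteredMatrix) -> SparseFit:
    """Leading singular triplet of ``X`` — the conventional first PC.

    Minimizes ``||X - d u v^T||_F^2`` over all rank-one factorizations.
    An all-zero matrix yields ``d = 0`` with canonical basis vectors
    ``u = e_1``, ``v = e_1`` and a warning.
    """
    _require_centered(X)
    A = X.values
    if not A.any():
        warnings.warn(
            "all-zero matrix: returning d=0 with canonical basis vectors",
            stacklevel=2,
        )
        u = np.zeros(X.n)
        v = np.zeros(X.p)
        u[0] = 1.0
        v[0] = 1.0
        return SparseFit(d=0.0, u=u, v=v, support=np.array([0]), method="pca")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    u, v = _fix_sign(U[:, 0], Vt[0])
    return SparseFit(
        d=float(s[0]),
        u=u,
        v=v,
        support=np.flatnonzero(v),
        method="pca",
    )


def deflate(X: CenteredMatrix, fit: SparseFit) -> CenteredMatrix:
    """Residual matrix ``X - d u v^T`` for fitting subsequent components.

    The sparse fit itself is subtracted (not a re-fitted dense triplet),
    so subsequent components are only approximately orthogonal to the
    first.  Column means are preserved because ``u`` is a normalized
    linear combination of centered columns.
    """
    if fit.u.shape[0] != X.n or fit.v.shape[0] != X.p:
        raise ValueError(
            f"fit dimensions ({fit.u.shape[0]}, {fit.v.shape[0]}) do not "
            f"match matrix ({X.n}, {X.p})"
        )
    residual = X.values - fit.d * np.outer(fit.u, fit.v)
    return CenteredMatrix(
        values=residual,
        feature_ids=list(X.feature_ids),
        sample_ids=list(X.sample_ids),
        centered=X.centered,
    )


def oracle_pca(X: CenteredMatrix, true_support) -> SparseFit:
    """PCA restricted to a known support — the ideal sparse baseline.

    The loadings on ``true_support`` equal the leading right singular
    vector of the column-reduced matrix; all other loadings are zero.
    This is the unpenalized estimator one would use if the truly
    relevant features were known in advance.
    """
    _require_centered(X)
    support = np.unique(np.asarray(true_support, dtype=int))
    if support.size == 0:
        raise ValueError("true_support must be non-empty")
    if support.min() < 0 or support.max() >= X.p:
        raise ValueError(f"support indices must lie in [0, {X.p})")
    reduced = X.values[:, support]
    U, s, Vt = np.linalg.svd(reduced, full_matrices=False)
    v = np.zeros(X.p)
    v[support] = Vt[0]
    u, v = _fix_sign(U[:, 0], v)
    return SparseFit(
        d=float(s[0]),
        u=u,
        v=v,
        support=np.flatnonzero(v),
        method="oracle",
    )


def project_scores(X: CenteredMatrix, fits: list[SparseFit]) -> np.ndarray:
    """Sample scores on each component: column ``k`` is ``X @ v_k``.

    These are the coordinates used for biplots (n x K).
    """
    for k, fit in enumerate(fits):
        if fit.v.shape[0] != X.p:
            raise ValueError(f"fit {k} has p={fit.v.shape[0]}, matrix has p={X.p}")
    return np.column_stack([X.values @ fit.v for fit in fits])
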