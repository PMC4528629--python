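"""Metrics and aggregation for the simulation benchmark.

The angle between the estimated and true loadings vectors,
``arccos |<v_hat, v>|`` in degrees, measures parameter-estimation
consistency; FDR and TPR on the estimated support measure
model-selection consistency.  Grid results are aggregated to medians
per (alpha, beta, method) cell.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import SparseFit

__all__ = [
    "angle_degrees",
    "fdr",
    "tpr",
    "score_fit",
    "classify_consistency",
    "summarize_grid",
]


def angle_degrees(v_hat: np.ndarray, v_true: np.ndarray) -> float:
    """Angle ``arccos |<v_hat, v_true>|`` in degrees, in [0, 90].

    Sign-invariant: ``v`` and ``-v`` span the same direction.  Inputs
    off unit norm by more than 1e-6 are renormalized with a warning;
    zero vectors are an error (empty fits are scored 90 degrees by
    :func:`score_fit`, not here).
    """
    v_hat = np.asarray(v_hat, dtype=float)
    v_true = np.asarray(v_true, dtype=float)
    vectors = []
    for name, v in (("v_hat", v_hat), ("v_true", v_true)):
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise ValueError(f"{name} is the zero vector; angle undefined")
        if abs(nrm - 1.0) > 1e-6:
            warnings.warn(f"{name} is not unit norm; renormalizing", stacklevel=2)
            v = v / nrm
        vectors.append(v)
    inner = float(np.clip(np.abs(vectors[0] @ vectors[1]), 0.0, 1.0))
    return float(np.degrees(np.arccos(inner)))


def fdr(support_hat, support_true) -> float:
    """False discovery rate ``|hat \\ true| / |hat|``; 0 for an empty estimate."""
    hat = set(np.asarray(support_hat, dtype=int).tolist())
    true = set(np.asarray(support_true, dtype=int).tolist())
    if not hat:
        return 0.0
    return len(hat - true) / len(hat)


def tpr(support_hat, support_true) -> float:
    """True positive rate ``|hat & true| / |true|``."""
    hat = set(np.asarray(support_hat, dtype=int).tolist())
    true = set(np.asarray(support_true, dtype=int).tolist())
    if not true:
        raise ValueError("true support must be non-empty")
    return len(hat & true) / len(true)


def score_fit(fit: SparseFit, model) -> tuple[float, float, float, int]:
    """(angle, FDR, TPR, support size) of a fit against the generating truth.

    An empty fit (all loadings zeroed) is scored as angle 90, FDR 0,
    TPR 0, so medians remain well defined in weak-signal regimes where
    sparse fits collapse.
    """
    if fit.empty or fit.support.size == 0:
        return 90.0, 0.0, 0.0, 0
    return (
        angle_degrees(fit.v, model.v_true),
        fdr(fit.support, model.support_true),
        tpr(fit.support, model.support_true),
        int(fit.support.size),
    )


def classify_consistency(median_angles_by_scale) -> str:
    """Finite-sample consistency proxy from median angles at growing p.

    The asymptotic taxonomy — consistent (angle -> 0), marginally
    inconsistent (limit in (0, 90)), strongly inconsistent (limit 90)
    — is not observable at finite scale; as an operational proxy the
    final-scale median is thresholded at the 10- and 45-degree contour
    levels: below 10 -> ``consistent``; in [10, 45] ->
    ``marginally_inconsistent``; above 45 -> ``strongly_inconsistent``.
    """
    medians = np.asarray(list(median_angles_by_scale), dtype=float)
    if medians.size == 0:
        raise ValueError("need at least one median angle")
    final = medians[-1]
    if final < 10.0:
        return "consistent"
    if final <= 45.0:
        return "marginally_inconsistent"
    return "strongly_inconsistent"


def summarize_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Medians of angle/FDR/TPR/support size per (alpha, beta, method).

    Missing replicates (failed fits) are excluded from the medians and
    counted out of ``n_ok``.  Even replicate counts use the standard
    midpoint-of-two median.
    """
    grouped = results.groupby(["alpha", "beta", "method"], sort=True)
    out = grouped.agg(
        n_ok=("angle_deg", "count"),
        med_angle=("angle_deg", "median"),
        med_fdr=("fdr", "median"),
        med_tpr=("tpr", "median"),
        med_support=("support_size", "median"),
    ).reset_index()
    return out
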