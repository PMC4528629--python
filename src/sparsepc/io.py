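"""Delimited-text readers and writers.

Matrices travel as TSV/CSV with a header row of feature ids and a
first column of sample ids (plain headerless numeric bodies are also
accepted, with generated identifiers).  Fits are written as a loadings
TSV, a scores TSV and a JSON metadata record; S4VDPCA additionally
emits its selection-probability and penalty-scan tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CenteredMatrix, SparseFit, _make_ids, project_scores
from .s4vd import StabilityProfile

__all__ = ["read_matrix", "write_matrix", "write_fit", "read_fit_metadata"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def read_matrix(path, features_in: str = "columns", sep: str | None = None) -> CenteredMatrix:
    """Parse a delimited numeric matrix; returns it *uncentered*.

    Header row and id column are auto-detected (any non-numeric token
    in the first row / first column).  ``features_in='rows'``
    transposes, for the molecular convention of features x samples.
    """
    if features_in not in ("rows", "columns"):
        raise ValueError("features_in must be 'rows' or 'columns'")
    path = Path(path)
    sep = sep or _sep_for(path)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str, skip_blank_lines=True)
    if raw.isna().any().any():
        j, i = np.argwhere(raw.isna().to_numpy())[0]
        raise ValueError(f"missing or ragged cell at row {j}, column {i} of {path}")
    first_row = raw.iloc[0].tolist()
    has_header = not all(_is_number(t) for t in first_row[1:])
    first_col = raw.iloc[1:, 0].tolist() if has_header else raw.iloc[:, 0].tolist()
    has_ids = not all(_is_number(t) for t in first_col)

    body = raw.iloc[1 if has_header else 0 :, 1 if has_ids else 0 :]
    row_ids = (
        raw.iloc[1 if has_header else 0 :, 0].tolist()
        if has_ids
        else _make_ids("r", body.shape[0])
    )
    col_ids = (
        raw.iloc[0, 1 if has_ids else 0 :].tolist()
        if has_header
        else _make_ids("c", body.shape[1])
    )
    try:
        values = body.to_numpy(dtype=float)
    except ValueError:
        for (j, i), cell in np.ndenumerate(body.to_numpy()):
            if not _is_number(cell):
                raise ValueError(
                    f"non-numeric cell {cell!r} at body row {j}, column {i} of {path}"
                ) from None
        raise
    if not np.isfinite(values).all():
        j, i = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"non-finite value at body row {j}, column {i} of {path}")

    if features_in == "rows":
        values = values.T
        sample_ids, feature_ids = col_ids, row_ids
    else:
        sample_ids, feature_ids = row_ids, col_ids
    if len(set(feature_ids)) != len(feature_ids):
        dupes = pd.Series(feature_ids)
        name = dupes[dupes.duplicated()].iloc[0]
        raise ValueError(f"duplicate feature id {name!r} in {path}")
    return CenteredMatrix(
        values=values,
        feature_ids=[str(f) for f in feature_ids],
        sample_ids=[str(s) for s in sample_ids],
        centered=False,
    )


def write_matrix(X: CenteredMatrix, path) -> None:
    """Samples-in-rows TSV/CSV with header row and id column."""
    path = Path(path)
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.feature_ids)
    df.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def write_fit(
    X: CenteredMatrix,
    fits: list[SparseFit],
    outdir,
    prefix: str = "sparsepc",
    profiles: list[StabilityProfile] | None = None,
    seed: int | None = None,
    extra_metadata: dict | None = None,
) -> dict[str, Path]:
    """Write loadings, scores, metadata and (for S4VDPCA) stability tables.

    Returns a mapping of artifact name to path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    k = len(fits)
    loadings = pd.DataFrame(
        {"feature_id": X.feature_ids}
        | {f"v{j + 1}": fits[j].v for j in range(k)}
    )
    written["loadings"] = outdir / f"{prefix}_loadings.tsv"
    loadings.to_csv(written["loadings"], sep="\t", index=False)

    scores = project_scores(X, fits)
    scores_df = pd.DataFrame(
        {"sample_id": X.sample_ids}
        | {f"pc{j + 1}": scores[:, j] for j in range(k)}
    )
    written["scores"] = outdir / f"{prefix}_scores.tsv"
    scores_df.to_csv(written["scores"], sep="\t", index=False)

    from . import __version__

    meta = {
        "version": __version__,
        "seed": seed,
        "components": [
            {
                "pc": j + 1,
                "method": f.method,
                "d": f.d,
                "lambda": f.lam,
                "df": f.df,
                "criterion_value": f.criterion_value,
                "empty": f.empty,
            }
            for j, f in enumerate(fits)
        ],
    }
    if extra_metadata:
        meta.update(extra_metadata)
    written["metadata"] = outdir / f"{prefix}_metadata.json"
    written["metadata"].write_text(json.dumps(meta, indent=2) + "\n")

    if profiles:
        for j, prof in enumerate(profiles):
            rank = pd.Series(-prof.probabilities).rank(method="first").astype(int)
            probs = pd.DataFrame(
                {
                    "feature_id": X.feature_ids,
                    "probability": prof.probabilities,
                    "rank": rank,
                }
            )
            key = f"selection_probabilities_pc{j + 1}"
            written[key] = outdir / f"{prefix}_{key}.tsv"
            probs.to_csv(written[key], sep="\t", index=False)
            scan = pd.DataFrame(
                {"lambda": prof.lambda_candidates, "tie_count": prof.tie_counts}
            )
            key = f"lambda_scan_pc{j + 1}"
            written[key] = outdir / f"{prefix}_{key}.tsv"
            scan.to_csv(written[key], sep="\t", index=False)
    return written


def read_fit_metadata(path) -> dict:
    """Reload a metadata JSON written by :func:`write_fit`."""
    return json.loads(Path(path).read_text())
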