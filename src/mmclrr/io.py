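"""Reading and writing views, labels, affinities and assignments.

Dense views are delimited text (TSV/CSV), features x samples, with a header
row of sample ids and a first column of feature ids.  Sparse views are
MatrixMarket ``.mtx`` files with sidecar id lists ``<stem>.rows.txt``
(feature ids) and ``<stem>.cols.txt`` (sample ids), one id per line.
Views loaded after the first are column-aligned to the first file's sample
order; a file whose sample-id set differs raises an alignment error naming
it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datasets import MultiViewDataset, ViewMatrix

__all__ = [
    "load_views",
    "load_labels",
    "write_views",
    "write_labels",
    "write_matrix_tsv",
    "write_matrix_mtx",
    "write_assignment",
]


class AlignmentError(ValueError):
    """Sample ids of one view do not match the reference view."""


def _read_dense(path: Path, sep: str) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    try:
        data = df.to_numpy(dtype=float)
    except ValueError as exc:
        # locate the first offending cell for the error message
        for j, col in enumerate(df.columns):
            for i, val in enumerate(df[col]):
                try:
                    float(val)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {val!r} at row "
                        f"{df.index[i]!r}, column {col!r}"
                    ) from exc
        raise
    return data, [str(i) for i in df.index], [str(c) for c in df.columns]


def _read_mtx(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    stem = path.with_suffix("")
    rows_file = stem.with_suffix(".rows.txt")
    cols_file = stem.with_suffix(".cols.txt")
    for f in (rows_file, cols_file):
        if not f.exists():
            raise FileNotFoundError(f"{path}: missing sidecar id list {f}")
    feature_ids = rows_file.read_text().split()
    sample_ids = cols_file.read_text().split()
    if len(feature_ids) != mat.shape[0] or len(sample_ids) != mat.shape[1]:
        raise ValueError(
            f"{path}: sidecar id counts ({len(feature_ids)}, {len(sample_ids)}) "
            f"do not match matrix shape {mat.shape}"
        )
    return np.asarray(mat, dtype=float), feature_ids, sample_ids


def load_views(
    paths: Sequence[str | Path],
    format: str = "tsv",
    transpose: bool = False,
    view_names: Sequence[str] | None = None,
) -> MultiViewDataset:
    """Load one file per view and align all views to the first file's samples.

    Parameters
    ----------
    paths : sequence of paths
        One matrix file per view.
    format : {"tsv", "csv", "mtx"}
    transpose : bool
        Set True for samples x features files.
    view_names : optional sequence of str
        Defaults to the file stems.
    """
    if format not in {"tsv", "csv", "mtx"}:
        raise ValueError(f"unknown format {format!r}; expected tsv, csv or mtx")
    if not paths:
        raise ValueError("need at least one view file")
    paths = [Path(p) for p in paths]
    names = list(view_names) if view_names is not None else [p.stem for p in paths]
    if len(names) != len(paths):
        raise ValueError("view_names length must match the number of paths")

    views: list[ViewMatrix] = []
    ref_ids: list[str] | None = None
    for path in paths:
        if format == "mtx":
            data, feat_ids, samp_ids = _read_mtx(path)
        else:
            data, feat_ids, samp_ids = _read_dense(path, "\t" if format == "tsv" else ",")
        if transpose:
            data, feat_ids, samp_ids = data.T, samp_ids, feat_ids
        if ref_ids is None:
            ref_ids = samp_ids
        elif samp_ids != ref_ids:
            if sorted(samp_ids) != sorted(ref_ids):
                raise AlignmentError(
                    f"{path}: sample ids do not match the first view "
                    f"(symmetric difference: "
                    f"{sorted(set(samp_ids) ^ set(ref_ids))[:5]} ...)"
                )
            order = [samp_ids.index(s) for s in ref_ids]
            data = data[:, order]
        views.append(ViewMatrix(data=data, feature_ids=feat_ids))
    assert ref_ids is not None
    return MultiViewDataset(views=views, sample_ids=ref_ids, view_names=names)


def load_labels(path: str | Path, n_samples: int | None = None) -> np.ndarray:
    """Load one label per sample and encode as integers 1..c.

    Accepts a one-column file of labels or a two-column (sample_id, label)
    TSV, with or without a header.  Codes preserve first-appearance order:
    the first distinct label becomes 1, the next new one 2, and so on.
    """
    path = Path(path)
    raw: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        raw.append(parts[-1])
    if raw and raw[0].lower() in {"label", "cluster", "labels"}:
        raw = raw[1:]
    if n_samples is not None and len(raw) != n_samples:
        raise ValueError(f"{path}: {len(raw)} labels for {n_samples} samples")
    codes: dict[str, int] = {}
    encoded = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in codes:
            codes[lab] = len(codes) + 1
        encoded[i] = codes[lab]
    return encoded


def write_views(
    dataset: MultiViewDataset,
    out_dir: str | Path,
    format: str = "tsv",
) -> list[Path]:
    """Write each view to ``out_dir`` (full float precision); returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, view in zip(dataset.view_names, dataset.views):
        if format == "mtx":
            path = out_dir / f"{name}.mtx"
            write_matrix_mtx(view.data, path, view.feature_ids, dataset.sample_ids)
        else:
            sep = "\t" if format == "tsv" else ","
            path = out_dir / f"{name}.{format}"
            pd.DataFrame(
                view.data, index=view.feature_ids, columns=dataset.sample_ids
            ).to_csv(path, sep=sep, float_format="%.17g")
        written.append(path)
    return written


def write_labels(labels: np.ndarray, sample_ids: Sequence[str], path: str | Path) -> None:
    """Two-column (sample_id, label) TSV with header."""
    pd.DataFrame({"sample_id": list(sample_ids), "label": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


def write_assignment(
    labels: np.ndarray, sample_ids: Sequence[str], path: str | Path
) -> None:
    """Two-column (sample_id, cluster) TSV with header."""
    pd.DataFrame({"sample_id": list(sample_ids), "cluster": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


def write_matrix_tsv(matrix: np.ndarray, path: str | Path,
                     row_ids: Sequence[str] | None = None,
                     col_ids: Sequence[str] | None = None) -> None:
    m = np.asarray(matrix)
    df = pd.DataFrame(
        m,
        index=row_ids if row_ids is not None else [str(i) for i in range(m.shape[0])],
        columns=col_ids if col_ids is not None else [str(j) for j in range(m.shape[1])],
    )
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_matrix_mtx(matrix: np.ndarray, path: str | Path,
                     row_ids: Sequence[str] | None = None,
                     col_ids: Sequence[str] | None = None) -> None:
    """MatrixMarket file plus ``.rows.txt``/``.cols.txt`` sidecar id lists."""
    path = Path(path)
    scipy.io.mmwrite(path, scipy.sparse.coo_matrix(np.asarray(matrix)))
    stem = path.with_suffix("")
    n_rows, n_cols = np.asarray(matrix).shape
    rows = row_ids if row_ids is not None else [f"r{i}" for i in range(n_rows)]
    cols = col_ids if col_ids is not None else [f"c{j}" for j in range(n_cols)]
    stem.with_suffix(".rows.txt").write_text("\n".join(map(str, rows)) + "\n")
    stem.with_suffix(".cols.txt").write_text("\n".join(map(str, cols)) + "\n")
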