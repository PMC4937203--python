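"""Labelled data cube for transposable data and its file formats.

A *transposable* dataset holds, for each of N independent subjects, one
r x c real matrix whose rows and columns are shared, meaningful entities
(typically genes x tissues).  Every subject's matrix carries the same row
and column labels in the same order, so the whole collection is an
N x r x c cube.

Two interchange formats are supported:

* **long** — a single delimited table with columns
  ``subject_id, row_id, col_id, value`` (one line per cube cell); this is
  the canonical format.
* **wide** — one delimited matrix file per subject (first column = row
  labels, header = column labels) bound together by a two-column manifest
  ``subject_id <tab> path``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransposableDataset",
    "load_long_table",
    "load_wide_matrices",
    "write_dataset",
    "subset",
    "filter_rows_by_total",
]

LONG_COLUMNS = ("subject_id", "row_id", "col_id", "value")


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(ids) == 0:
        raise ValueError(f"{what}: at least one label required")
    if any(x == "" for x in ids):
        raise ValueError(f"{what}: empty-string labels are not allowed")
    if len(set(ids)) != len(ids):
        dup = next(x for x in ids if ids.count(x) > 1)
        raise ValueError(f"{what}: duplicate label {dup!r}")
    return ids


@dataclass
class TransposableDataset:
    """N x r x c labelled cube: one r x c matrix per subject.

    Parameters
    ----------
    values : ndarray, shape (N, r, c)
        Finite real measurements; ``values[i, a, b]`` is subject *i*'s value
        for row entity *a* (e.g. gene) in column entity *b* (e.g. tissue).
    subject_ids, row_ids, col_ids : sequences of unique non-empty strings
        Labels for the three axes, in storage order.
    """

    values: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"values must be a 3-d (subject, row, column) array, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (no NaN/inf)")
        self.subject_ids = _check_ids(self.subject_ids, "subject_ids")
        self.row_ids = _check_ids(self.row_ids, "row_ids")
        self.col_ids = _check_ids(self.col_ids, "col_ids")
        n, r, c = self.values.shape
        if (n, r, c) != (len(self.subject_ids), len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"label lengths {(len(self.subject_ids), len(self.row_ids), len(self.col_ids))} "
                f"do not match cube shape {(n, r, c)}"
            )

    # -- basic geometry ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rows(self) -> int:
        return self.values.shape[1]

    @property
    def n_cols(self) -> int:
        return self.values.shape[2]

    def matrix(self, subject: str) -> np.ndarray:
        """Return one subject's r x c matrix (a copy)."""
        i = self.subject_ids.index(subject)
        return self.values[i].copy()

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with columns subject_id,row_id,col_id,value."""
        n, r, c = self.values.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_ids, r * c),
                "row_id": np.tile(np.repeat(self.row_ids, c), n),
                "col_id": np.tile(self.col_ids, n * r),
                "value": self.values.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# loading


def load_long_table(path: str | os.PathLike, delimiter: str = "\t") -> TransposableDataset:
    """Read a long-format table into a :class:`TransposableDataset`.

    The file must contain a header with the columns
    ``subject_id, row_id, col_id, value`` and exactly one line for every
    (subject, row, column) triple.  Subject/row/column order is the order of
    first appearance in the file.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={0: str, 1: str, 2: str}, float_precision="round_trip")
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long table {path}: missing column(s) {missing}")
    try:
        vals = pd.to_numeric(df["value"], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"long table {path}: non-numeric value ({exc})") from None

    subjects = list(pd.unique(df["subject_id"]))
    rows = list(pd.unique(df["row_id"]))
    cols = list(pd.unique(df["col_id"]))
    dup = df.duplicated(subset=["subject_id", "row_id", "col_id"])
    if dup.any():
        k = df.loc[dup.idxmax(), ["subject_id", "row_id", "col_id"]]
        raise ValueError(
            f"long table {path}: duplicate triple ({k.iloc[0]}, {k.iloc[1]}, {k.iloc[2]})"
        )

    n, r, c = len(subjects), len(rows), len(cols)
    cube = np.full((n, r, c), np.nan)
    si = pd.Categorical(df["subject_id"], categories=subjects).codes
    ri = pd.Categorical(df["row_id"], categories=rows).codes
    ci = pd.Categorical(df["col_id"], categories=cols).codes
    cube[si, ri, ci] = vals.to_numpy()

    if np.isnan(cube).any():
        i, a, b = np.argwhere(np.isnan(cube))[0]
        raise ValueError(
            f"long table {path}: incomplete cube — missing triple "
            f"({subjects[i]}, {rows[a]}, {cols[b]})"
        )
    return TransposableDataset(cube, subjects, rows, cols)


def load_wide_matrices(manifest: str | os.PathLike, delimiter: str = "\t") -> TransposableDataset:
    """Read per-subject wide matrix files listed in a two-column manifest.

    The manifest maps ``subject_id`` to a matrix file path (relative paths
    are resolved against the manifest's directory).  Each matrix file has
    column labels in its header and row labels in its first column.  All
    files must carry identical label *sets*; files whose labels are permuted
    relative to the first subject's are reordered to match it.
    """
    mpath = Path(manifest)
    man = pd.read_csv(mpath, sep=delimiter, header=None, names=["subject_id", "path"], dtype=str)
    if man["subject_id"].duplicated().any():
        dup = man.loc[man["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"manifest {manifest}: duplicate subject {dup!r}")
    subjects = list(man["subject_id"])
    mats, ref_rows, ref_cols = [], None, None
    for sid, rel in zip(subjects, man["path"]):
        p = Path(rel)
        if not p.is_absolute():
            p = mpath.parent / p
        wide = pd.read_csv(p, sep=delimiter, index_col=0, float_precision="round_trip")
        wide.index = wide.index.astype(str)
        wide.columns = wide.columns.astype(str)
        if ref_rows is None:
            ref_rows = _check_ids(list(wide.index), f"subject {sid}: row labels")
            ref_cols = _check_ids(list(wide.columns), f"subject {sid}: column labels")
        else:
            if set(wide.index) != set(ref_rows) or set(wide.columns) != set(ref_cols):
                raise ValueError(
                    f"wide matrices: label set of subject {sid!r} does not match "
                    f"subject {subjects[0]!r}"
                )
            wide = wide.loc[ref_rows, ref_cols]
        mats.append(wide.to_numpy(dtype=float))
    return TransposableDataset(np.stack(mats), subjects, ref_rows, ref_cols)


# ---------------------------------------------------------------------------
# writing


def write_dataset(
    ds: TransposableDataset,
    path: str | os.PathLike,
    format: str = "long",
    delimiter: str = "\t",
) -> None:
    """Write a dataset in ``long`` (single file) or ``wide`` format.

    For ``wide``, *path* is a directory that will contain one
    ``<subject>.tsv`` matrix per subject plus ``manifest.tsv``.  Floats are
    written with full precision so that a write/load round trip reproduces
    the cube exactly.
    """
    if format == "long":
        ds.to_long_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")
    elif format == "wide":
        d = Path(path)
        d.mkdir(parents=True, exist_ok=True)
        entries = []
        for i, sid in enumerate(ds.subject_ids):
            fname = f"{sid}.tsv"
            pd.DataFrame(ds.values[i], index=ds.row_ids, columns=ds.col_ids).to_csv(
                d / fname, sep=delimiter, float_format="%.17g"
            )
            entries.append((sid, fname))
        pd.DataFrame(entries).to_csv(d / "manifest.tsv", sep=delimiter, index=False, header=False)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'long' or 'wide')")


# ---------------------------------------------------------------------------
# label-driven subsetting and expression filtering


def _resolve(requested: Sequence[str], available: list[str], axis: str) -> list[int]:
    requested = [str(x) for x in requested]
    if len(requested) == 0:
        raise ValueError(f"subset: empty {axis} selection")
    if len(set(requested)) != len(requested):
        raise ValueError(f"subset: duplicate {axis} label in selection")
    lut = {x: i for i, x in enumerate(available)}
    unknown = [x for x in requested if x not in lut]
    if unknown:
        raise ValueError(f"subset: unknown {axis} label(s) {unknown}")
    return [lut[x] for x in requested]


def subset(
    ds: TransposableDataset,
    rows: Sequence[str] | None = None,
    cols: Sequence[str] | None = None,
) -> TransposableDataset:
    """Restrict a dataset to the requested row/column labels, in the
    requested order.  Subjects are unchanged."""
    vals = ds.values
    new_rows, new_cols = list(ds.row_ids), list(ds.col_ids)
    if rows is not None:
        idx = _resolve(rows, ds.row_ids, "row")
        vals = vals[:, idx, :]
        new_rows = [ds.row_ids[i] for i in idx]
    if cols is not None:
        idx = _resolve(cols, ds.col_ids, "column")
        vals = vals[:, :, idx]
        new_cols = [ds.col_ids[i] for i in idx]
    return TransposableDataset(vals.copy(), list(ds.subject_ids), new_rows, new_cols)


def filter_rows_by_total(
    ds: TransposableDataset,
    threshold: float,
    reduction: str = "mean_over_subjects",
) -> tuple[TransposableDataset, list[str]]:
    """Drop weakly-expressed rows whose total across columns falls below
    *threshold* (the motivating workflow removes genes whose RPKM sum over
    tissues is below 0.1).

    reduction
        ``"mean_over_subjects"`` (default): drop row *a* iff the subject-mean
        of its column sums is below the threshold.
        ``"per_subject_any"``: drop row *a* iff any single subject's column
        sum for that row is below the threshold.

    Returns the filtered dataset (surviving rows keep their order) together
    with the list of dropped row ids.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    row_sums = ds.values.sum(axis=2)  # (N, r)
    if reduction == "mean_over_subjects":
        drop = row_sums.mean(axis=0) < threshold
    elif reduction == "per_subject_any":
        drop = (row_sums < threshold).any(axis=0)
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    keep = [rid for rid, d in zip(ds.row_ids, drop) if not d]
    dropped = [rid for rid, d in zip(ds.row_ids, drop) if d]
    if not keep:
        raise ValueError("filter_rows_by_total: all rows dropped")
    return subset(ds, rows=keep), dropped
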