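"""Readers and writers for the formats the tool touches.

Dense delimited text (TSV/CSV with a header row and a row-name column) is
the primary interchange format; Matrix Market triplets with companion
row/column name files are accepted for sparse inputs and densified, since
the clustering arithmetic is dense in at most k_init - 1 dimensions
anyway.  An orientation flag declares whether rows are cells or genes.

Run outputs are plain text: an assignments TSV (one column per hierarchy
level), a merge-trace TSV, a Newick tree of the merges, a metadata file
sufficient to regenerate the run, and a manifest with checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import __version__
from .errors import InvalidInputError, InvalidParameterError
from .hierarchy import Hierarchy
from .pca import ExpressionMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_outputs",
    "read_assignments",
    "hierarchy_to_newick",
]

_DELIMS = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "csv", "mtx", "txt"):
        return "tsv" if suffix == "txt" else suffix
    raise InvalidParameterError(f"cannot infer format from {path.name!r}")


def read_matrix(
    path: str | Path,
    format: str | None = None,
    orientation: str = "cells-rows",
    row_names: str | Path | None = None,
    col_names: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix, normalising orientation to cells-as-rows.

    For MTX input, row and column names are read from companion one-name-
    per-line files (defaults: ``<stem>.rows.txt`` / ``<stem>.cols.txt``
    next to the matrix).  Non-finite entries and duplicate identifiers are
    rejected with positional context.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if orientation not in ("cells-rows", "genes-rows"):
        raise InvalidParameterError(f"unknown orientation {orientation!r}")
    if fmt in _DELIMS:
        try:
            df = pd.read_csv(path, sep=_DELIMS[fmt], index_col=0)
        except Exception as exc:
            raise InvalidInputError(f"failed to parse {path}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        row_ids = [str(r) for r in df.index]
        col_ids = [str(c) for c in df.columns]
    elif fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise InvalidInputError(f"failed to parse {path}: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        row_path = Path(row_names) if row_names else path.with_suffix(".rows.txt")
        col_path = Path(col_names) if col_names else path.with_suffix(".cols.txt")
        for p in (row_path, col_path):
            if not p.exists():
                raise InvalidInputError(f"missing companion name file: {p}")
        row_ids = row_path.read_text().split()
        col_ids = col_path.read_text().split()
        if len(row_ids) != values.shape[0] or len(col_ids) != values.shape[1]:
            raise InvalidInputError(
                f"name files ({len(row_ids)} x {len(col_ids)}) do not match "
                f"matrix shape {values.shape}"
            )
    else:
        raise InvalidParameterError(f"unsupported format {fmt!r}")
    if orientation == "genes-rows":
        values, row_ids, col_ids = values.T, col_ids, row_ids
    return ExpressionMatrix(values=values, cell_ids=row_ids, gene_ids=col_ids)


def write_matrix(X: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write an expression matrix as delimited text, cells as rows."""
    if format not in _DELIMS:
        raise InvalidParameterError(f"unsupported output format {format!r}")
    df = pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_ids)
    df.to_csv(Path(path), sep=_DELIMS[format], index_label="cell_id")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (cell_id, label) TSV into a Series indexed by cell."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise InvalidInputError(f"failed to parse labels {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise InvalidInputError(f"{path}: expected two columns (cell_id, label)")
    if df.iloc[:, 0].duplicated().any():
        dup = df.iloc[:, 0][df.iloc[:, 0].duplicated()].iloc[0]
        raise InvalidInputError(f"{path}: duplicate cell id {dup!r}")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="label")


def write_labels(cell_ids: list[str], labels, path: str | Path, name: str = "label") -> None:
    pd.DataFrame({"cell_id": cell_ids, name: np.asarray(labels)}).to_csv(
        Path(path), sep="\t", index=False
    )


def _assignments_frame(h: Hierarchy) -> pd.DataFrame:
    cols = {f"k={k}": h.levels[k] for k in sorted(h.levels, reverse=True)}
    return pd.DataFrame(cols, index=pd.Index(h.cell_ids, name="cell_id"))


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Read an assignments TSV back into a cells x levels integer frame."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    bad = [c for c in df.columns if not c.startswith("k=")]
    if bad:
        raise InvalidInputError(f"{path}: unexpected columns {bad}")
    return df.astype(int)


def hierarchy_to_newick(h: Hierarchy) -> str:
    """Render the merge trace as a Newick tree over the cells.

    Each initial cluster becomes a star over its member cells; every merge
    joins two subtrees under an internal node labelled ``M<order>`` in
    merge order.  All branch lengths are 1.
    """
    initial = h.levels[h.k_init]
    # leaf names are quoted so underscores survive Newick parsing
    subtree = {
        lab: "(" + ",".join(
            f"'{h.cell_ids[idx]}':1" for idx in np.flatnonzero(initial == lab)
        ) + f")C{lab}"
        for lab in range(1, h.k_init + 1)
    }
    # Merge traces are expressed in each level's first-appearance labels;
    # uniting b into a (a < b) shifts labels above b down by one, which is
    # exactly the relabelling the hierarchy itself applies between levels.
    for order, rec in enumerate(h.merge_trace, start=1):
        a, b = rec["cluster_a"], rec["cluster_b"]
        node = f"({subtree.pop(a)}:1,{subtree.pop(b)}:1)M{order}"
        subtree = {(lab - 1 if lab > b else lab): t for lab, t in subtree.items()}
        subtree[a] = node
    (tree,) = subtree.values()
    return tree + ";"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_run(h: Hierarchy, out_dir: Path) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    assign_path = out_dir / "assignments.tsv"
    _assignments_frame(h).to_csv(assign_path, sep="\t")
    paths.append(assign_path)
    trace_path = out_dir / "merge_trace.tsv"
    pd.DataFrame(h.merge_trace)[
        ["level", "cluster_a", "cluster_b", "log_score", "dim"]
    ].to_csv(trace_path, sep="\t", index=False)
    paths.append(trace_path)
    tree_path = out_dir / "tree.nwk"
    tree_path.write_text(hierarchy_to_newick(h) + "\n")
    paths.append(tree_path)
    meta_path = out_dir / "run_metadata.json"
    meta = {
        "tool": "pcareduce",
        "version": __version__,
        "k_init": h.k_init,
        "strategy": h.strategy,
        "seed": h.seed,
        "kmeans_seed": h.kmeans_seed,
        "n_cells": h.n,
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    paths.append(meta_path)
    return paths


def write_outputs(result: Hierarchy | list[Hierarchy], out_dir: str | Path) -> dict:
    """Write run artifacts and return a checksummed manifest.

    A single hierarchy is written directly into ``out_dir``; an ensemble
    goes into ``run_000/ ... run_NNN/`` subdirectories.  The manifest
    (also written as ``manifest.json``) maps relative paths to SHA-256
    checksums.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(result, Hierarchy):
        paths = _write_run(result, out_dir)
    else:
        paths = []
        for idx, h in enumerate(result):
            paths.extend(_write_run(h, out_dir / f"run_{idx:03d}"))
    manifest = {
        "artifacts": {
            str(p.relative_to(out_dir)): _sha256(p) for p in sorted(paths)
        }
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
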