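"""Readers and writers for the matrix and tabular formats the pipeline touches.

Supported on-disk representations:

* MatrixMarket coordinate triplets (``.mtx``) with ``genes.tsv`` /
  ``cells.tsv`` sidecars, CellRanger-style. MTX files may be stored
  genes × cells (the CellRanger convention); orientation is
  auto-detected from the sidecar lengths and transposed to
  cells × genes in memory.
* Dense TSV: first row gene ids, first column cell ids.
* Labels TSV: two columns ``cell_id <tab> class``, no header.
* Ranking TSV: columns ``rank`` (1-based), ``gene_id``, ``score``.

All writers are deterministic byte-for-byte given identical inputs
(UTF-8, LF line endings); MTX coordinates are 1-based per the
MatrixMarket standard while in-memory indices are 0-based.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataset import ExpressionDataset
from .rankers import GeneRanking


def _read_id_column(path: str | os.PathLike) -> list[str]:
    """First column of a headerless TSV (gene/cell sidecar)."""
    ids: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column labels TSV into a cell_id -> class mapping."""
    labels: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'cell_id<TAB>class', got {line!r}"
                )
            cell, cls = parts
            if cell in labels:
                raise ValueError(f"{path}: duplicate cell id {cell!r}")
            labels[cell] = cls
    return labels


def write_labels(labels: dict[str, str] | "pd.Series", path: str | os.PathLike) -> None:
    items = labels.items() if isinstance(labels, dict) else labels.to_dict().items()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for cell, cls in items:
            fh.write(f"{cell}\t{cls}\n")


def read_expression(
    matrix_path: str | os.PathLike,
    format: str,
    labels_path: str | os.PathLike,
    genes_path: str | os.PathLike | None = None,
    cells_path: str | os.PathLike | None = None,
) -> ExpressionDataset:
    """Read an expression matrix plus labels into an :class:`ExpressionDataset`.

    Parameters
    ----------
    matrix_path
        The ``.mtx`` file (``format="mtx"``) or dense TSV (``format="dense"``).
    format
        ``"mtx"`` or ``"dense"``.
    labels_path
        Two-column TSV mapping every cell id to its class.
    genes_path, cells_path
        Sidecar id files; required for ``mtx``, defaulting to
        ``genes.tsv`` / ``cells.tsv`` next to the matrix.
    """
    matrix_path = Path(matrix_path)
    if format == "mtx":
        genes_path = genes_path or matrix_path.parent / "genes.tsv"
        cells_path = cells_path or matrix_path.parent / "cells.tsv"
        gene_ids = _read_id_column(genes_path)
        cell_ids = _read_id_column(cells_path)
        mat = scipy.io.mmread(os.fspath(matrix_path))
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64)
        if mat.shape == (len(gene_ids), len(cell_ids)) and mat.shape[0] != mat.shape[1]:
            mat = mat.T  # genes x cells on disk (CellRanger) -> cells x genes
        elif mat.shape == (len(cell_ids), len(gene_ids)):
            pass
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither "
                f"(cells={len(cell_ids)}, genes={len(gene_ids)}) nor its transpose"
            )
        values = mat
    elif format == "dense":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=np.float64)
        gene_ids = [str(g) for g in df.columns]
        cell_ids = [str(c) for c in df.index]
    else:
        raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'dense'")

    label_map = read_labels(labels_path)
    missing = [c for c in cell_ids if c not in label_map]
    if missing:
        raise ValueError(
            f"labels file {labels_path} is missing cell(s): {', '.join(missing[:5])}"
        )
    labels = np.array([label_map[c] for c in cell_ids], dtype=object)
    return ExpressionDataset(
        values=values, gene_ids=gene_ids, cell_ids=cell_ids, labels=labels
    )


def write_expression(
    ds: ExpressionDataset,
    out_dir: str | os.PathLike,
    format: str = "mtx",
    basename: str = "matrix",
) -> dict[str, Path]:
    """Write a dataset as MTX + sidecars + labels, or dense TSV + labels.

    Returns the paths written, keyed by role. Round-trips with
    :func:`read_expression` losslessly up to float representation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if format == "mtx":
        mtx_path = out_dir / f"{basename}.mtx"
        # stored genes x cells per the CellRanger convention
        sparse = scipy.sparse.coo_matrix(ds.values.T)
        scipy.io.mmwrite(os.fspath(mtx_path), sparse, precision=10)
        paths["matrix"] = mtx_path
        genes_path = out_dir / "genes.tsv"
        with open(genes_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.writelines(f"{g}\n" for g in ds.gene_ids)
        paths["genes"] = genes_path
        cells_path = out_dir / "cells.tsv"
        with open(cells_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.writelines(f"{c}\n" for c in ds.cell_ids)
        paths["cells"] = cells_path
    elif format == "dense":
        dense_path = out_dir / f"{basename}.tsv"
        df = pd.DataFrame(ds.values, index=ds.cell_ids, columns=ds.gene_ids)
        df.to_csv(dense_path, sep="\t", float_format="%.10g", lineterminator="\n")
        paths["matrix"] = dense_path
    else:
        raise ValueError(f"unknown format {format!r}")
    labels_path = out_dir / "labels.tsv"
    write_labels(dict(zip(ds.cell_ids, (str(x) for x in ds.labels))), labels_path)
    paths["labels"] = labels_path
    return paths


def write_ranking(r: GeneRanking, path: str | os.PathLike) -> None:
    """Write a ranking as a TSV with columns rank (1-based), gene_id, score."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rank\tgene_id\tscore\n")
        for i, (g, s) in enumerate(zip(r.ordered_genes, r.scores), 1):
            fh.write(f"{i}\t{g}\t{s:.12g}\n")


def read_ranking(path: str | os.PathLike, method: str = "unknown") -> GeneRanking:
    """Read a ranking TSV back; rejects duplicate genes."""
    genes: list[str] = []
    scores: list[float] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("rank"):
            raise ValueError(f"{path}: missing ranking header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            rank_s, gene, score_s = line.split("\t")
            if gene in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate gene {gene!r}")
            seen.add(gene)
            genes.append(gene)
            scores.append(float(score_s))
    return GeneRanking(method=method, ordered_genes=genes, scores=np.array(scores))
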