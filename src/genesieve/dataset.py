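"""Core in-memory container for labeled expression profiles.

The pipeline operates on a cells × genes matrix of non-negative,
log-normalized expression values together with one categorical class
label per cell (for example, the prime–boost vaccination strategy of
the cell's donor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExpressionDataset:
    """Cells × genes expression matrix with per-cell class labels.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_cells, n_genes)``, non-negative,
        on a log-normalized scale (unitless).
    gene_ids
        Ordered unique gene identifiers, one per column.
    cell_ids
        Ordered unique cell identifiers, one per row.
    labels
        Per-cell class label, drawn from a finite label set of size >= 2
        for classification tasks (a single class is permitted at
        construction time; classifiers reject it downstream).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes matrix")
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != {n_genes} columns"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != {n_cells} rows"
            )
        if len(self.labels) != n_cells:
            raise ValueError(
                f"labels length {len(self.labels)} != {n_cells} rows"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids contain duplicates")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids contain duplicates")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative (log scale)")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        """Sorted distinct class labels."""
        return sorted({str(x) for x in self.labels})

    def gene_index(self, gene_id: str) -> int:
        """Column index of a gene id (raises KeyError if absent)."""
        try:
            return self._gene_lookup[gene_id]
        except AttributeError:
            self._gene_lookup = {g: i for i, g in enumerate(self.gene_ids)}
            return self._gene_lookup[gene_id]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionDataset":
        """Restrict to the given genes, in the given order."""
        idx = [self.gene_index(g) for g in gene_ids]
        return ExpressionDataset(
            values=self.values[:, idx],
            gene_ids=list(gene_ids),
            cell_ids=list(self.cell_ids),
            labels=self.labels.copy(),
        )

    def class_counts(self) -> dict[str, int]:
        """Number of cells per class label."""
        out: dict[str, int] = {}
        for lab in self.labels:
            out[str(lab)] = out.get(str(lab), 0) + 1
        return dict(sorted(out.items()))
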