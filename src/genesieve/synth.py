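"""Synthetic labeled expression datasets with planted discriminative genes.

Generates sparse, non-negative, log-scale expression profiles for a
small number of classes (default three, named after prime–boost
vaccination strategies) with a known subset of class-discriminative
genes among many null genes. Every downstream stage of the pipeline —
ranking, incremental feature selection, rule mining, consensus — is
testable against the planted ground truth without any external data.

Noise model: each value is drawn as ``max(0, Normal(base_mean + shift,
dispersion))`` and then independently zeroed with probability
``dropout_rate``. This yields sparse values in roughly [0, 8] on the
default settings — the range of log-normalized single-cell expression —
without committing to a count model. Library-size effects and batch
structure are deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset

DEFAULT_CLASS_NAMES = ("BNT-BNT", "ChAd-BNT", "ChAd-ChAd")


@dataclass
class SynthSpec:
    """Parameters of the synthetic dataset generator.

    Attributes
    ----------
    class_sizes
        Cells per class (positive integers). Default mimics the
        imbalance of a B-cell cohort split across three vaccination
        strategies (499 / 2266 / 889).
    n_genes
        Total number of genes.
    n_informative
        Number of planted class-discriminative genes (<= n_genes).
    effect_size
        Mean log-expression shift between classes for informative genes.
    base_mean
        Log-scale background mean common to all genes.
    dispersion
        Gaussian noise SD on the log scale (per-gene overdispersion).
    dropout_rate
        Probability in [0, 1] that any single value is zeroed.
    seed
        Seed for the generator; identical spec -> identical dataset.
    class_names
        Class labels; padded/generated if more classes than names.
    """

    class_sizes: list[int] = field(default_factory=lambda: [499, 2266, 889])
    n_genes: int = 500
    n_informative: int = 10
    effect_size: float = 2.0
    base_mean: float = 1.5
    dispersion: float = 1.0
    dropout_rate: float = 0.5
    seed: int = 0
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        if not self.class_sizes:
            raise ValueError("class_sizes must be non-empty")
        for s in self.class_sizes:
            if int(s) <= 0:
                raise ValueError(f"class sizes must be positive, got {s}")
        self.class_sizes = [int(s) for s in self.class_sizes]
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError(
                f"n_informative must be in [0, n_genes], got {self.n_informative}"
            )
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.base_mean < 0:
            raise ValueError("base_mean must be non-negative")
        if len(self.class_names) < len(self.class_sizes):
            extra = tuple(
                f"class{i}" for i in range(len(self.class_names), len(self.class_sizes))
            )
            self.class_names = tuple(self.class_names) + extra

    @property
    def n_classes(self) -> int:
        return len(self.class_sizes)

    @property
    def labels_in_use(self) -> tuple[str, ...]:
        return tuple(self.class_names[: self.n_classes])


@dataclass
class GroundTruth:
    """Which genes were planted and with what per-class mean shift."""

    informative_genes: set[str]
    class_mean_shifts: dict[tuple[str, str], float]  # (gene_id, class) -> shift


def _shift_pattern(gene_rank: int, n_classes: int) -> np.ndarray:
    """Signed per-class pattern for the gene_rank-th informative gene.

    A base up/neutral/down vector is rotated by the gene's rank so the
    patterns differ across informative genes and every pattern separates
    at least one class pair. Works for any n_classes >= 2.
    """
    base = np.zeros(n_classes)
    base[0] = 1.0
    base[-1] = -1.0
    return np.roll(base, gene_rank % n_classes)


def generate_dataset(spec: SynthSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a labeled expression dataset from a :class:`SynthSpec`.

    Returns the dataset together with a :class:`GroundTruth` naming the
    planted informative genes and their per-class mean shifts. Identical
    spec (including seed) yields a bitwise-identical dataset.
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = sum(spec.class_sizes)
    n_classes = spec.n_classes

    gene_ids = [f"G{j:05d}" for j in range(spec.n_genes)]
    cell_ids = [f"C{i:05d}" for i in range(n_cells)]
    labels = np.concatenate(
        [
            np.full(sz, spec.labels_in_use[c], dtype=object)
            for c, sz in enumerate(spec.class_sizes)
        ]
    )
    class_index = np.concatenate(
        [np.full(sz, c, dtype=np.int64) for c, sz in enumerate(spec.class_sizes)]
    )

    # informative genes are evenly spread over the gene index range so
    # they are not an index-order artifact for tie-broken rankers
    if spec.n_informative > 0:
        info_idx = np.linspace(
            0, spec.n_genes - 1, spec.n_informative, dtype=np.int64
        )
        info_idx = np.unique(info_idx)
        # linspace may collide for tiny n_genes; fill greedily
        j = 0
        while len(info_idx) < spec.n_informative:
            if j not in info_idx:
                info_idx = np.sort(np.append(info_idx, j))
            j += 1
    else:
        info_idx = np.array([], dtype=np.int64)

    shift = np.zeros((n_classes, spec.n_genes))
    truth_shifts: dict[tuple[str, str], float] = {}
    for rank, j in enumerate(info_idx):
        pat = _shift_pattern(rank, n_classes) * spec.effect_size
        shift[:, j] = pat
        for c in range(n_classes):
            truth_shifts[(gene_ids[j], spec.labels_in_use[c])] = float(pat[c])

    mean = spec.base_mean + shift[class_index, :]  # cells x genes
    values = rng.normal(loc=mean, scale=spec.dispersion)
    np.maximum(values, 0.0, out=values)
    if spec.dropout_rate > 0:
        keep = rng.random(values.shape) >= spec.dropout_rate
        values *= keep

    ds = ExpressionDataset(
        values=values, gene_ids=gene_ids, cell_ids=cell_ids, labels=labels
    )
    truth = GroundTruth(
        informative_genes={gene_ids[j] for j in info_idx},
        class_mean_shifts=truth_shifts,
    )
    return ds, truth
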