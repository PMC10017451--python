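"""SMOTE oversampling of minority classes to the majority-class size.

Each synthetic sample is placed uniformly at random on the segment
between a minority-class point and one of its k same-class Euclidean
nearest neighbors: s = x + λ (x_nn − x), λ ~ U(0, 1). Oversampling
continues per class until every class matches the majority count.
Applied inside each cross-validation training fold only, on the
current gene subset, so synthetic points never reach a test fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class BalancedSet:
    """Augmented matrix/labels with synthetic rows flagged.

    Original rows appear first and unchanged; ``synthetic_flags`` is
    True exactly for generated rows.
    """

    values: np.ndarray
    labels: np.ndarray
    synthetic_flags: np.ndarray

    def __post_init__(self) -> None:
        if not (
            len(self.values) == len(self.labels) == len(self.synthetic_flags)
        ):
            raise ValueError("values, labels and synthetic_flags must align")


def smote_balance(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> BalancedSet:
    """Balance all classes up to the majority-class size via SMOTE.

    Parameters
    ----------
    X
        Samples × features matrix.
    y
        Per-sample class labels.
    k
        Number of same-class nearest neighbors considered per seed
        point; capped at (class size − 1) with a warning when a
        minority class is smaller than k + 1.
    seed
        RNG seed; fixed seed gives a deterministic augmentation.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")

    counts: dict[str, int] = {}
    for lab in y:
        counts[str(lab)] = counts.get(str(lab), 0) + 1
    majority = max(counts.values())

    rng = np.random.default_rng(seed)
    new_rows: list[np.ndarray] = []
    new_labels: list[str] = []
    for cls in sorted(counts):
        deficit = majority - counts[cls]
        if deficit == 0:
            continue
        if counts[cls] < 2:
            raise ValueError(
                f"minority class {cls!r} has a single sample; SMOTE needs >= 2"
            )
        cls_idx = np.flatnonzero(np.array([str(v) == cls for v in y]))
        Xc = X[cls_idx]
        k_eff = min(k, len(Xc) - 1)
        if k_eff < k:
            warnings.warn(
                f"class {cls!r} has {len(Xc)} samples; k capped at {k_eff}",
                stacklevel=2,
            )
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
        # column 0 is the point itself
        neighbor_idx = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        seeds = rng.integers(0, len(Xc), size=deficit)
        picks = rng.integers(0, k_eff, size=deficit)
        lam = rng.random(size=deficit)
        # open interval (0, 1): redraw the measure-zero exact-0 draws
        while np.any(lam == 0.0):
            lam[lam == 0.0] = rng.random(size=int(np.sum(lam == 0.0)))
        base = Xc[seeds]
        nbr = Xc[neighbor_idx[seeds, picks]]
        synth = base + lam[:, None] * (nbr - base)
        new_rows.append(synth)
        new_labels.extend([cls] * deficit)

    if new_rows:
        values = np.vstack([X] + new_rows)
        labels = np.concatenate([y, np.array(new_labels, dtype=object)])
    else:
        values = X.copy()
        labels = y.copy()
    flags = np.zeros(len(values), dtype=bool)
    flags[len(X):] = True
    return BalancedSet(values=values, labels=labels, synthetic_flags=flags)
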