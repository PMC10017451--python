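"""Five gene-importance ranking algorithms over labeled expression profiles.

Each ranker consumes an :class:`~genesieve.dataset.ExpressionDataset`
and produces a :class:`GeneRanking` — an ordered gene list with
method-specific importance scores:

``mrmr``
    Greedy max-relevance / min-redundancy ordering using the MID
    (difference) criterion on mutual information computed over
    3-state discretized expression (below/within/above mean ± SD).
``mcfs``
    Monte Carlo feature selection: decision trees on random gene
    projections and bootstrap cell samples; a gene's relative
    importance (RI) aggregates the information gain of its splits,
    weighted by tree accuracy and node mass.
``lasso``
    One-vs-rest lasso linear models on standardized expression against
    per-class indicators; a gene scores the largest absolute
    coefficient it attains in any class model.
``gbdt_split``
    Gradient-boosted decision trees (LightGBM); a gene scores the
    total number of times it is used to split, over all trees
    (total gain is computed alongside but not used for ordering).
``pfi``
    Permutation feature importance: the ratio of a random forest's
    misclassification rate after shuffling one gene's column to its
    baseline rate, averaged over repetitions.

All rankers are deterministic given their seed; ties are broken by
original gene index throughout.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Lasso
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .dataset import ExpressionDataset

RANKER_METHODS = ("mrmr", "mcfs", "lasso", "gbdt_split", "pfi")


def child_seed(seed: int, *tags) -> int:
    """Stable sub-seed derived from a parent seed and string/int tags.

    Keeps every derived seed in [0, 2^31) so it is valid for any
    estimator's ``random_state``.
    """
    parts = [int(seed) & 0x7FFFFFFF]
    parts += [zlib.crc32(str(t).encode("utf-8")) for t in tags]
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


@dataclass
class GeneRanking:
    """Ordered gene list with per-gene importance scores.

    ``ordered_genes`` is a permutation of the dataset's genes, or a
    declared top-N prefix of one. ``aux_scores`` carries secondary
    per-gene quantities aligned to the order (e.g. total split gain
    for the GBDT ranker) that do not affect the ordering.
    """

    method: str
    ordered_genes: list[str]
    scores: np.ndarray
    seed: int | None = None
    aux_scores: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.ordered_genes) != len(self.scores):
            raise ValueError("scores must align with ordered_genes")
        if len(set(self.ordered_genes)) != len(self.ordered_genes):
            raise ValueError("ranking contains duplicate genes")

    def top(self, n: int) -> list[str]:
        return self.ordered_genes[:n]

    def __len__(self) -> int:
        return len(self.ordered_genes)


@dataclass
class McfsParams:
    """Monte Carlo feature selection parameters.

    s random gene projections of m genes each; t trees per projection,
    each on a bootstrap sample of the cells (``bootstrap_frac`` of them,
    with replacement), evaluated on its out-of-bag cells. u and v are
    the exponents on tree accuracy and relative node mass in the RI
    score. ``m`` defaults to ceil(0.05 * n_genes) at call time.

    ``min_leaf_frac`` regularizes the projection trees: each leaf must
    hold at least that fraction of the bootstrap sample. Fully-grown
    trees always split to purity and hence spread a near-constant
    impurity budget over their features regardless of feature quality;
    classical MCFS uses pruned trees for the same reason.
    """

    s: int = 200
    t: int = 5
    m: int | None = None
    u: float = 1.0
    v: float = 1.0
    bootstrap_frac: float = 0.66
    min_leaf_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 1 or self.t < 1:
            raise ValueError("s and t must be positive")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be positive")
        if self.u < 0 or self.v < 0:
            raise ValueError("u and v must be non-negative")
        if not 0 < self.bootstrap_frac <= 1:
            raise ValueError("bootstrap_frac must be in (0, 1]")
        if not 0 <= self.min_leaf_frac < 1:
            raise ValueError("min_leaf_frac must be in [0, 1)")


@dataclass
class PfiParams:
    """Permutation-feature-importance parameters.

    K shuffle repetitions per gene; the error measure L(y, f(X)) is the
    misclassification rate. ``mode='ratio'`` scores a gene as
    e_perm / e_base (the default); ``'difference'`` as e_perm − e_base.

    ``min_leaf`` regularizes the forest's trees so the model does not
    memorize the data it is evaluated on: errors are measured on the
    training data itself, and a fully-grown forest has (near-)zero
    baseline error and no sensitivity to permuting any one column.
    """

    K: int = 5
    error_measure: str = "misclassification"
    mode: str = "ratio"
    n_trees: int = 100
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.mode not in ("ratio", "difference"):
            raise ValueError("mode must be 'ratio' or 'difference'")


# ---------------------------------------------------------------------------
# discretization and mutual information
# ---------------------------------------------------------------------------

def discretize_gene(values: np.ndarray) -> np.ndarray:
    """Map a gene's expression values to 3 states: 0=low, 1=mid, 2=high.

    low if v < mean − SD, high if v > mean + SD, else mid. A constant
    gene (SD = 0) maps entirely to mid.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    mu = values.mean()
    sd = values.std()
    states = np.ones(values.shape, dtype=np.int8)
    states[values < mu - sd] = 0
    states[values > mu + sd] = 2
    return states


def _codes(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Integer-code an arbitrary discrete vector."""
    _, inv = np.unique(np.asarray(x), return_inverse=True)
    return inv.astype(np.int64), int(inv.max()) + 1 if inv.size else 0


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (in nats) of two discrete vectors.

    MI = sum over the observed joint frequency table of
    p(x,y) * log[ p(x,y) / (p(x) p(y)) ]. Non-negative and symmetric.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size == 0:
        raise ValueError("vectors must be non-empty")
    xc, nx = _codes(x)
    yc, ny = _codes(y)
    joint = np.zeros((nx, ny), dtype=np.float64)
    np.add.at(joint, (xc, yc), 1.0)
    p = joint / x.size
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    terms = np.zeros_like(p)
    terms[mask] = p[mask] * np.log(p[mask] / (px @ py)[mask])
    return float(max(terms.sum(), 0.0))


def _mi_vector(xc: np.ndarray, n_states_x: int, onehots: list[np.ndarray]) -> np.ndarray:
    """MI (nats) between one coded vector and every column of a coded matrix.

    ``onehots[b]`` is the float (cells, genes) indicator of state b of
    the discretized gene matrix; MI is computed from the 3 x n_states_x
    joint table of each column, vectorized over genes via BLAS.
    """
    n = onehots[0].shape[0]
    n_states_d = len(onehots)
    counts = np.empty((n_states_x, n_states_d, onehots[0].shape[1]))
    for a in range(n_states_x):
        xa = (xc == a).astype(np.float64)
        for b in range(n_states_d):
            counts[a, b] = xa @ onehots[b]
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    terms[~(p > 0)] = 0.0
    return np.maximum(terms.sum(axis=(0, 1)), 0.0)


def discretize_dataset(ds: ExpressionDataset) -> np.ndarray:
    """Discretize every gene column to the 3-state scheme (int8 matrix)."""
    mu = ds.values.mean(axis=0)
    sd = ds.values.std(axis=0)
    states = np.ones(ds.values.shape, dtype=np.int8)
    states[ds.values < mu - sd] = 0
    states[ds.values > mu + sd] = 2
    return states


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

def rank_mrmr(
    ds: ExpressionDataset,
    top_n: int | None = None,
    criterion: str = "MID",
) -> GeneRanking:
    """Greedy max-relevance min-redundancy gene ordering.

    The first gene maximizes MI with the class label; each subsequent
    gene g maximizes MI(g, label) − mean_{s in S} MI(g, s) over the
    already-selected set S (MID criterion; MIQ uses the quotient
    instead). Ties break toward the smaller original gene index.
    The recorded score is the criterion value at selection time.
    """
    if top_n is None:
        top_n = ds.n_genes
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if top_n > ds.n_genes:
        raise ValueError(f"top_n={top_n} exceeds n_genes={ds.n_genes}")
    if criterion not in ("MID", "MIQ"):
        raise ValueError("criterion must be 'MID' or 'MIQ'")

    D = discretize_dataset(ds)
    onehots = [(D == b).astype(np.float64) for b in range(3)]
    yc, ny = _codes(ds.labels)

    relevance = _mi_vector(yc, ny, onehots)
    redundancy_sum = np.zeros(ds.n_genes)
    selected: list[int] = []
    scores: list[float] = []
    available = np.ones(ds.n_genes, dtype=bool)

    for step in range(top_n):
        if step == 0:
            crit = relevance.copy()
        else:
            red = redundancy_sum / len(selected)
            if criterion == "MID":
                crit = relevance - red
            else:
                crit = relevance / (red + 1e-12)
        crit[~available] = -np.inf
        g = int(np.argmax(crit))  # argmax returns the first max: stable
        selected.append(g)
        scores.append(float(crit[g]))
        available[g] = False
        if step < top_n - 1:
            redundancy_sum += _mi_vector(D[:, g].astype(np.int64), 3, onehots)

    return GeneRanking(
        method="mrmr",
        ordered_genes=[ds.gene_ids[g] for g in selected],
        scores=np.array(scores),
        seed=None,
    )


# ---------------------------------------------------------------------------
# MCFS
# ---------------------------------------------------------------------------

def _tree_split_gains(tree) -> list[tuple[int, float, int]]:
    """(feature_index_within_projection, impurity decrease, node size)
    for every internal node of a fitted sklearn tree."""
    t = tree.tree_
    out = []
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        n = t.n_node_samples[node]
        ig = t.impurity[node] - (
            t.n_node_samples[left] * t.impurity[left]
            + t.n_node_samples[right] * t.impurity[right]
        ) / n
        out.append((int(t.feature[node]), float(ig), int(n)))
    return out


def _mean_class_recall(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Unweighted mean of per-class recalls over classes present in y_true."""
    recalls = []
    for cls in np.unique(y_true):
        m = y_true == cls
        recalls.append(float(np.mean(y_pred[m] == cls)))
    return float(np.mean(recalls))


def rank_mcfs(
    ds: ExpressionDataset,
    p: McfsParams | None = None,
    collect: list | None = None,
) -> GeneRanking:
    """Monte Carlo feature selection ranking.

    Builds ``s`` random projections of ``m`` genes; on each, ``t``
    decision trees are fit on bootstrap samples of the cells and scored
    by wAcc — the unweighted mean of per-class recalls on the
    out-of-bag cells. A gene's relative importance accumulates, over
    every split on that gene in every tree,

        RI_g += wAcc^u * IG(node) * (n_node / n_root)^v

    where IG is the impurity decrease of the split. Never-selected
    genes score exactly 0 and sort by gene index.

    ``collect``, when a list, receives one record per tree
    ``(projection_genes, fitted_tree, wacc)`` for independent
    verification of the accumulation.
    """
    p = p or McfsParams()
    m = p.m if p.m is not None else max(1, math.ceil(0.05 * ds.n_genes))
    if m > ds.n_genes:
        raise ValueError(f"m={m} exceeds n_genes={ds.n_genes}")

    rng = np.random.default_rng(p.seed)
    X = ds.values
    y = np.asarray([str(v) for v in ds.labels])
    n = ds.n_cells
    n_boot = max(1, int(round(p.bootstrap_frac * n)))
    min_leaf = max(1, int(round(p.min_leaf_frac * n_boot)))
    ri = np.zeros(ds.n_genes)

    for _ in range(p.s):
        feats = np.sort(rng.choice(ds.n_genes, size=m, replace=False))
        for _ in range(p.t):
            boot = rng.integers(0, n, size=n_boot)
            tree_seed = int(rng.integers(0, 2**31))
            oob = np.setdiff1d(np.arange(n), np.unique(boot), assume_unique=True)
            clf = DecisionTreeClassifier(
                random_state=tree_seed, min_samples_leaf=min_leaf
            )
            clf.fit(X[boot][:, feats], y[boot])
            eval_idx = oob if oob.size else boot
            pred = clf.predict(X[eval_idx][:, feats])
            wacc = _mean_class_recall(y[eval_idx], pred)
            if collect is not None:
                collect.append((feats.copy(), clf, wacc))
            n_root = clf.tree_.n_node_samples[0]
            for local_f, ig, n_node in _tree_split_gains(clf):
                ri[feats[local_f]] += (
                    (wacc**p.u) * ig * (n_node / n_root) ** p.v
                )

    order = np.argsort(-ri, kind="stable")
    return GeneRanking(
        method="mcfs",
        ordered_genes=[ds.gene_ids[g] for g in order],
        scores=ri[order],
        seed=p.seed,
    )


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

_LASSO_BASE_ALPHA = 0.01


def rank_lasso(ds: ExpressionDataset, C: float = 1.0, seed: int = 0) -> GeneRanking:
    """L1-coefficient gene ranking.

    Fits one-vs-rest L1-penalized (lasso) linear models on standardized
    gene values against per-class 0/1 indicators; a gene's score is the
    largest absolute coefficient it attains across class models.
    ``C`` is the inverse regularization strength relative to a base
    penalty of 0.01 (the solver's alpha is 0.01 / C), so smaller C
    means a stronger penalty. The lasso objective averages the loss
    over cells, making the ranking invariant to duplicating the data.
    Zero-coefficient genes sort by gene index. The fit is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    classes = ds.classes
    if len(classes) < 2:
        raise ValueError("rank_lasso requires at least 2 classes")
    if C <= 0:
        raise ValueError("C must be positive")
    Xs = StandardScaler().fit_transform(ds.values)
    y = np.asarray([str(v) for v in ds.labels])
    coef_rows = []
    for cls in classes:
        target = (y == cls).astype(np.float64)
        model = Lasso(alpha=_LASSO_BASE_ALPHA / C, max_iter=5000)
        model.fit(Xs, target)
        coef_rows.append(model.coef_)
    score = np.abs(np.vstack(coef_rows)).max(axis=0)
    order = np.argsort(-score, kind="stable")
    return GeneRanking(
        method="lasso",
        ordered_genes=[ds.gene_ids[g] for g in order],
        scores=score[order],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# GBDT split-count (LightGBM backend)
# ---------------------------------------------------------------------------

def rank_gbdt_split(
    ds: ExpressionDataset,
    n_rounds: int = 100,
    seed: int = 0,
    **lgb_params,
) -> GeneRanking:
    """Split-count gene ranking from a gradient-boosted tree ensemble.

    Trains a multiclass LightGBM model for ``n_rounds`` boosting
    iterations with otherwise-default parameters; a gene's score is
    T_Split — the total number of times it is used to split across all
    trees. T_Gain (the summed split gain) is computed and carried in
    ``aux_scores['gain']`` but does not affect the ordering.
    """
    import lightgbm as lgb

    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if len(ds.classes) < 2:
        raise ValueError("rank_gbdt_split requires at least 2 classes")
    y = np.asarray([str(v) for v in ds.labels])
    params = dict(
        n_estimators=n_rounds,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    params.update(lgb_params)
    clf = lgb.LGBMClassifier(**params)
    clf.fit(ds.values, y)
    split = clf.booster_.feature_importance(importance_type="split").astype(np.float64)
    gain = clf.booster_.feature_importance(importance_type="gain").astype(np.float64)
    order = np.argsort(-split, kind="stable")
    return GeneRanking(
        method="gbdt_split",
        ordered_genes=[ds.gene_ids[g] for g in order],
        scores=split[order],
        seed=seed,
        aux_scores={"gain": gain[order]},
    )


# ---------------------------------------------------------------------------
# permutation feature importance
# ---------------------------------------------------------------------------

def rank_pfi(ds: ExpressionDataset, p: PfiParams | None = None) -> GeneRanking:
    """Permutation-feature-importance gene ranking.

    A random forest f is fit on the full data; the baseline error
    e_base is its misclassification rate on that same data. For each
    gene j and repetition k, column j is shuffled and the error e_{j,k}
    recomputed; the gene's importance is mean_k e_{j,k} / e_base
    (ratio mode). A perfectly fit forest would give e_base = 0, in
    which case e_base is floored at 1/(2 n_cells) to keep ratios
    finite.
    """
    p = p or PfiParams()
    y = np.asarray([str(v) for v in ds.labels])
    if len(np.unique(y)) < 2:
        raise ValueError("rank_pfi requires at least 2 classes")
    rng = np.random.default_rng(p.seed)
    rf = RandomForestClassifier(
        n_estimators=p.n_trees,
        min_samples_leaf=p.min_leaf,
        random_state=child_seed(p.seed, "pfi-forest"),
        n_jobs=1,
    )
    rf.fit(ds.values, y)
    e_base = float(np.mean(rf.predict(ds.values) != y))
    if e_base == 0.0:
        e_base = 1.0 / (2 * ds.n_cells)

    n = ds.n_cells
    # K permuted copies evaluated in one predict call per gene
    X_big = np.tile(ds.values, (p.K, 1))
    y_big = np.tile(y, p.K)
    scores = np.empty(ds.n_genes)
    for j in range(ds.n_genes):
        saved = X_big[:, j].copy()
        for k in range(p.K):
            X_big[k * n : (k + 1) * n, j] = ds.values[rng.permutation(n), j]
        errs = (rf.predict(X_big) != y_big).reshape(p.K, n).mean(axis=1)
        if p.mode == "ratio":
            scores[j] = float(np.mean(errs / e_base))
        else:
            scores[j] = float(np.mean(errs - e_base))
        X_big[:, j] = saved

    order = np.argsort(-scores, kind="stable")
    return GeneRanking(
        method="pfi",
        ordered_genes=[ds.gene_ids[g] for g in order],
        scores=scores[order],
        seed=p.seed,
    )


# ---------------------------------------------------------------------------
# all five
# ---------------------------------------------------------------------------

def rank_all(
    ds: ExpressionDataset,
    seed: int = 0,
    mcfs_params: McfsParams | None = None,
    pfi_params: PfiParams | None = None,
    lasso_C: float = 1.0,
    gbdt_rounds: int = 100,
    mrmr_top_n: int | None = None,
    methods: tuple[str, ...] = RANKER_METHODS,
) -> dict[str, GeneRanking]:
    """Run the requested rankers (default: all five) with per-method seeds
    derived from one global seed; returns rankings keyed by method name."""
    out: dict[str, GeneRanking] = {}
    for method in methods:
        if method == "mrmr":
            out[method] = rank_mrmr(ds, top_n=mrmr_top_n)
        elif method == "mcfs":
            mp = mcfs_params or McfsParams(seed=child_seed(seed, "mcfs"))
            out[method] = rank_mcfs(ds, mp)
        elif method == "lasso":
            out[method] = rank_lasso(ds, C=lasso_C, seed=child_seed(seed, "lasso"))
        elif method == "gbdt_split":
            out[method] = rank_gbdt_split(
                ds, n_rounds=gbdt_rounds, seed=child_seed(seed, "gbdt")
            )
        elif method == "pfi":
            pp = pfi_params or PfiParams(seed=child_seed(seed, "pfi"))
            out[method] = rank_pfi(ds, pp)
        else:
            raise ValueError(f"unknown ranking method {method!r}")
    return out
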