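"""Unit tests for the five rankers, discretization and mutual information."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genesieve import (
    ExpressionDataset,
    McfsParams,
    PfiParams,
    SynthSpec,
    discretize_gene,
    generate_dataset,
    mutual_information,
    rank_all,
    rank_gbdt_split,
    rank_lasso,
    rank_mcfs,
    rank_mrmr,
    rank_pfi,
)
from genesieve.rankers import _tree_split_gains, discretize_dataset


# --------------------------------------------------------------------- oracle

def mi_bruteforce(x, y):
    """Independent double-sum over the joint frequency table."""
    n = len(x)
    total = 0.0
    for a in set(x):
        for b in set(y):
            pxy = sum(1 for xi, yi in zip(x, y) if xi == a and yi == b) / n
            if pxy == 0:
                continue
            px = sum(1 for xi in x if xi == a) / n
            py = sum(1 for yi in y if yi == b) / n
            total += pxy * math.log(pxy / (px * py))
    return total


def mrmr_greedy_oracle(D, y, top_n):
    """Exhaustive greedy MID ordering, recomputing everything per step."""
    G = D.shape[1]
    rel = [mi_bruteforce(list(D[:, j]), list(y)) for j in range(G)]
    selected = []
    while len(selected) < top_n:
        best, best_score = None, -np.inf
        for j in range(G):
            if j in selected:
                continue
            if selected:
                red = np.mean([mi_bruteforce(list(D[:, j]), list(D[:, s]))
                               for s in selected])
                score = rel[j] - red
            else:
                score = rel[j]
            if score > best_score:  # strict: ties keep the earlier index
                best, best_score = j, score
        selected.append(best)
    return selected


# --------------------------------------------------------------- discretize

def test_discretize_constant_gene_is_all_mid():
    assert np.array_equal(discretize_gene([0, 0, 0, 0]), [1, 1, 1, 1])


def test_discretize_single_outlier():
    # mu = 2.5, sigma = sqrt(75/4) ~ 4.33; only 10 > mu + sigma
    assert np.array_equal(discretize_gene([0, 0, 0, 10]), [1, 1, 1, 2])


def test_discretize_symmetric_input_maps_antisymmetrically():
    assert np.array_equal(discretize_gene([-3.0, 0.0, 3.0]), [0, 1, 2])


def test_discretize_rejects_empty_and_nonfinite():
    with pytest.raises(ValueError):
        discretize_gene([])
    with pytest.raises(ValueError):
        discretize_gene([1.0, np.nan])


def test_discretize_dataset_matches_per_gene(small_planted):
    ds, _ = small_planted
    D = discretize_dataset(ds)
    for j in [0, 7, 59]:
        assert np.array_equal(D[:, j], discretize_gene(ds.values[:, j]))


# ----------------------------------------------------------------------- MI

def test_mi_independent_pattern_is_zero():
    assert mutual_information(list("aabb"), list("cdcd")) == pytest.approx(0.0, abs=1e-12)


def test_mi_identity_two_equiprobable_states_is_log2():
    x = list("abababab")
    assert mutual_information(x, x) == pytest.approx(math.log(2), abs=1e-12)


def test_mi_matches_hand_computed_joint_table():
    # joint {(a,c):2, (a,d):1, (b,d):1}:
    # 0.5 ln(4/3) + 0.25 ln(2/3) + 0.25 ln 2 = 0.21576155...
    x = ["a", "a", "a", "b"]
    y = ["c", "c", "d", "d"]
    assert mutual_information(x, y) == pytest.approx(0.2157615543388171, abs=1e-12)


def test_mi_rejects_length_mismatch():
    with pytest.raises(ValueError):
        mutual_information([1, 2], [1, 2, 3])


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                min_size=1, max_size=60))
def test_mi_properties_vs_oracle(pairs):
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    mi = mutual_information(x, y)
    assert mi >= 0
    assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
    assert mi == pytest.approx(mi_bruteforce(x, y), abs=1e-10)
    # MI(x, x) = H(x)
    h = -sum(
        (c / len(x)) * math.log(c / len(x))
        for c in np.unique(x, return_counts=True)[1]
    )
    assert mutual_information(x, x) == pytest.approx(h, abs=1e-10)


# --------------------------------------------------------------------- mRMR

def test_mrmr_matches_exhaustive_greedy_oracle():
    rng = np.random.default_rng(42)
    for trial in range(3):
        n, G = 200, 6
        values = rng.gamma(2.0, 1.0, size=(n, G))
        labels = rng.choice(["A", "B", "C"], size=n)
        ds = ExpressionDataset(
            values=values,
            gene_ids=[f"g{j}" for j in range(G)],
            cell_ids=[f"c{i}" for i in range(n)],
            labels=labels.astype(object),
        )
        ranking = rank_mrmr(ds)
        D = discretize_dataset(ds)
        expected = mrmr_greedy_oracle(D, labels, G)
        assert ranking.ordered_genes == [f"g{j}" for j in expected]


def test_mrmr_planted_gene_ranks_first():
    rng = np.random.default_rng(0)
    n = 300
    labels = np.array(["A"] * 150 + ["B"] * 150, dtype=object)
    values = rng.gamma(2.0, 1.0, size=(n, 8))
    values[:150, 3] += 4.0  # plant gene 3
    ds = ExpressionDataset(
        values=values, gene_ids=[f"g{j}" for j in range(8)],
        cell_ids=[f"c{i}" for i in range(n)], labels=labels,
    )
    assert rank_mrmr(ds).ordered_genes[0] == "g3"


def test_mrmr_redundant_copy_penalized():
    rng = np.random.default_rng(1)
    n = 400
    labels = np.array(["A"] * 200 + ["B"] * 200, dtype=object)
    strong = rng.normal(2.0, 1.0, n) + 3.0 * (labels == "A")
    weak = rng.normal(2.0, 1.0, n) + 1.5 * (labels == "A")
    noise = rng.normal(2.0, 1.0, (n, 2))
    # g0 = strong, g1 = exact copy of strong, g2 = independent weak signal
    values = np.column_stack([strong, strong, weak, noise])
    values -= values.min()
    ds = ExpressionDataset(
        values=values, gene_ids=[f"g{j}" for j in range(5)],
        cell_ids=[f"c{i}" for i in range(n)], labels=labels,
    )
    order = rank_mrmr(ds).ordered_genes
    assert order[0] == "g0"  # tie with g1 broken by index
    assert order.index("g2") < order.index("g1")  # duplicate penalized


def test_mrmr_full_output_is_permutation(small_planted):
    ds, _ = small_planted
    r = rank_mrmr(ds)
    assert sorted(r.ordered_genes) == sorted(ds.gene_ids)


def test_mrmr_rejects_bad_top_n(small_planted):
    ds, _ = small_planted
    with pytest.raises(ValueError):
        rank_mrmr(ds, top_n=0)
    with pytest.raises(ValueError):
        rank_mrmr(ds, top_n=ds.n_genes + 1)


# --------------------------------------------------------------------- MCFS

def test_mcfs_unprojected_gene_scores_zero(small_planted):
    ds, _ = small_planted
    collected = []
    r = rank_mcfs(ds, McfsParams(s=2, t=1, m=3, seed=5), collect=collected)
    projected = set()
    for feats, _, _ in collected:
        projected |= set(feats)
    scores = dict(zip(r.ordered_genes, r.scores))
    for j, g in enumerate(ds.gene_ids):
        if j not in projected:
            assert scores[g] == 0.0


def test_mcfs_u0_v0_reduces_to_total_impurity_decrease(small_planted):
    """With u = v = 0 the RI is the raw impurity decrease summed over
    every split on the gene; verify against direct accumulation over
    the same fitted trees."""
    ds, _ = small_planted
    collected = []
    r = rank_mcfs(ds, McfsParams(s=2, t=1, m=3, u=0.0, v=0.0, seed=9),
                  collect=collected)
    expected = np.zeros(ds.n_genes)
    for feats, tree, _ in collected:
        for local_f, ig, _ in _tree_split_gains(tree):
            expected[feats[local_f]] += ig
    scores = dict(zip(r.ordered_genes, r.scores))
    for j, g in enumerate(ds.gene_ids):
        assert scores[g] == pytest.approx(expected[j], abs=1e-12)


def test_mcfs_scores_non_increasing_and_permutation(small_planted):
    ds, _ = small_planted
    r = rank_mcfs(ds, McfsParams(s=30, t=2, seed=3))
    assert sorted(r.ordered_genes) == sorted(ds.gene_ids)
    assert np.all(np.diff(r.scores) <= 1e-12)


def test_mcfs_rejects_m_larger_than_genes(small_planted):
    ds, _ = small_planted
    with pytest.raises(ValueError):
        rank_mcfs(ds, McfsParams(m=ds.n_genes + 1))


# -------------------------------------------------------------------- LASSO

def test_lasso_null_data_strong_penalty_all_zero():
    ds, _ = generate_dataset(
        SynthSpec(class_sizes=[40, 40], n_genes=30, n_informative=0, seed=2)
    )
    r = rank_lasso(ds, C=0.01)
    assert np.all(r.scores == 0.0)
    assert r.ordered_genes == ds.gene_ids  # tie-broken by input order


def test_lasso_recovers_planted_gene(small_planted):
    ds, truth = small_planted
    r = rank_lasso(ds)
    top = set(r.ordered_genes[: len(truth.informative_genes)])
    assert len(top & truth.informative_genes) >= 4


def test_lasso_invariant_to_duplicating_every_cell(small_planted):
    ds, _ = small_planted
    dup = ExpressionDataset(
        values=np.vstack([ds.values, ds.values]),
        gene_ids=ds.gene_ids,
        cell_ids=list(ds.cell_ids) + [c + "_dup" for c in ds.cell_ids],
        labels=np.concatenate([ds.labels, ds.labels]),
    )
    assert rank_lasso(ds).ordered_genes == rank_lasso(dup).ordered_genes


def test_lasso_rejects_single_class():
    ds = ExpressionDataset(
        values=np.ones((5, 3)), gene_ids=["a", "b", "c"],
        cell_ids=[f"c{i}" for i in range(5)],
        labels=np.array(["X"] * 5, dtype=object),
    )
    with pytest.raises(ValueError):
        rank_lasso(ds)


# --------------------------------------------------------------------- GBDT

def test_gbdt_split_counts_conserved_and_zero_for_unused(small_planted):
    import lightgbm as lgb

    ds, _ = small_planted
    # a constant gene can never be split on
    const = ExpressionDataset(
        values=np.column_stack([ds.values[:, :-1], np.ones(ds.n_cells)]),
        gene_ids=ds.gene_ids[:-1] + ["constant"],
        cell_ids=ds.cell_ids, labels=ds.labels,
    )
    r = rank_gbdt_split(const, n_rounds=20, seed=1, min_child_samples=5)
    # conservation: sum of split counts == total internal nodes over all trees
    clf = lgb.LGBMClassifier(
        n_estimators=20, random_state=1, deterministic=True,
        force_row_wise=True, n_jobs=1, verbose=-1, min_child_samples=5,
    )
    clf.fit(const.values, const.labels.astype(str))
    internal = sum(
        t["num_leaves"] - 1
        for t in clf.booster_.dump_model()["tree_info"]
    )
    assert r.scores.sum() == internal
    scores = dict(zip(r.ordered_genes, r.scores))
    assert scores["constant"] == 0.0
    assert np.all(np.diff(r.scores) <= 0)
    assert "gain" in r.aux_scores and len(r.aux_scores["gain"]) == len(r)


def test_gbdt_rejects_single_class():
    ds = ExpressionDataset(
        values=np.random.default_rng(0).random((30, 4)),
        gene_ids=list("abcd"), cell_ids=[f"c{i}" for i in range(30)],
        labels=np.array(["X"] * 30, dtype=object),
    )
    with pytest.raises(ValueError):
        rank_gbdt_split(ds)


# ---------------------------------------------------------------------- PFI

def test_pfi_null_gene_importance_near_one():
    rng = np.random.default_rng(3)
    n, G = 300, 20
    labels = np.array(["A"] * 150 + ["B"] * 150, dtype=object)
    values = rng.random((n, G))
    # an overlapping (not separable) signal so the baseline error is > 0
    values[:, 0] += 0.8 * (labels == "A")
    ds = ExpressionDataset(
        values=values, gene_ids=[f"g{j}" for j in range(G)],
        cell_ids=[f"c{i}" for i in range(n)], labels=labels,
    )
    r = rank_pfi(ds, PfiParams(K=10, seed=4))
    scores = dict(zip(r.ordered_genes, r.scores))
    # genes 1..19 are independent of labels and of each other
    for j in range(1, G):
        assert scores[f"g{j}"] == pytest.approx(1.0, abs=0.35)
    assert r.ordered_genes[0] == "g0"


def test_pfi_perfect_predictor_ranks_first():
    rng = np.random.default_rng(5)
    n = 200
    labels = np.array(["A"] * 70 + ["B"] * 60 + ["C"] * 70, dtype=object)
    values = rng.random((n, 5))
    codes = {"A": 0.0, "B": 1.0, "C": 2.0}
    values[:, 2] = [codes[l] for l in labels]  # gene 2 encodes the label
    ds = ExpressionDataset(
        values=values, gene_ids=[f"g{j}" for j in range(5)],
        cell_ids=[f"c{i}" for i in range(n)], labels=labels,
    )
    r = rank_pfi(ds, PfiParams(K=5, seed=6))
    assert r.ordered_genes[0] == "g2"
    assert r.scores[0] > r.scores[1]


def test_pfi_fixed_seed_reproducible(small_planted):
    ds, _ = small_planted
    a = rank_pfi(ds, PfiParams(K=2, n_trees=20, seed=8))
    b = rank_pfi(ds, PfiParams(K=2, n_trees=20, seed=8))
    assert a.ordered_genes == b.ordered_genes
    assert np.array_equal(a.scores, b.scores)


def test_pfi_rejects_bad_K():
    with pytest.raises(ValueError):
        PfiParams(K=0)


# ------------------------------------------------------------------ rank_all

def test_rank_all_returns_five_permutations_and_is_deterministic(small_planted):
    ds, _ = small_planted
    kw = dict(
        seed=11,
        mcfs_params=McfsParams(s=20, t=2, seed=1),
        pfi_params=PfiParams(K=2, n_trees=20, seed=2),
        gbdt_rounds=10,
    )
    first = rank_all(ds, **kw)
    second = rank_all(ds, **kw)
    assert set(first) == {"mrmr", "mcfs", "lasso", "gbdt_split", "pfi"}
    for method, r in first.items():
        assert sorted(r.ordered_genes) == sorted(ds.gene_ids)
        assert r.ordered_genes == second[method].ordered_genes


def test_increasing_effect_size_improves_planted_ranks():
    """Median rank position of planted genes never degrades as the
    class separation grows (3-point effect grid, mRMR ranker)."""
    medians = []
    for effect in [0.25, 0.75, 2.0]:
        ranks = []
        for seed in range(5):
            ds, truth = generate_dataset(
                SynthSpec(class_sizes=[60, 80, 60], n_genes=80,
                          n_informative=6, effect_size=effect,
                          dropout_rate=0.5, seed=seed)
            )
            r = rank_mrmr(ds)
            pos = {g: i for i, g in enumerate(r.ordered_genes)}
            ranks.extend(pos[g] for g in truth.informative_genes)
        medians.append(np.median(ranks))
    assert medians[0] >= medians[1] >= medians[2]
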