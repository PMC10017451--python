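"""IFS engine: subset sweep mechanics, selection rules, determinism."""

import numpy as np
import pytest

from genesieve import (
    EvalResult,
    IFSCurve,
    IFSRecord,
    SynthSpec,
    generate_dataset,
    rank_gbdt_split,
    run_ifs,
    run_matrix,
    select_feasible,
    select_optimal,
)


def make_record(size: int, wf1: float) -> IFSRecord:
    ev = EvalResult(
        per_class_precision={}, per_class_recall={}, per_class_f1={},
        accuracy=wf1, macro_f1=wf1, weighted_f1=wf1, mcc=0.0, class_weights={},
    )
    return IFSRecord(subset_size=size, classifier="dt", eval=ev)


def make_curve(sizes_wf1s) -> IFSCurve:
    return IFSCurve(
        ranking_method="test", classifier="dt",
        records=[make_record(s, w) for s, w in sizes_wf1s],
        step=10, cap=5000, folds=10, seed=0,
    )


def feasible_linear_scan_oracle(curve, delta, min_optimal_size):
    """Independent re-derivation of the feasibility rule."""
    opt_i = max(range(len(curve.records)),
                key=lambda i: (curve.records[i].eval.weighted_f1, -i))
    opt = curve.records[opt_i]
    if opt.subset_size <= min_optimal_size:
        return None
    for i, rec in enumerate(curve.records):
        if rec.subset_size >= opt.subset_size:
            break
        if rec.eval.weighted_f1 >= opt.eval.weighted_f1 - delta:
            return i
    return None


@pytest.fixture(scope="module")
def planted_setup():
    ds, truth = generate_dataset(
        SynthSpec(class_sizes=[40, 60, 50], n_genes=60, n_informative=5,
                  effect_size=2.0, dropout_rate=0.4, seed=3)
    )
    ranking = rank_gbdt_split(ds, n_rounds=30, seed=1, min_child_samples=5)
    return ds, truth, ranking


# ------------------------------------------------------------------ run_ifs

def test_subset_sizes_follow_step_and_cap(planted_setup):
    ds, _, ranking = planted_setup
    curve = run_ifs(ds, ranking, "dt", step=10, cap=30, folds=5, seed=1)
    assert curve.subset_sizes == [10, 20, 30]


def test_cap_truncates_to_ranking_length(planted_setup):
    ds, _, ranking = planted_setup
    curve = run_ifs(ds, ranking, "dt", step=25, cap=5000, folds=5, seed=1)
    assert curve.subset_sizes == [25, 50, 60]  # last is |ranking|, not a multiple


def test_curve_is_deterministic_and_pools_every_cell(planted_setup):
    ds, _, ranking = planted_setup
    a = run_ifs(ds, ranking, "dt", step=10, cap=20, folds=5, seed=7)
    b = run_ifs(ds, ranking, "dt", step=10, cap=20, folds=5, seed=7)
    assert a.to_frame().equals(b.to_frame())
    # pooled evaluation covers exactly the original cells: class weights
    # recomputed from the full label vector
    w = a.records[0].eval.class_weights
    counts = ds.class_counts()
    for cls, cnt in counts.items():
        assert w[cls] == pytest.approx(cnt / ds.n_cells)


def test_planted_subset_beats_chance_and_contains_signal(planted_setup):
    ds, truth, ranking = planted_setup
    curve = run_ifs(ds, ranking, "rf", step=10, cap=20, folds=5, seed=2,
                    rf_trees=50)
    opt = curve.optimal
    assert opt.eval.weighted_f1 > 0.8
    top = set(ranking.top(opt.subset_size))
    assert len(top & truth.informative_genes) >= 4


def test_run_ifs_rejections(planted_setup):
    ds, _, ranking = planted_setup
    with pytest.raises(ValueError, match="folds"):
        run_ifs(ds, ranking, "dt", folds=50)  # classes smaller than folds
    with pytest.raises(ValueError, match="step"):
        run_ifs(ds, ranking, "dt", step=100, folds=5)
    with pytest.raises(ValueError, match="classifier"):
        run_ifs(ds, ranking, "svm", folds=5)


# ---------------------------------------------------------------- selection

def test_select_optimal_prefers_last_when_increasing():
    curve = make_curve([(10, 0.5), (20, 0.6), (30, 0.7)])
    assert select_optimal(curve) == 2


def test_select_optimal_tie_goes_to_smaller_subset():
    curve = make_curve([(10, 0.5), (20, 0.7), (30, 0.7)])
    assert select_optimal(curve) == 1


def test_select_optimal_single_record_and_empty():
    assert select_optimal(make_curve([(10, 0.4)])) == 0
    with pytest.raises(ValueError):
        select_optimal(make_curve([]))


def test_feasible_reproduces_worked_curve():
    # optimal DT at 2960 genes scored 0.853; the 30-gene subset scored
    # 0.845 — a 0.008 gap, within delta 0.015, so 30 is feasible
    sizes = [10, 20, 30] + list(range(40, 3001, 10))
    wf1 = {10: 0.800, 20: 0.820, 30: 0.845, 2960: 0.853}
    curve = make_curve([(s, wf1.get(s, 0.830)) for s in sizes])
    curve.optimal_index = select_optimal(curve)
    assert curve.optimal.subset_size == 2960
    fi = select_feasible(curve, delta=0.015, min_optimal_size=100)
    assert curve.records[fi].subset_size == 30
    assert curve.optimal.eval.weighted_f1 - curve.records[fi].eval.weighted_f1 \
        == pytest.approx(0.008, abs=1e-12)


def test_feasible_none_for_small_optimum():
    curve = make_curve([(10, 0.8), (20, 0.85), (30, 0.9)])
    curve.optimal_index = select_optimal(curve)
    assert select_feasible(curve, delta=0.015, min_optimal_size=100) is None


def test_feasible_flat_curve_picks_first_record():
    curve = make_curve([(s, 0.8) for s in range(10, 201, 10)])
    curve.optimal_index = select_optimal(curve)
    # tie rule puts the optimum at 10 genes <= 100: no feasible sought
    assert curve.optimal.subset_size == 10
    assert select_feasible(curve) is None
    # force the optimum to the cap: every smaller record qualifies
    curve.records[-1] = make_record(200, 0.801)
    curve.optimal_index = select_optimal(curve)
    assert select_feasible(curve, delta=0.015, min_optimal_size=100) == 0


def test_feasible_rejects_negative_delta():
    curve = make_curve([(10, 0.8)])
    curve.optimal_index = 0
    with pytest.raises(ValueError):
        select_feasible(curve, delta=-0.1)


def test_feasible_matches_linear_scan_oracle_on_random_curves():
    rng = np.random.default_rng(0)
    for _ in range(30):
        n = rng.integers(3, 25)
        sizes = [10 * (i + 1) for i in range(n)]
        curve = make_curve(list(zip(sizes, rng.uniform(0.3, 0.95, n).round(3))))
        curve.optimal_index = select_optimal(curve)
        delta = float(rng.uniform(0.0, 0.1))
        mos = int(rng.choice([0, 50, 100]))
        assert select_feasible(curve, delta, mos) == \
            feasible_linear_scan_oracle(curve, delta, mos)


# --------------------------------------------------------------- run_matrix

def test_run_matrix_single_pair(planted_setup):
    ds, _, ranking = planted_setup
    curves = run_matrix(
        ds, {"gbdt_split": ranking}, classifiers=("dt",),
        step=10, cap=20, folds=5, seed=1,
    )
    assert list(curves) == [("gbdt_split", "dt")]
    assert curves[("gbdt_split", "dt")].optimal_index is not None
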