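"""End-to-end orchestration: simulate/load → rank → IFS → rules → consensus.

One :class:`PipelineConfig` (or flat key=value config file) drives the
whole run. A single global seed deterministically derives every
per-stage seed, so re-running the same config reproduces every result
file byte-for-byte, and any stage can be re-run standalone with its
derived seed.

Outputs written to the configured directory:

* ``ranking_<method>.tsv`` — one per ranking method
* ``curve_<method>_<classifier>.tsv`` — one per (ranker, classifier)
* ``summary.tsv`` — optimal and starred feasible rows, one table
* ``rules_<method>.txt`` / ``rules_<method>.tsv`` — decision-tree rules
  mined from each ranker's optimal DT subset
* ``consensus_membership.tsv`` / ``consensus_regions.tsv``
* ``manifest.json`` — config, derived seeds, package versions
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from . import io as gio
from .consensus import venn_intersections
from .dataset import ExpressionDataset
from .ifs import IFSCurve, run_matrix, summarize_matrix
from .rankers import (
    RANKER_METHODS,
    GeneRanking,
    McfsParams,
    PfiParams,
    child_seed,
    rank_all,
)
from .resampling import smote_balance
from .rules import RuleSet, extract_rules, write_rules_text
from .synth import SynthSpec, generate_dataset


class StageError(RuntimeError):
    """Failure of one named pipeline stage; earlier outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``synth`` / (``matrix_path`` + ``labels_path``) must
    be provided.
    """

    outdir: str = "genesieve_out"
    seed: int = 0
    # input: synthetic spec or file paths
    synth: SynthSpec | None = None
    matrix_path: str | None = None
    matrix_format: str = "mtx"
    labels_path: str | None = None
    # rankers
    methods: tuple[str, ...] = RANKER_METHODS
    mrmr_top_n: int | None = None
    mcfs: McfsParams | None = None
    pfi: PfiParams | None = None
    lasso_C: float = 1.0
    gbdt_rounds: int = 100
    # IFS
    classifiers: tuple[str, ...] = ("dt", "rf")
    step: int = 10
    cap: int = 5000
    folds: int = 10
    smote_k: int = 5
    delta: float = 0.015
    min_optimal_size: int = 100
    rf_trees: int = 100
    # rule mining
    min_support: int = 1

    def __post_init__(self) -> None:
        has_files = self.matrix_path is not None and self.labels_path is not None
        if (self.synth is None) == (not has_files):
            raise ValueError(
                "exactly one of a SynthSpec or matrix_path+labels_path is required"
            )
        bad = set(self.methods) - set(RANKER_METHODS)
        if bad:
            raise ValueError(f"unknown ranking methods: {sorted(bad)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _load_input(cfg: PipelineConfig) -> ExpressionDataset:
    if cfg.synth is not None:
        ds, _ = generate_dataset(cfg.synth)
        return ds
    return gio.read_expression(cfg.matrix_path, cfg.matrix_format, cfg.labels_path)


def mine_rules_for_curve(
    ds: ExpressionDataset,
    ranking: GeneRanking,
    subset_size: int,
    smote_k: int,
    seed: int,
    min_support: int = 1,
) -> RuleSet:
    """Train the rule-generating decision tree and extract its rules.

    The tree is fit on the full dataset, SMOTE-balanced, restricted to
    the top ``subset_size`` genes of the ranking — the subset the
    optimal DT classifier used.
    """
    genes = ranking.top(subset_size)
    sub = ds.subset_genes(genes)
    bal = smote_balance(
        sub.values,
        np.array([str(v) for v in ds.labels]),
        k=smote_k,
        seed=child_seed(seed, "rules-smote"),
    )
    tree = DecisionTreeClassifier(
        criterion="gini", random_state=child_seed(seed, "rules-tree")
    )
    tree.fit(bal.values, bal.labels.astype(str))
    rs = extract_rules(tree, genes, min_support=min_support)
    rs.source = (ranking.method, subset_size)
    return rs


def consensus_sets_from_curves(
    curves: dict[tuple[str, str], IFSCurve],
    rankings: dict[str, GeneRanking],
) -> dict[str, set[str]]:
    """Per-method gene sets for the consensus stage.

    For each ranking method, takes the genes of the feasible RF
    classifier when one exists, else the optimal RF classifier.
    """
    sets: dict[str, set[str]] = {}
    for method, ranking in rankings.items():
        curve = curves.get((method, "rf"))
        if curve is None:
            continue
        rec = curve.feasible if curve.feasible is not None else curve.optimal
        sets[method] = set(ranking.top(rec.subset_size))
    return sets


def _write_frame(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run simulate/load → rank → IFS → rules → consensus, writing a
    report bundle to ``cfg.outdir``. Returns the in-memory artifacts
    and the paths written."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    try:
        ds = _load_input(cfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError("input", exc) from exc

    # --- rank ---
    try:
        mcfs = cfg.mcfs or McfsParams(seed=child_seed(cfg.seed, "mcfs"))
        pfi = cfg.pfi or PfiParams(seed=child_seed(cfg.seed, "pfi"))
        rankings = rank_all(
            ds,
            seed=cfg.seed,
            mcfs_params=mcfs,
            pfi_params=pfi,
            lasso_C=cfg.lasso_C,
            gbdt_rounds=cfg.gbdt_rounds,
            mrmr_top_n=cfg.mrmr_top_n,
            methods=cfg.methods,
        )
        for method, ranking in rankings.items():
            p = out / f"ranking_{method}.tsv"
            gio.write_ranking(ranking, p)
            paths[f"ranking_{method}"] = p
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("rank", exc) from exc

    # --- IFS ---
    try:
        curves = run_matrix(
            ds,
            rankings,
            classifiers=cfg.classifiers,
            step=cfg.step,
            cap=cfg.cap,
            folds=cfg.folds,
            smote_k=cfg.smote_k,
            seed=cfg.seed,
            rf_trees=cfg.rf_trees,
            delta=cfg.delta,
            min_optimal_size=cfg.min_optimal_size,
        )
        for (method, clf), curve in curves.items():
            p = out / f"curve_{method}_{clf}.tsv"
            _write_frame(curve.to_frame(), p)
            paths[f"curve_{method}_{clf}"] = p
        summary = summarize_matrix(curves)
        p = out / "summary.tsv"
        _write_frame(summary, p)
        paths["summary"] = p
    except Exception as exc:  # noqa: BLE001
        raise StageError("ifs", exc) from exc

    # --- rules (from each ranker's optimal DT subset) ---
    rule_sets: dict[str, RuleSet] = {}
    if "dt" in cfg.classifiers:
        try:
            for method in sorted(rankings):
                curve = curves[(method, "dt")]
                rs = mine_rules_for_curve(
                    ds,
                    rankings[method],
                    curve.optimal.subset_size,
                    smote_k=cfg.smote_k,
                    seed=child_seed(cfg.seed, "rules", method),
                    min_support=cfg.min_support,
                )
                rule_sets[method] = rs
                pt = out / f"rules_{method}.txt"
                write_rules_text(rs, pt)
                paths[f"rules_{method}_txt"] = pt
                pv = out / f"rules_{method}.tsv"
                _write_frame(rs.to_frame(), pv)
                paths[f"rules_{method}_tsv"] = pv
        except Exception as exc:  # noqa: BLE001
            raise StageError("rules", exc) from exc

    # --- consensus over RF-selected gene sets ---
    try:
        sets = consensus_sets_from_curves(curves, rankings)
        report = venn_intersections(sets) if sets else None
        if report is not None:
            p = out / "consensus_membership.tsv"
            _write_frame(report.membership_frame(), p)
            paths["consensus_membership"] = p
            p = out / "consensus_regions.tsv"
            _write_frame(report.region_frame(), p)
            paths["consensus_regions"] = p
    except Exception as exc:  # noqa: BLE001
        raise StageError("consensus", exc) from exc

    # --- manifest ---
    try:
        import lightgbm
        import sklearn

        from . import __version__

        cfg_dict = cfg.to_dict()
        cfg_dict.pop("outdir", None)  # a location, not a run parameter
        manifest = {
            "config": json.loads(json.dumps(cfg_dict, default=str)),
            "derived_seeds": {
                "mcfs": child_seed(cfg.seed, "mcfs"),
                "pfi": child_seed(cfg.seed, "pfi"),
                "lasso": child_seed(cfg.seed, "lasso"),
                "gbdt": child_seed(cfg.seed, "gbdt"),
                "ifs": {
                    f"{m}/{c}": child_seed(cfg.seed, "ifs", m, c)
                    for m in sorted(rankings)
                    for c in cfg.classifiers
                },
            },
            "versions": {
                "genesieve": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
                "lightgbm": lightgbm.__version__,
            },
            "n_cells": ds.n_cells,
            "n_genes": ds.n_genes,
            "class_counts": ds.class_counts(),
        }
        p = out / "manifest.json"
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["manifest"] = p
    except Exception as exc:  # noqa: BLE001
        raise StageError("manifest", exc) from exc

    return {
        "dataset": ds,
        "rankings": rankings,
        "curves": curves,
        "rule_sets": rule_sets,
        "consensus": report,
        "paths": paths,
    }


# ---------------------------------------------------------------------------
# flat key=value config files
# ---------------------------------------------------------------------------

_INT_KEYS = {
    "seed", "step", "cap", "folds", "smote_k", "min_optimal_size",
    "rf_trees", "gbdt_rounds", "min_support", "mrmr_top_n",
    "synth.n_genes", "synth.n_informative", "synth.seed",
    "mcfs.s", "mcfs.t", "mcfs.m", "mcfs.seed", "pfi.K", "pfi.seed",
    "pfi.n_trees",
}
_FLOAT_KEYS = {
    "delta", "lasso_C", "synth.effect_size", "synth.base_mean",
    "synth.dispersion", "synth.dropout_rate", "mcfs.u", "mcfs.v",
    "mcfs.bootstrap_frac",
}
_LIST_KEYS = {"methods", "classifiers", "synth.class_sizes", "synth.class_names"}


def parse_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file into a PipelineConfig.

    Lists are comma-separated; nested synth/mcfs/pfi parameters use
    dotted keys (``synth.n_genes = 500``). Lines starting with ``#``
    are comments.
    """
    raw: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()

    def convert(key: str, val: str):
        if key in _INT_KEYS:
            return int(val)
        if key in _FLOAT_KEYS:
            return float(val)
        if key in _LIST_KEYS:
            items = [v.strip() for v in val.split(",") if v.strip()]
            if key == "synth.class_sizes":
                return [int(v) for v in items]
            return tuple(items)
        return val

    top: dict = {}
    synth_kw: dict = {}
    mcfs_kw: dict = {}
    pfi_kw: dict = {}
    for key, val in raw.items():
        cval = convert(key, val)
        if key.startswith("synth."):
            synth_kw[key[len("synth."):]] = cval
        elif key.startswith("mcfs."):
            mcfs_kw[key[len("mcfs."):]] = cval
        elif key.startswith("pfi."):
            pfi_kw[key[len("pfi."):]] = cval
        else:
            top[key] = cval
    if synth_kw or top.pop("input", None) == "synth":
        top["synth"] = SynthSpec(**synth_kw)
    if mcfs_kw:
        top["mcfs"] = McfsParams(**mcfs_kw)
    if pfi_kw:
        top["pfi"] = PfiParams(**pfi_kw)
    return PipelineConfig(**top)
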