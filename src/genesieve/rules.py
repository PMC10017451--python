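"""If-then classification rules mined from a trained decision tree.

Every root-to-leaf path of a CART tree is a conjunction of threshold
predicates on gene expression (``gene <= t`` on the left branch,
``gene > t`` on the right) ending in the leaf's majority class.
Conditions on the same gene along a path are merged to the tightest
interval, so each rule holds at most one upper and one lower bound per
gene. The rules tile the feature space: any expression vector
satisfies exactly one rule, and applying the rules reproduces the
tree's own predictions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier


@dataclass
class Rule:
    """Conjunction of (gene, <=/>, threshold) predicates with an outcome."""

    predicates: list[tuple[str, str, float]]
    predicted_class: str
    support: int
    purity: float

    def matches(self, sample: dict[str, float]) -> bool:
        for gene, cmp, thr in self.predicates:
            v = sample[gene]
            if cmp == "<=":
                if not v <= thr:
                    return False
            elif cmp == ">":
                if not v > thr:
                    return False
            else:
                raise ValueError(f"bad comparator {cmp!r}")
        return True

    def __str__(self) -> str:
        if not self.predicates:
            cond = "TRUE"
        else:
            cond = " and ".join(
                f"[{g} {c} {t:.2f}]" for g, c, t in self.predicates
            )
        return f"{cond} -> {self.predicted_class} (support {self.support})"


@dataclass
class RuleSet:
    """All rules of one tree, with per-class counts and provenance."""

    rules: list[Rule]
    class_counts: dict[str, int]
    source: tuple[str, int] | None = None  # (ranking_method, subset_size)

    def __len__(self) -> int:
        return len(self.rules)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid, rule in enumerate(self.rules):
            if not rule.predicates:
                rows.append(
                    {
                        "rule_id": rid,
                        "predicate_index": -1,
                        "gene": "",
                        "cmp": "",
                        "threshold": np.nan,
                        "class": rule.predicted_class,
                        "support": rule.support,
                        "purity": rule.purity,
                    }
                )
            for pi, (g, c, t) in enumerate(rule.predicates):
                rows.append(
                    {
                        "rule_id": rid,
                        "predicate_index": pi,
                        "gene": g,
                        "cmp": c,
                        "threshold": t,
                        "class": rule.predicted_class,
                        "support": rule.support,
                        "purity": rule.purity,
                    }
                )
        return pd.DataFrame(rows)


def _merge_path(path: list[tuple[str, str, float]]) -> list[tuple[str, str, float]]:
    """Tighten same-gene conditions: keep min upper bound, max lower bound.

    Order of first appearance along the path is preserved.
    """
    upper: dict[str, float] = {}
    lower: dict[str, float] = {}
    order: list[tuple[str, str]] = []
    for gene, cmp, thr in path:
        key = (gene, cmp)
        if cmp == "<=":
            if gene not in upper or thr < upper[gene]:
                upper[gene] = thr
        else:
            if gene not in lower or thr > lower[gene]:
                lower[gene] = thr
        if key not in order:
            order.append(key)
    return [
        (g, c, upper[g] if c == "<=" else lower[g]) for g, c in order
    ]


def extract_rules(
    tree: DecisionTreeClassifier,
    gene_ids: list[str],
    class_names: list[str] | None = None,
    min_support: int = 1,
) -> RuleSet:
    """Extract one rule per leaf of a fitted decision tree.

    ``gene_ids`` names the feature columns the tree was trained on;
    ``class_names`` overrides the tree's own class labels. Rules with
    support below ``min_support`` are dropped from the report (default
    keeps everything).
    """
    try:
        t = tree.tree_
    except AttributeError as exc:
        raise ValueError("tree is not fitted") from exc
    classes = (
        [str(c) for c in class_names]
        if class_names is not None
        else [str(c) for c in tree.classes_]
    )

    rules: list[Rule] = []

    def walk(node: int, path: list[tuple[str, str, float]]) -> None:
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            counts = t.value[node].ravel()
            cls = classes[int(np.argmax(counts))]
            support = int(t.n_node_samples[node])
            purity = float(counts.max() / counts.sum()) if counts.sum() else 0.0
            rules.append(
                Rule(
                    predicates=_merge_path(path),
                    predicted_class=cls,
                    support=support,
                    purity=purity,
                )
            )
            return
        gene = gene_ids[int(t.feature[node])]
        thr = float(t.threshold[node])
        walk(left, path + [(gene, "<=", thr)])
        walk(right, path + [(gene, ">", thr)])

    walk(0, [])
    kept = [r for r in rules if r.support >= min_support]
    counts: dict[str, int] = {c: 0 for c in classes}
    for r in kept:
        counts[r.predicted_class] += 1
    return RuleSet(rules=kept, class_counts=counts)


def apply_rules(rs: RuleSet, sample: dict[str, float]) -> str:
    """Predict a sample's class with the unique rule it satisfies.

    Raises if no rule or more than one rule fires — either indicates a
    rule-extraction inconsistency, since a tree's leaves partition the
    feature space.
    """
    hits = [r for r in rs.rules if r.matches(sample)]
    if len(hits) != 1:
        raise ValueError(
            f"expected exactly one matching rule, found {len(hits)} "
            "(rule set does not tile the feature space)"
        )
    return hits[0].predicted_class


def write_rules_text(rs: RuleSet, path) -> None:
    """Human-readable rules file, thresholds rounded to 2 decimals."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rid, rule in enumerate(rs.rules):
            fh.write(f"Rule {rid}: {rule}\n")
        fh.write("\n")
        for cls in sorted(rs.class_counts):
            fh.write(f"# rules predicting {cls}: {rs.class_counts[cls]}\n")
        fh.write(f"# total rules: {len(rs.rules)}\n")
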