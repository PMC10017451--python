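"""Mine human-readable if-then classification rules from a decision
tree trained on the optimal gene subset.

Each rule is the conjunction of expression thresholds along one
root-to-leaf path; together the rules tile the feature space, so every
cell satisfies exactly one of them.
"""

from genesieve import SynthSpec, generate_dataset, rank_gbdt_split, run_ifs
from genesieve.pipeline import mine_rules_for_curve

ds, _ = generate_dataset(
    SynthSpec(class_sizes=[40, 80, 60], n_genes=50, n_informative=5,
              effect_size=2.5, dropout_rate=0.4, seed=11)
)
ranking = rank_gbdt_split(ds, n_rounds=30, seed=3, min_child_samples=5)
curve = run_ifs(ds, ranking, "dt", step=10, cap=30, folds=5, seed=3)
opt_size = curve.optimal.subset_size
print(f"optimal DT subset: top {opt_size} genes "
      f"(weighted F1 {curve.optimal.eval.weighted_f1:.3f})\n")

rules = mine_rules_for_curve(ds, ranking, opt_size, smote_k=5, seed=3)
for i, rule in enumerate(rules.rules[:5]):
    print(f"Rule {i}: {rule}")
print(f"... {len(rules)} rules in total")
print(f"rules per class: {rules.class_counts}")
print("\nSupport counts the SMOTE-balanced training rows that reach each "
      "leaf; thresholds are log-normalized expression cutoffs.")
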