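"""Generate a labeled expression dataset with planted signal genes and
rank all genes with the five importance algorithms.

Prints, for each ranker, how many of the planted genes appear in its
top 10 — on this easy setting a good ranker should recover most of
them.
"""

from genesieve import (
    McfsParams,
    PfiParams,
    SynthSpec,
    generate_dataset,
    rank_gbdt_split,
    rank_lasso,
    rank_mcfs,
    rank_mrmr,
    rank_pfi,
)

spec = SynthSpec(
    class_sizes=[50, 100, 80],   # three imbalanced vaccination-strategy classes
    n_genes=60,
    n_informative=5,             # planted class-discriminative genes
    effect_size=2.0,             # mean log-expression shift between classes
    dropout_rate=0.5,            # half the values are zeroed, as in sparse scRNA-seq
    seed=1,
)
ds, truth = generate_dataset(spec)
print(f"dataset: {ds.n_cells} cells x {ds.n_genes} genes, "
      f"classes {ds.class_counts()}")
print(f"planted genes: {sorted(truth.informative_genes)}\n")

rankings = {
    "mrmr": rank_mrmr(ds),
    "mcfs": rank_mcfs(ds, McfsParams(seed=2)),
    "lasso": rank_lasso(ds),
    "gbdt_split": rank_gbdt_split(ds, n_rounds=30, seed=2, min_child_samples=5),
    "pfi": rank_pfi(ds, PfiParams(seed=2)),
}
for method, r in rankings.items():
    top10 = r.ordered_genes[:10]
    hits = len(truth.informative_genes & set(top10))
    print(f"{method:>10}: {hits}/5 planted genes in its top 10 "
          f"(leader {top10[0]}, score {r.scores[0]:.3f})")

print("\nEach line shows one ranker's recovery of the planted signal; "
      "5/5 means the ranking put every truly discriminative gene first.")
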