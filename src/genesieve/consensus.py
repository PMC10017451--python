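"""Cross-ranker consensus: Venn-style intersection of selected gene sets.

The gene subsets selected for each ranking method (the feasible random
forest subset when one exists, else the optimal one) are decomposed
into their exact intersection regions — one region per non-empty
membership pattern over the methods. Genes supported by at least
``consensus_min`` methods (default 3 of 5) are reported as consensus
genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd


@dataclass
class ConsensusReport:
    """Per-method gene sets with their full overlap decomposition."""

    per_method_sets: dict[str, set[str]]
    region_counts: dict[frozenset, int]
    membership_table: dict[str, frozenset]
    consensus_min: int = 3

    @property
    def consensus_genes(self) -> list[str]:
        """Genes supported by >= consensus_min methods, most-supported first."""
        return sorted(
            (g for g, m in self.membership_table.items() if len(m) >= self.consensus_min),
            key=lambda g: (-len(self.membership_table[g]), g),
        )

    def membership_frame(self) -> pd.DataFrame:
        methods = sorted(self.per_method_sets)
        rows = []
        for gene in sorted(
            self.membership_table,
            key=lambda g: (-len(self.membership_table[g]), g),
        ):
            mem = self.membership_table[gene]
            row: dict = {"gene": gene}
            for m in methods:
                row[m] = int(m in mem)
            row["support"] = len(mem)
            rows.append(row)
        return pd.DataFrame(rows)

    def region_frame(self) -> pd.DataFrame:
        rows = []
        for region, count in sorted(
            self.region_counts.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
        ):
            rows.append({"methods": "&".join(sorted(region)), "n_genes": count})
        return pd.DataFrame(rows)


def venn_intersections(sets: dict[str, set[str]], consensus_min: int = 3) -> ConsensusReport:
    """Exact region decomposition of 2–5 named gene sets.

    Each gene in the union is assigned to exactly one region — the
    frozenset of methods whose sets contain it — so region counts sum
    to the union size. Region counts are invariant to input ordering.
    """
    if not sets:
        raise ValueError("at least one non-empty set is required")
    nonempty = {m: set(s) for m, s in sets.items() if s}
    if not nonempty:
        raise ValueError("all sets are empty")

    membership: dict[str, frozenset] = {}
    for gene in set().union(*nonempty.values()):
        membership[gene] = frozenset(m for m, s in nonempty.items() if gene in s)
    regions: dict[frozenset, int] = {}
    for mem in membership.values():
        regions[mem] = regions.get(mem, 0) + 1
    return ConsensusReport(
        per_method_sets=nonempty,
        region_counts=regions,
        membership_table=membership,
        consensus_min=consensus_min,
    )


def pairwise_intersection_size(report: ConsensusReport, a: str, b: str) -> int:
    """|A ∩ B| reconstructed from the region decomposition."""
    return sum(
        count
        for region, count in report.region_counts.items()
        if a in region and b in region
    )
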