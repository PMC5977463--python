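"""Clustering of tree structures by topology pattern (CTS grouping).

Reactions whose trees share one topology pattern — same nesting of pairs,
loners and rule markers, compound identities ignored — form a cluster of
tree structures (CTS).  Clusters are ranked by descending size (ties by
lexicographic pattern) and labelled by the rules appearing in the
pattern: Balance (only ``!``), Count (only ``!!``), or Count-Balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

import pandas as pd

from .rsf import BALANCE, COUNT, Internal, TreeStructure, parse_rsf, topology_pattern

__all__ = ["ClusterOfTrees", "cluster_trees", "rule_label", "clusters_to_table",
           "write_clusters_tsv"]


@dataclass(frozen=True)
class ClusterOfTrees:
    cts_id: str
    pattern: str
    member_reaction_ids: tuple[str, ...]
    rule_label: str

    @property
    def size(self) -> int:
        return len(self.member_reaction_ids)


def _collect_rules(node) -> set[str]:
    if isinstance(node, Internal):
        return ({node.rule} | _collect_rules(node.left)
                | _collect_rules(node.right))
    return set()


def rule_label(pattern: str) -> str:
    """Label a pattern by the rules its markers record.

    ``Balance`` for only ``!`` markers, ``Count`` for only ``!!``,
    ``Count-Balance`` for both.  A markerless pattern (a bare pair tip,
    possible only for unfiltered one-to-one reactions) counts as Balance.
    """
    rules = _collect_rules(parse_rsf(pattern, mode="pattern"))
    if rules == {COUNT}:
        return "Count"
    if rules == {BALANCE, COUNT}:
        return "Count-Balance"
    return "Balance"


def cluster_trees(trees: Iterable[TreeStructure]) -> list[ClusterOfTrees]:
    """Partition trees by topology pattern into ranked clusters.

    Deterministic under permutation of the input: members are sorted by
    reaction id, clusters by (-size, pattern), and ``cts_id`` is assigned
    by rank starting at CTS-1.
    """
    groups: dict[str, list[str]] = {}
    for tree in trees:
        groups.setdefault(topology_pattern(tree), []).append(tree.reaction_id)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        ClusterOfTrees(f"CTS-{rank}", pattern, tuple(sorted(members)),
                       rule_label(pattern))
        for rank, (pattern, members) in enumerate(ordered, start=1)
    ]


def clusters_to_table(clusters: Iterable[ClusterOfTrees]) -> pd.DataFrame:
    """Cluster census as a table: id, pattern, size, rule label, members."""
    return pd.DataFrame(
        [
            {
                "cts_id": c.cts_id,
                "pattern": c.pattern,
                "size": c.size,
                "rule_label": c.rule_label,
                "member_reaction_ids": ";".join(c.member_reaction_ids),
            }
            for c in clusters
        ],
        columns=["cts_id", "pattern", "size", "rule_label",
                 "member_reaction_ids"],
    )


def write_clusters_tsv(clusters: Iterable[ClusterOfTrees],
                       handle: TextIO) -> None:
    clusters_to_table(clusters).to_csv(handle, sep="\t", index=False)
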