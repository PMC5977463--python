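"""Enzyme-class (EC number) enrichment within tree-topology clusters.

Each reaction carries zero or more EC numbers; at a chosen level (first
one, two or three dot-separated fields) a reaction contributes one *EC
assignment* per distinct class.  For every eligible cluster x observed
class, a 2x2 contingency table

    a: assignments of the class inside the cluster
    b: other assignments inside the cluster
    c: assignments of the class outside the cluster
    d: other assignments outside the cluster

is tested with the two-sided Fisher exact test; p-values are adjusted by
Benjamini-Hochberg across all tests at that level, and the effect size
is the (optionally Haldane-Anscombe-corrected) odds ratio (a/b)/(c/d).
A record is flagged enriched when FDR < 0.05 and log odds >= 0.5.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterOfTrees

__all__ = [
    "ContingencyTable",
    "EnrichmentRecord",
    "ecn_prefix",
    "build_contingency",
    "fisher_two_sided",
    "bh_adjust",
    "odds_ratio",
    "enrich_all",
    "records_to_table",
    "write_enrichment_tsv",
    "plot_enrichment_dotplot",
]

_ECN = re.compile(r"^\d+(\.(\d+|-)){0,3}$")


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentRecord:
    cts_id: str
    ecn_class: str
    level: int
    table: ContingencyTable
    p_value: float
    fdr: float
    odds_ratio: float
    log_odds: float
    enriched: bool


def ecn_prefix(ecn: str, level: int) -> str:
    """First ``level`` dot-separated fields of an EC number.

    ``("1.13.11.2", 3) -> "1.13.11"``.  A dash or missing field within
    the requested prefix is an error naming the offending EC number.
    """
    if not 1 <= level <= 3:
        raise ValueError(f"level must be 1..3, got {level}")
    if not _ECN.match(ecn):
        raise ValueError(f"malformed EC number {ecn!r}")
    fields = ecn.split(".")
    if len(fields) < level:
        raise ValueError(f"EC number {ecn!r} too short for level {level}")
    prefix = fields[:level]
    if "-" in prefix:
        raise ValueError(f"EC number {ecn!r} undefined at level {level}")
    return ".".join(prefix)


def build_contingency(
    assignments: Mapping[str, Iterable[str]],
    clusters: Sequence[ClusterOfTrees],
    cts_id: str,
    ecn_class: str,
) -> ContingencyTable:
    """2x2 table of EC assignments for one cluster x class.

    ``assignments`` maps reaction id to its set of EC classes at the
    tested level (reactions without any EC must be excluded upstream).
    The universe is every (reaction, class) assignment over all clustered
    reactions.
    """
    cluster = next((c for c in clusters if c.cts_id == cts_id), None)
    if cluster is None:
        raise ValueError(f"unknown cluster id {cts_id!r}")
    members = set(cluster.member_reaction_ids)
    a = b = c = d = 0
    for other in clusters:
        for rid in other.member_reaction_ids:
            for klass in set(assignments.get(rid, ())):
                inside = rid in members
                hit = klass == ecn_class
                if inside and hit:
                    a += 1
                elif inside:
                    b += 1
                elif hit:
                    c += 1
                else:
                    d += 1
    return ContingencyTable(a, b, c, d)


def fisher_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: the total hypergeometric probability of
    all margin-preserving tables no more likely than the observed one.
    An all-zero table returns 1 by convention."""
    if table.total == 0:
        return 1.0
    _, p = fisher_exact([[table.a, table.b], [table.c, table.d]],
                        alternative="two-sided")
    return float(min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    if len(p_values) == 0:
        return []
    _, adjusted, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(p) for p in adjusted]


def odds_ratio(
    table: ContingencyTable,
    zero_correction: bool | None = None,
    log_base: str = "e",
) -> tuple[float, float]:
    """(a/b)/(c/d) and its logarithm.

    ``zero_correction=None`` applies the Haldane-Anscombe +0.5 correction
    exactly when some cell is zero; True/False force it on/off.  The log
    is natural by default (``log_base="10"`` switches).
    """
    cells = [float(table.a), float(table.b), float(table.c), float(table.d)]
    if zero_correction is None:
        zero_correction = any(x == 0 for x in cells)
    if zero_correction:
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    if 0.0 in (b, c, d, a):
        raise ValueError("zero cell without correction")
    ratio = (a / b) / (c / d)
    log_odds = math.log10(ratio) if log_base == "10" else math.log(ratio)
    return ratio, log_odds


def enrich_all(
    assignments: Mapping[str, Iterable[str]],
    clusters: Sequence[ClusterOfTrees],
    level: int = 1,
    min_cluster_size: int = 10,
    fdr_alpha: float = 0.05,
    min_log_odds: float = 0.5,
    log_base: str = "e",
) -> list[EnrichmentRecord]:
    """Fisher tests for every eligible cluster x observed class.

    ``assignments`` maps reaction id to full EC numbers; classes are
    derived at ``level`` (ECs undefined at that level are skipped).
    Clusters need more than ``min_cluster_size`` assigned reactions to be
    tested; FDR is controlled across all tests at this level.
    """
    leveled: dict[str, set[str]] = {}
    for rid, ecns in assignments.items():
        classes = set()
        for ecn in ecns:
            try:
                classes.add(ecn_prefix(ecn, level))
            except ValueError:
                continue  # undefined at this level
        if classes:
            leveled[rid] = classes

    tests: list[tuple[str, str, ContingencyTable]] = []
    for cluster in clusters:
        n_assigned = sum(
            1 for rid in cluster.member_reaction_ids if rid in leveled
        )
        if n_assigned < min_cluster_size:
            continue
        observed = sorted({
            klass for rid in cluster.member_reaction_ids
            for klass in leveled.get(rid, ())
        })
        for klass in observed:
            tests.append((
                cluster.cts_id, klass,
                build_contingency(leveled, clusters, cluster.cts_id, klass),
            ))
    p_values = [fisher_two_sided(t) for _, _, t in tests]
    fdrs = bh_adjust(p_values)
    records = []
    for (cts_id, klass, table), p, fdr in zip(tests, p_values, fdrs):
        ratio, log_odds = odds_ratio(table, log_base=log_base)
        records.append(EnrichmentRecord(
            cts_id=cts_id, ecn_class=klass, level=level, table=table,
            p_value=p, fdr=fdr, odds_ratio=ratio, log_odds=log_odds,
            enriched=bool(fdr < fdr_alpha and log_odds >= min_log_odds),
        ))
    return records


def records_to_table(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cts_id": r.cts_id, "level": r.level, "ecn_class": r.ecn_class,
                "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                "p_value": r.p_value, "fdr": r.fdr,
                "odds_ratio": r.odds_ratio, "log_odds": r.log_odds,
                "enriched": r.enriched,
            }
            for r in records
        ],
        columns=["cts_id", "level", "ecn_class", "a", "b", "c", "d",
                 "p_value", "fdr", "odds_ratio", "log_odds", "enriched"],
    )


def write_enrichment_tsv(records: Iterable[EnrichmentRecord],
                         handle: TextIO) -> None:
    records_to_table(records).to_csv(handle, sep="\t", index=False)


def plot_enrichment_dotplot(records: Sequence[EnrichmentRecord], path: str,
                            enriched_only: bool = True) -> None:
    """Dot plot of class x cluster coloured by log odds, sized by hits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = [r for r in records if r.enriched] if enriched_only else list(records)
    fig, ax = plt.subplots(figsize=(8, 5))
    if shown:
        xs = sorted({r.cts_id for r in shown})
        ys = sorted({r.ecn_class for r in shown})
        xi = {v: i for i, v in enumerate(xs)}
        yi = {v: i for i, v in enumerate(ys)}
        sc = ax.scatter(
            [xi[r.cts_id] for r in shown],
            [yi[r.ecn_class] for r in shown],
            c=[r.log_odds for r in shown],
            s=[20 + 10 * r.table.a for r in shown],
            cmap="viridis",
        )
        ax.set_xticks(range(len(xs)), xs, rotation=90)
        ax.set_yticks(range(len(ys)), ys)
        fig.colorbar(sc, ax=ax, label="log odds ratio")
    ax.set_xlabel("cluster")
    ax.set_ylabel("EC class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
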