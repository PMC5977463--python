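"""Validation of predicted compound pairs against reactant-pair annotations.

Each tree's pair tips are compared, unordered, with the curated
reactant-pair annotations of the same reaction.  Reactions are
categorised as EPP (every predicted pair matched), FP (none matched) or
MP (mixed), with individual pairs in mixed reactions labelled MPP
(matched) or MFP (unmatched).

Per-cluster precision is estimated from the hit/fail counts with a beta
posterior.  Two parameterizations are offered:

``table`` (default)
    Beta(hits, fails) — the parameterization whose 2.5%/97.5% quantiles
    reproduce published per-cluster interval tables; it falls back to
    ``methods`` whenever a shape parameter would be zero.

``methods``
    Beta(hits + 1, fails + 1), the standard uniform-prior posterior with
    mean E(theta) = (y + 1)/(n + 2).

The interval average (mean of the two quantiles) ranks clusters into
high (>= 0.8), medium (>= 0.6) and low confidence bands, and pairs are
cross-tabulated by annotation class x hit-fail label x band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd
from scipy.stats import beta as beta_dist

from .cluster import ClusterOfTrees
from .kegg_io import RPairRecord
from .rsf import TreeStructure

__all__ = [
    "PairMatch",
    "ReactionCategory",
    "PrecisionEstimate",
    "ValidationResult",
    "match_tree_pairs",
    "categorize_reaction",
    "beta_interval",
    "cts_precision",
    "confidence_band",
    "class_crosstab",
    "validate_trees",
]

PAIR_LABELS = ("EPP", "MPP", "MFP", "FP")
BANDS = ("high", "medium", "low")


@dataclass(frozen=True)
class PairMatch:
    """One pair tip compared against the reaction's annotations."""

    reaction_id: str
    pair: frozenset[str]
    matched: bool
    matched_rclass_id: str | None = None
    kotera_class: str = "unknown"


@dataclass(frozen=True)
class ReactionCategory:
    reaction_id: str
    category: str  # EPP | MP | FP
    pair_labels: tuple[str, ...]  # per pair: EPP | MPP | MFP | FP


@dataclass(frozen=True)
class PrecisionEstimate:
    """Beta-posterior precision summary for one scope (a CTS or the
    whole set): y hits out of n pairs, 2.5%/97.5% quantiles, their mean,
    and the uniform-prior posterior mean (y+1)/(n+2)."""

    scope_id: str
    y: int
    n: int
    q025: float
    q975: float
    interval_average: float
    posterior_mean: float


def match_tree_pairs(
    tree: TreeStructure, rpairs: Sequence[RPairRecord]
) -> list[PairMatch]:
    """Compare each pair tip with the reaction's annotations.

    Matching is unordered on compound ids; loner tips never participate
    (inorganic leftovers like water carry no pair annotation).
    """
    by_pair: dict[frozenset, RPairRecord] = {}
    for rec in rpairs:
        if rec.reaction_id == tree.reaction_id:
            by_pair.setdefault(rec.pair, rec)
    matches = []
    for tip in tree.pair_tips():
        rec = by_pair.get(tip.pair)
        if rec is not None:
            matches.append(PairMatch(tree.reaction_id, tip.pair, True,
                                     rec.rclass_id, rec.kotera_class))
        else:
            matches.append(PairMatch(tree.reaction_id, tip.pair, False))
    return matches


def categorize_reaction(matches: Sequence[PairMatch]) -> ReactionCategory:
    """EPP if all pairs matched, FP if none, MP (MPP/MFP per pair) else."""
    if not matches:
        raise ValueError("reaction has no pair tips; excluded from validation")
    rid = matches[0].reaction_id
    hits = sum(m.matched for m in matches)
    if hits == len(matches):
        return ReactionCategory(rid, "EPP", ("EPP",) * len(matches))
    if hits == 0:
        return ReactionCategory(rid, "FP", ("FP",) * len(matches))
    labels = tuple("MPP" if m.matched else "MFP" for m in matches)
    return ReactionCategory(rid, "MP", labels)


def beta_interval(
    y: int, n: int, parameterization: str = "table", scope_id: str = "general"
) -> PrecisionEstimate:
    """Central 95% beta interval for a hit rate of ``y`` out of ``n``.

    ``table``: Beta(y, n - y), falling back to the uniform-prior
    ``methods`` form Beta(y + 1, n - y + 1) when y = 0 or y = n.
    """
    if y < 0 or n < 0 or y > n:
        raise ValueError(f"bad counts y={y}, n={n}")
    if parameterization not in ("table", "methods"):
        raise ValueError(f"unknown parameterization {parameterization!r}")
    fails = n - y
    if parameterization == "table" and y > 0 and fails > 0:
        a, b = float(y), float(fails)
    else:
        a, b = y + 1.0, fails + 1.0
    q025 = float(beta_dist.ppf(0.025, a, b))
    q975 = float(beta_dist.ppf(0.975, a, b))
    return PrecisionEstimate(
        scope_id=scope_id, y=y, n=n, q025=q025, q975=q975,
        interval_average=(q025 + q975) / 2.0,
        posterior_mean=(y + 1) / (n + 2),
    )


def cts_precision(
    cluster: ClusterOfTrees,
    matches_by_reaction: Mapping[str, Sequence[PairMatch]],
    min_reactions: int = 10,
    parameterization: str = "table",
) -> PrecisionEstimate | None:
    """Per-cluster precision estimate, or None (skipped) when fewer than
    ``min_reactions`` member reactions have at least one predicted pair."""
    y = n = n_with_pairs = 0
    for rid in cluster.member_reaction_ids:
        matches = matches_by_reaction.get(rid, ())
        if matches:
            n_with_pairs += 1
        y += sum(m.matched for m in matches)
        n += len(matches)
    if n_with_pairs < min_reactions or n == 0:
        return None
    return beta_interval(y, n, parameterization, scope_id=cluster.cts_id)


def confidence_band(interval_average: float) -> str:
    """high for x >= 0.8, medium for 0.8 > x >= 0.6, low for x < 0.6."""
    if not 0.0 <= interval_average <= 1.0:
        raise ValueError(f"interval average {interval_average} outside [0, 1]")
    if interval_average >= 0.8:
        return "high"
    if interval_average >= 0.6:
        return "medium"
    return "low"


def _fallback_class(pair: frozenset, rpairs: Sequence[RPairRecord]) -> str:
    for rec in rpairs:
        if pair & rec.pair:
            return rec.kotera_class
    return "unknown"


def class_crosstab(
    matches_by_reaction: Mapping[str, Sequence[PairMatch]],
    categories: Mapping[str, ReactionCategory],
    bands_by_reaction: Mapping[str, str],
    rpairs: Sequence[RPairRecord] = (),
) -> pd.DataFrame:
    """Long-format counts over (kotera_class, label, band).

    Unmatched pairs borrow the class of any same-compound annotation in
    their reaction, else ``unknown``.  Pairs of reactions without a band
    (skipped clusters) are not tabulated.  The count column total equals
    the number of pairs considered.
    """
    rpairs_by_rxn: dict[str, list[RPairRecord]] = {}
    for rec in rpairs:
        rpairs_by_rxn.setdefault(rec.reaction_id, []).append(rec)
    counts: dict[tuple[str, str, str], int] = {}
    for rid, matches in matches_by_reaction.items():
        band = bands_by_reaction.get(rid)
        if band is None or rid not in categories:
            continue
        labels = categories[rid].pair_labels
        for match, label in zip(matches, labels):
            klass = (match.kotera_class if match.matched else
                     _fallback_class(match.pair, rpairs_by_rxn.get(rid, ())))
            key = (klass, label, band)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"kotera_class": k, "label": lab, "band": band, "count": n}
        for (k, lab, band), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["kotera_class", "label", "band",
                                       "count"])


@dataclass
class ValidationResult:
    """Everything the validation stage produces in one place."""

    matches_by_reaction: dict[str, list[PairMatch]]
    categories: dict[str, ReactionCategory]
    excluded: list[str]  # reactions without any pair tip
    general: PrecisionEstimate
    per_cluster: dict[str, PrecisionEstimate | None]
    bands: dict[str, str]  # cts_id -> band, evaluated clusters only
    table: pd.DataFrame  # per-scope summary rows
    crosstab: pd.DataFrame  # class x label x band counts

    def write_table_tsv(self, handle: TextIO) -> None:
        self.table.to_csv(handle, sep="\t", index=False)

    def write_crosstab_tsv(self, handle: TextIO) -> None:
        self.crosstab.to_csv(handle, sep="\t", index=False)


def validate_trees(
    trees: Iterable[TreeStructure],
    rpairs: Sequence[RPairRecord],
    clusters: Sequence[ClusterOfTrees],
    min_reactions: int = 10,
    parameterization: str = "table",
) -> ValidationResult:
    """Run the whole validation stage: match, categorise, estimate
    precision per cluster and overall, band, and cross-tabulate."""
    matches_by_reaction: dict[str, list[PairMatch]] = {}
    categories: dict[str, ReactionCategory] = {}
    excluded: list[str] = []
    for tree in trees:
        matches = match_tree_pairs(tree, rpairs)
        if not matches:
            excluded.append(tree.reaction_id)
            continue
        matches_by_reaction[tree.reaction_id] = matches
        categories[tree.reaction_id] = categorize_reaction(matches)

    y = sum(m.matched for ms in matches_by_reaction.values() for m in ms)
    n = sum(len(ms) for ms in matches_by_reaction.values())
    general = beta_interval(y, n, parameterization) if n else beta_interval(
        0, 0, "methods")

    per_cluster: dict[str, PrecisionEstimate | None] = {}
    bands: dict[str, str] = {}
    bands_by_reaction: dict[str, str] = {}
    rows = [_summary_row("general", None, general,
                         list(categories.values()))]
    for cluster in clusters:
        est = cts_precision(cluster, matches_by_reaction, min_reactions,
                            parameterization)
        per_cluster[cluster.cts_id] = est
        if est is None:
            continue
        band = confidence_band(est.interval_average)
        bands[cluster.cts_id] = band
        member_cats = [categories[r] for r in cluster.member_reaction_ids
                       if r in categories]
        rows.append(_summary_row(cluster.cts_id, band, est, member_cats))
        for rid in cluster.member_reaction_ids:
            bands_by_reaction[rid] = band

    table = pd.DataFrame(rows, columns=[
        "scope", "n_reactions", "n_epp", "n_fp", "n_mp", "n_pairs", "hits",
        "fails", "q025", "q975", "interval_average", "posterior_mean", "band",
    ])
    crosstab = class_crosstab(matches_by_reaction, categories,
                              bands_by_reaction, rpairs)
    return ValidationResult(matches_by_reaction, categories, excluded,
                            general, per_cluster, bands, table, crosstab)


def _summary_row(scope: str, band: str | None, est: PrecisionEstimate,
                 member_categories: Sequence[ReactionCategory]) -> dict:
    tally = {"EPP": 0, "FP": 0, "MP": 0}
    for cat in member_categories:
        tally[cat.category] += 1
    return {
        "scope": scope,
        "n_reactions": len(member_categories),
        "n_epp": tally["EPP"],
        "n_fp": tally["FP"],
        "n_mp": tally["MP"],
        "n_pairs": est.n,
        "hits": est.y,
        "fails": est.n - est.y,
        "q025": est.q025,
        "q975": est.q975,
        "interval_average": est.interval_average,
        "posterior_mean": est.posterior_mean,
        "band": band if band is not None
        else confidence_band(est.interval_average),
    }
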