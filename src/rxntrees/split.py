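"""The balance and count rules, and recursive tree construction.

A reaction's two sides are aggregated into *units* (one per distinct
compound, stoichiometric multiples folded into the unit weight).  An
element of the Cartesian product (ECP) pairs a non-empty subset of the
substrate units with a non-empty subset of the product units; the pairing
of both full sides is always excluded.  The balance rule scores each ECP
by the normalised molecular-weight difference

    d = |W_a - W_b| / max(W_a, W_b)

and selects the minimum.  When several ECPs tie at the minimum (within a
small tolerance), the count rule disambiguates by network-wide ECP
frequency; remaining ties break on the lexicographically smallest
canonical key so construction is fully deterministic.

Splitting recurses: the selected ECP becomes the right child, the
remainder of the sub-reaction the left child, and a selected
multi-compound ECP is itself split further (with its own full pairing
excluded again), until every compound sits in exactly one pair or loner
tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Iterable, Mapping, Sequence

from .kegg_io import Compound, Reaction, ReactionTerm
from .rsf import BALANCE, COUNT, Internal, LonerTip, PairTip, TreeStructure

__all__ = [
    "Unit",
    "SubProblem",
    "EcpCandidate",
    "CountIndex",
    "SplitConfig",
    "SplitError",
    "aggregate_units",
    "mass_difference",
    "enumerate_candidates",
    "ecp_key",
    "build_count_index",
    "select_candidate",
    "build_tree",
    "build_trees",
    "walk_subproblems",
]


class SplitError(ValueError):
    """Tree construction cannot proceed (missing weight, size guard...)."""


@dataclass(frozen=True)
class Unit:
    """One distinct compound on one side; weight = coefficient x mol_weight."""

    compound_id: str
    coefficient: int
    weight: float

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError(f"unit {self.compound_id}: weight must be > 0")


@dataclass(frozen=True)
class SubProblem:
    """The not-yet-split part of a reaction; sides kept in substrate /
    product orientation throughout the recursion."""

    left: tuple[Unit, ...]
    right: tuple[Unit, ...]


@dataclass(frozen=True)
class EcpCandidate:
    a: tuple[Unit, ...]
    b: tuple[Unit, ...]
    w_a: float
    w_b: float
    d: float


@dataclass
class CountIndex:
    """Network-wide ECP frequencies keyed by canonical (side-agnostic)
    compound-id multiset pairs; each reaction counts at most once per key."""

    frequencies: dict[tuple, int] = field(default_factory=dict)

    def frequency(self, key: tuple) -> int:
        return self.frequencies.get(key, 0)


@dataclass(frozen=True)
class SplitConfig:
    """Numerical knobs for tree construction.

    ``tie_tol`` is the absolute tolerance on d (itself dimensionless in
    [0, 1]) within which candidates count as tied at the minimum;
    ``max_candidates`` guards against pathological subset counts.
    """

    tie_tol: float = 1e-9
    max_candidates: int = 2_000_000


def aggregate_units(
    side: Sequence[ReactionTerm], catalog: Mapping[str, Compound]
) -> tuple[Unit, ...]:
    """Fold a side's terms into one weighted unit per distinct compound."""
    merged: dict[str, int] = {}
    for term in side:
        merged[term.compound_id] = (
            merged.get(term.compound_id, 0) + term.coefficient
        )
    units = []
    for cid in sorted(merged):
        compound = catalog.get(cid)
        if compound is None or compound.mol_weight is None:
            raise SplitError(f"no molecular weight for compound {cid}")
        units.append(Unit(cid, merged[cid], merged[cid] * compound.mol_weight))
    return tuple(units)


def mass_difference(w_a: float, w_b: float) -> float:
    """Normalised weight difference |W_a - W_b| / max(W_a, W_b) in [0, 1]."""
    if not (w_a > 0 and w_b > 0):
        raise ValueError("weights must be positive")
    return abs(w_a - w_b) / max(w_a, w_b)


def _subsets(units: Sequence[Unit], max_size: int | None):
    top = len(units) if max_size is None else min(max_size, len(units))
    for size in range(1, top + 1):
        yield from combinations(units, size)


def enumerate_candidates(
    sp: SubProblem,
    max_subset_size: int | None = None,
    max_candidates: int | None = None,
) -> list[EcpCandidate]:
    """Every (non-empty subset, non-empty subset) pairing except the full
    pairing of this sub-problem.  Empty if either side is empty."""
    if not sp.left or not sp.right:
        return []
    n_total = (2 ** len(sp.left) - 1) * (2 ** len(sp.right) - 1) - 1
    if max_candidates is not None and n_total > max_candidates:
        raise SplitError(
            f"candidate count {n_total} exceeds guard {max_candidates}"
        )
    out = []
    for a in _subsets(sp.left, max_subset_size):
        w_a = sum(u.weight for u in a)
        for b in _subsets(sp.right, max_subset_size):
            if len(a) == len(sp.left) and len(b) == len(sp.right):
                continue  # the whole sub-reaction
            w_b = sum(u.weight for u in b)
            out.append(EcpCandidate(a, b, w_a, w_b, mass_difference(w_a, w_b)))
    return out


def ecp_key(a: Iterable[Unit], b: Iterable[Unit]) -> tuple:
    """Canonical side-agnostic key: sorted pair of compound-id multisets."""
    side_a = tuple(sorted(
        chain.from_iterable([u.compound_id] * u.coefficient for u in a)
    ))
    side_b = tuple(sorted(
        chain.from_iterable([u.compound_id] * u.coefficient for u in b)
    ))
    return tuple(sorted((side_a, side_b)))


def build_count_index(
    reactions: Iterable[Reaction],
    catalog: Mapping[str, Compound],
    max_subset_size: int = 4,
) -> CountIndex:
    """Count, per canonical ECP key, in how many reactions the ECP occurs
    as a candidate (subset sizes capped per side)."""
    index = CountIndex()
    for rxn in reactions:
        sp = SubProblem(aggregate_units(rxn.substrates, catalog),
                        aggregate_units(rxn.products, catalog))
        keys = {
            ecp_key(c.a, c.b)
            for c in enumerate_candidates(sp, max_subset_size=max_subset_size)
        }
        for key in keys:
            index.frequencies[key] = index.frequencies.get(key, 0) + 1
    return index


def select_candidate(
    sp: SubProblem,
    index: CountIndex | None = None,
    tie_tol: float = 1e-9,
    max_candidates: int | None = None,
) -> tuple[EcpCandidate, str]:
    """Pick the next ECP: balance rule if a unique minimum-d candidate
    exists within ``tie_tol``, otherwise the count rule among the tied
    candidates (frequency ties break on the smallest canonical key)."""
    candidates = enumerate_candidates(sp, max_candidates=max_candidates)
    if not candidates:
        raise SplitError("no candidates for this sub-problem")
    d_min = min(c.d for c in candidates)
    tied = [c for c in candidates if c.d - d_min <= tie_tol]
    if len(tied) == 1:
        return tied[0], BALANCE
    if index is None:
        index = CountIndex()
    best = min(
        tied,
        key=lambda c: (-index.frequency(ecp_key(c.a, c.b)), ecp_key(c.a, c.b)),
    )
    return best, COUNT


def _remove(units: tuple[Unit, ...], taken: tuple[Unit, ...]) -> tuple[Unit, ...]:
    taken_ids = {u.compound_id for u in taken}
    return tuple(u for u in units if u.compound_id not in taken_ids)


def build_tree(
    reaction: Reaction,
    catalog: Mapping[str, Compound],
    index: CountIndex | None = None,
    config: SplitConfig = SplitConfig(),
) -> TreeStructure:
    """Recursively decompose one reaction into its tree structure.

    The selected ECP goes on the right, the remainder on the left; a
    selected multi-compound ECP becomes its own sub-problem (full pairing
    excluded again).  A one-sided remainder peels its lightest unit as a
    left loner (balance marker).  Every compound of the reaction ends up
    in exactly one tip.
    """
    left = aggregate_units(reaction.substrates, catalog)
    right = aggregate_units(reaction.products, catalog)

    def build(lhs: tuple[Unit, ...], rhs: tuple[Unit, ...]):
        if len(lhs) == 1 and len(rhs) == 1:
            return PairTip(lhs[0].compound_id, rhs[0].compound_id)
        if not rhs or not lhs:
            units, side = (lhs, "substrate") if lhs else (rhs, "product")
            if not units:
                raise SplitError("empty sub-problem")
            if len(units) == 1:
                return LonerTip(units[0].compound_id, side)
            lightest = min(units, key=lambda u: (u.weight, u.compound_id))
            rest = tuple(u for u in units if u is not lightest)
            child = build(rest, ()) if side == "substrate" else build((), rest)
            return Internal(BALANCE, LonerTip(lightest.compound_id, side), child)
        selected, rule = select_candidate(
            SubProblem(lhs, rhs), index, tie_tol=config.tie_tol,
            max_candidates=config.max_candidates,
        )
        remainder = build(_remove(lhs, selected.a), _remove(rhs, selected.b))
        chosen = build(selected.a, selected.b)
        return Internal(rule, remainder, chosen)

    return TreeStructure.from_root(reaction.id, build(left, right))


def build_trees(
    reactions: Iterable[Reaction],
    catalog: Mapping[str, Compound],
    index: CountIndex | None = None,
    config: SplitConfig = SplitConfig(),
) -> list[TreeStructure]:
    """Build one tree per reaction, sharing one count index.

    When ``index`` is None it is built from the given reactions first
    (the count rule is a whole-network measure).
    """
    reactions = list(reactions)
    if index is None:
        index = build_count_index(reactions, catalog)
    return [build_tree(r, catalog, index, config) for r in reactions]


def walk_subproblems(
    tree: TreeStructure,
    reaction: Reaction,
    catalog: Mapping[str, Compound],
):
    """Yield ``(internal_node, SubProblem, selected)`` for every internal
    node, reconstructing the sub-problem each split faced from the tips
    below it.  Useful for auditing rule decisions after the fact."""
    units = {
        u.compound_id: u
        for u in aggregate_units(reaction.substrates, catalog)
        + aggregate_units(reaction.products, catalog)
    }

    def tips_sides(node) -> tuple[tuple[Unit, ...], tuple[Unit, ...]]:
        if isinstance(node, PairTip):
            return (units[node.substrate_id],), (units[node.product_id],)
        if isinstance(node, LonerTip):
            unit = (units[node.compound_id],)
            return (unit, ()) if node.side == "substrate" else ((), unit)
        ll, lr = tips_sides(node.left)
        rl, rr = tips_sides(node.right)
        return ll + rl, lr + rr

    def walk(node):
        if not isinstance(node, Internal):
            return
        lhs, rhs = tips_sides(node)
        sel_l, sel_r = tips_sides(node.right)
        yield node, SubProblem(tuple(sorted(lhs, key=lambda u: u.compound_id)),
                               tuple(sorted(rhs, key=lambda u: u.compound_id))), \
            (sel_l, sel_r)
        yield from walk(node.left)
        yield from walk(node.right)

    yield from walk(tree.root)
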