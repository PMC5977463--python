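"""Synthetic benchmark universes and bundled worked examples.

The generator emulates the structure that makes rule-based reaction
splitting work on real metabolism: heavy cofactor couples that change
very little (small relative weight difference), main substrates that
change a lot, and a few pool species (water, phosphate, a nucleotide
analogue) reused across many reactions so that network-wide ECP
frequencies rank them highly.  Reaction templates mirror four archetypal
shapes:

``redox_transfer``   A + Cox <=> B + Cred        two pairs
``elimination``      A <=> B + H2O-analogue      pair + loner
``hydrolysis``       A + H2O <=> B + Pi          pair + two loners
``tie_transfer``     NTP + A <=> NDP + B         exact weight tie, so the
                                                 count rule must fire

Every generated reaction is mass-balanced by construction (product
weights are derived by subtraction), and a *separation guarantee* is
enforced: each cofactor couple's relative weight difference is strictly
smaller than any main-pair relative difference the templates can
produce, which makes 100% planted-pair recovery provable rather than
empirical.

``bundled_examples`` returns a small fixed catalog of real KEGG-style
reactions with reference molecular weights computed from their chemical
formulas, plus reactant-pair annotations for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formula import formula_weight
from .kegg_io import Compound, Reaction, RPairRecord, parse_equation
from .rsf import TreeStructure

__all__ = [
    "CofactorPair",
    "UniverseSpec",
    "Universe",
    "SyntheticTruth",
    "DEFAULT_TEMPLATES",
    "make_universe",
    "make_reactions",
    "default_benchmark",
    "recovery_rate",
    "bundled_examples",
]

DEFAULT_TEMPLATES = ("redox_transfer", "elimination", "hydrolysis",
                     "tie_transfer")

# Pool weights are analogues of water, orthophosphate and a nucleoside
# triphosphate; the tie template derives an NDP-like partner of weight
# _NTP_WEIGHT - _TIE_DELTA for its forced count-rule tie.
_TIE_DELTA = 80.0
_NTP_WEIGHT = 500.0


@dataclass(frozen=True)
class CofactorPair:
    """An oxidised/reduced couple; ``delta`` is the weight difference."""

    ox_id: str
    red_id: str
    ox_weight: float
    delta: float


@dataclass(frozen=True)
class UniverseSpec:
    """Parameters of a synthetic compound universe.

    ``main_min_delta`` is the smallest main-pair weight difference any
    template can produce (with a redox template in play this equals the
    cofactor delta, because mass balance transfers it to the main pair).
    The separation guarantee requires every cofactor couple's relative
    difference delta/max_pair_weight to be strictly below
    ``main_min_delta / max_main_weight``.
    """

    seed: int = 42
    n_main_compounds: int = 400
    main_weight_range: tuple[float, float] = (250.0, 400.0)
    main_min_delta: float = 2.016
    cofactor_pairs: tuple[CofactorPair, ...] = (
        CofactorPair("NOX0001", "NRD0001", 663.430, 2.016),
    )
    pool_compounds: tuple[tuple[str, float], ...] = (
        ("WAT0001", 18.015),
        ("PHO0001", 97.977),
        ("NTP0001", _NTP_WEIGHT),
    )

    def check_separation(self) -> None:
        lo, hi = self.main_weight_range
        if not 0 < lo < hi:
            raise ValueError("main_weight_range must be 0 < lo < hi")
        main_rel = self.main_min_delta / hi
        for pair in self.cofactor_pairs:
            pair_max = pair.ox_weight + max(pair.delta, 0.0)
            cof_rel = abs(pair.delta) / pair_max
            if not cof_rel < main_rel:
                raise ValueError(
                    f"separation guarantee violated: cofactor {pair.ox_id}/"
                    f"{pair.red_id} relative delta {cof_rel:.5f} is not below "
                    f"the minimal main-pair relative difference {main_rel:.5f}"
                )


@dataclass
class Universe:
    spec: UniverseSpec
    catalog: dict[str, Compound]


@dataclass
class SyntheticTruth:
    """Planted ground-truth pairs per reaction (unordered compound-id
    pairs with class labels main/cofac/leave)."""

    planted: dict[str, list[tuple[frozenset[str], str]]] = field(
        default_factory=dict
    )

    def n_pairs(self) -> int:
        return sum(len(v) for v in self.planted.values())

    def to_rpair_records(self) -> list[RPairRecord]:
        """Annotation rows equivalent to the planted truth, with synthetic
        RCLASS-style placeholder ids."""
        records = []
        counter = 0
        for rid in sorted(self.planted):
            for pair, klass in self.planted[rid]:
                counter += 1
                a, b = sorted(pair)
                records.append(
                    RPairRecord(rid, a, b, f"RCSYN{counter:05d}", klass)
                )
        return records


def make_universe(spec: UniverseSpec = UniverseSpec()) -> Universe:
    """Deterministically build the compound catalog for a spec.

    Raises before any reaction is generated if the separation guarantee
    is violated.
    """
    spec.check_separation()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.main_weight_range
    catalog: dict[str, Compound] = {}
    weights = rng.uniform(lo, hi, size=spec.n_main_compounds)
    for i, w in enumerate(weights, start=1):
        catalog[f"M{i:05d}"] = Compound(f"M{i:05d}", None, float(round(w, 4)))
    for pair in spec.cofactor_pairs:
        catalog[pair.ox_id] = Compound(pair.ox_id, None, pair.ox_weight)
        catalog[pair.red_id] = Compound(pair.red_id, None,
                                        pair.ox_weight + pair.delta)
    for cid, w in spec.pool_compounds:
        catalog[cid] = Compound(cid, None, w)
    return Universe(spec, catalog)


def _pool_weight(universe: Universe, cid: str) -> float:
    compound = universe.catalog.get(cid)
    if compound is None or compound.mol_weight is None:
        raise ValueError(f"template references unknown pool compound {cid!r}")
    return compound.mol_weight


def make_reactions(
    universe: Universe,
    templates: Sequence[str] = DEFAULT_TEMPLATES,
    n: int = 500,
    seed: int | None = None,
) -> tuple[list[Reaction], SyntheticTruth]:
    """Generate ``n`` template reactions with planted ground truth.

    Templates are cycled round-robin; per-reaction product compounds are
    created on the fly (weights fixed by mass balance) and added to the
    universe catalog in place.  Deterministic for a given seed (default:
    spec seed + 1).
    """
    unknown = set(templates) - set(DEFAULT_TEMPLATES)
    if unknown:
        raise ValueError(f"unknown template(s): {sorted(unknown)}")
    if not templates and n > 0:
        raise ValueError("no templates given")
    spec = universe.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    main_ids = [cid for cid in universe.catalog if cid.startswith("M")]
    if not main_ids and n > 0:
        raise ValueError("universe has no main compounds")
    water = _pool_weight(universe, "WAT0001")
    phosphate = _pool_weight(universe, "PHO0001")
    ntp_id = "NTP0001"
    ntp = _pool_weight(universe, ntp_id)
    ndp_id = "NDP0001"
    if n and "tie_transfer" in templates and ndp_id not in universe.catalog:
        universe.catalog[ndp_id] = Compound(ndp_id, None, ntp - _TIE_DELTA)

    reactions: list[Reaction] = []
    truth = SyntheticTruth()

    def new_compound(prefix: str, i: int, weight: float) -> str:
        cid = f"{prefix}{i:05d}"
        universe.catalog[cid] = Compound(cid, None, weight)
        return cid

    for i in range(1, n + 1):
        template = templates[(i - 1) % len(templates)]
        rid = f"S{i:05d}"
        planted: list[tuple[frozenset[str], str]] = []
        if template == "redox_transfer":
            a_id = main_ids[int(rng.integers(len(main_ids)))]
            cof = spec.cofactor_pairs[
                int(rng.integers(len(spec.cofactor_pairs)))
            ]
            w_a = universe.catalog[a_id].mol_weight
            b_id = new_compound("B", i, w_a - cof.delta)
            rxn = Reaction(rid,
                           (_term(a_id), _term(cof.ox_id)),
                           (_term(b_id), _term(cof.red_id)))
            planted = [(frozenset((a_id, b_id)), "main"),
                       (frozenset((cof.ox_id, cof.red_id)), "cofac")]
        elif template == "elimination":
            a_id = main_ids[int(rng.integers(len(main_ids)))]
            w_a = universe.catalog[a_id].mol_weight
            b_id = new_compound("B", i, w_a - water)
            rxn = Reaction(rid, (_term(a_id),),
                           (_term(b_id), _term("WAT0001")))
            planted = [(frozenset((a_id, b_id)), "main")]
        elif template == "hydrolysis":
            a_id = main_ids[int(rng.integers(len(main_ids)))]
            w_a = universe.catalog[a_id].mol_weight
            b_id = new_compound("B", i, w_a + water - phosphate)
            rxn = Reaction(rid, (_term(a_id), _term("WAT0001")),
                           (_term(b_id), _term("PHO0001")))
            planted = [(frozenset((a_id, b_id)), "main")]
        else:  # tie_transfer
            ndp = universe.catalog[ndp_id].mol_weight
            a_id = new_compound("TA", i, 2 * ndp - ntp)
            b_id = new_compound("TB", i, ndp)  # exact tie with the NDP pool
            rxn = Reaction(rid, (_term(ntp_id), _term(a_id)),
                           (_term(ndp_id), _term(b_id)))
            planted = [(frozenset((ntp_id, ndp_id)), "cofac"),
                       (frozenset((a_id, b_id)), "main")]
        reactions.append(rxn)
        truth.planted[rid] = planted
    return reactions, truth


def _term(cid: str):
    from .kegg_io import ReactionTerm
    return ReactionTerm(cid, 1)


def default_benchmark(
    seed: int = 42, n: int = 500
) -> tuple[Universe, list[Reaction], SyntheticTruth]:
    """The separation-guaranteed benchmark: one redox couple, three pool
    species, four templates, 500 reactions by default."""
    universe = make_universe(UniverseSpec(seed=seed))
    reactions, truth = make_reactions(universe, DEFAULT_TEMPLATES, n,
                                      seed=seed + 1)
    return universe, reactions, truth


def recovery_rate(
    trees: Iterable[TreeStructure], truth: SyntheticTruth
) -> float:
    """Fraction of planted pairs appearing as pair tips of their tree."""
    trees_by_id: Mapping[str, TreeStructure] = {
        t.reaction_id: t for t in trees
    }
    total = found = 0
    for rid, pairs in truth.planted.items():
        tree = trees_by_id.get(rid)
        tips = {tip.pair for tip in tree.pair_tips()} if tree else set()
        for pair, _ in pairs:
            total += 1
            found += pair in tips
    return found / total if total else float("nan")


# ---------------------------------------------------------------------------
# Bundled worked examples

# Chemical formulas of the fixture compounds; reference weights are
# derived from these with conventional atomic weights.  ADP (C00008) and
# dGDP (C00361) share the formula C10H15N5O10P2, so their weights tie
# exactly -- the canonical count-rule case.
_BUNDLED_FORMULAS = {
    "C00001": "H2O",            # water
    "C00002": "C10H16N5O13P3",  # ATP
    "C00007": "O2",             # oxygen
    "C00008": "C10H15N5O10P2",  # ADP
    "C00009": "H3PO4",          # orthophosphate
    "C00014": "H3N",            # ammonia
    "C00018": "C8H10NO6P",      # pyridoxal 5'-phosphate
    "C00061": "C17H21N4O9P",    # FMN
    "C00074": "C3H5O6P",        # phosphoenolpyruvate
    "C00084": "C2H4O",          # acetaldehyde
    "C00085": "C6H13O9P",       # D-fructose 6-phosphate
    "C00088": "HNO2",           # nitrite
    "C00094": "H2SO3",          # sulfite
    "C00095": "C6H12O6",        # D-fructose
    "C00117": "C5H11O8P",       # D-ribose 5-phosphate
    "C00118": "C3H7O6P",        # D-glyceraldehyde 3-phosphate
    "C00361": "C10H15N5O10P2",  # dGDP
    "C00362": "C10H14N5O7P",    # dGMP
    "C00631": "C3H7O7P",        # 2-phospho-D-glycerate
    "C01847": "C17H23N4O9P",    # reduced FMN
    "C02501": "C6H6O5",         # 2-hydroxymuconate
    "C06336": "C6H6O5S",        # 3-sulfocatechol
    "C18091": "C2H5NO2",        # ethylnitronate
}

_BUNDLED_REACTIONS = [
    ("R00658", "C00631 <=> C00074 + C00001", ["4.2.1.11"]),
    ("R02090", "C00002 + C00362 <=> C00008 + C00361", ["2.7.4.8"]),
    ("R00760", "C00002 + C00095 <=> C00008 + C00085", ["2.7.1.4"]),
    ("R00025",
     "C18091 + C01847 + C00007 <=> C00084 + C00088 + C00061 + C00001",
     ["1.13.12.16"]),
    ("R10088", "C00117 + C00118 + C00014 <=> C00018 + C00009 + 4 C00001",
     ["4.3.3.6"]),
    ("R07795", "C06336 + C00007 + C00001 <=> C02501 + C00094",
     ["1.13.11.2"]),
]

# Reactant-pair annotations for the fixtures.  RCLASS ids starting with
# "RCSYN" are synthetic placeholders (the curated identifier is not part
# of the fixture); the R00025 and R10088 ids are the curated ones.  The
# R07795 oxygen/sulfite row is a leave pair without an RCLASS id,
# mirroring a pair dropped from the curated set.
_BUNDLED_RPAIRS = [
    ("R00658", "C00631", "C00074", "RCSYN0658", "main"),
    ("R02090", "C00002", "C00008", "RCSYN2090", "cofac"),
    ("R02090", "C00362", "C00361", "RCSYN2091", "main"),
    ("R00760", "C00095", "C00085", "RCSYN0760", "main"),
    ("R00760", "C00002", "C00008", "RCSYN0761", "cofac"),
    ("R00025", "C00061", "C01847", "RC00126", "cofac"),
    ("R00025", "C00084", "C18091", "RC02541", "main"),
    ("R00025", "C00088", "C18091", "RC02759", "main"),
    ("R10088", "C00018", "C00117", "RC03049", "main"),
    ("R10088", "C00018", "C00118", "RC01783", "main"),
    ("R07795", "C06336", "C02501", "RCSYN7795", "main"),
    ("R07795", "C00007", "C00094", None, "leave"),
]


def bundled_examples() -> tuple[
    dict[str, Compound], list[Reaction], list[RPairRecord]
]:
    """Six fixed reactions with reference formula weights and their
    reactant-pair annotations."""
    catalog = {
        cid: Compound(cid, formula, formula_weight(formula))
        for cid, formula in _BUNDLED_FORMULAS.items()
    }
    reactions = [
        parse_equation(rid, equation, ecns)
        for rid, equation, ecns in _BUNDLED_REACTIONS
    ]
    rpairs = [
        RPairRecord(rid, a, b, rclass, klass)
        for rid, a, b, rclass, klass in _BUNDLED_RPAIRS
    ]
    return catalog, reactions, rpairs
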