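"""Input/output for compound, reaction and reactant-pair tables.

Two dialects are supported for compounds and reactions:

``kegg_flat``
    The LIGAND record-per-entry text format: 12-column keyword field,
    continuation lines, records terminated by ``///``.  For compounds the
    weight is taken from ``MOL_WEIGHT``, falling back to ``EXACT_MASS``.

``tsv``
    A simplified tab-separated dialect.  Compounds: ``id, formula,
    mol_weight``; reactions: ``id, equation[, ecns]`` with EC numbers
    semicolon-joined; an equation may also be given as ``"R00001: lhs <=>
    rhs"`` on a single line.

Reactant-pair annotations are read from a 5-column TSV (``reaction_id,
compound_a, compound_b, rclass_id, class``).

The dataset filters mirror a curation policy for rule-based reaction
splitting: glycan participants, symbolic stoichiometric coefficients and
one-compound-per-side (isomerisation-like) reactions are removed, plus
reactions whose compounds lack a usable molecular weight.  A mass-balance
filter is available but disabled by default.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

logger = logging.getLogger(__name__)

__all__ = [
    "Compound",
    "ReactionTerm",
    "Reaction",
    "RPairRecord",
    "FilterPolicy",
    "FilterReport",
    "KeggIoError",
    "KOTERA_CLASSES",
    "parse_compound_table",
    "parse_reaction_table",
    "parse_equation",
    "parse_rpair_table",
    "filter_reactions",
    "write_compound_tsv",
    "write_reaction_tsv",
    "write_rpair_tsv",
    "write_filter_report",
]

KOTERA_CLASSES = ("main", "cofac", "trans", "leave", "ligase", "unknown")


class KeggIoError(ValueError):
    """Malformed input table or record."""


@dataclass(frozen=True)
class Compound:
    """A chemical species: identifier, optional formula, molecular weight.

    ``mol_weight`` is ``None`` for entries whose source record carried no
    numeric weight; such compounds are retained in the catalog but cannot
    take part in tree building (the missing-weight filter removes their
    reactions).
    """

    id: str
    formula: str | None = None
    mol_weight: float | None = None

    def __post_init__(self) -> None:
        if self.mol_weight is not None and not self.mol_weight > 0:
            raise ValueError(f"compound {self.id}: mol_weight must be > 0")


@dataclass(frozen=True)
class ReactionTerm:
    compound_id: str
    coefficient: int = 1

    def __post_init__(self) -> None:
        if self.coefficient < 1:
            raise ValueError(
                f"term {self.compound_id}: coefficient must be >= 1"
            )


@dataclass(frozen=True)
class Reaction:
    """One stoichiometric equation, as written (left = substrates).

    Repeated compounds within a side are folded into the coefficient.
    ``ill_defined`` marks equations with symbolic coefficients (``n``,
    ``n+1``); they are representable but rejected by the default filter
    policy.
    """

    id: str
    substrates: tuple[ReactionTerm, ...]
    products: tuple[ReactionTerm, ...]
    ecns: tuple[str, ...] = ()
    ill_defined: bool = False

    def __post_init__(self) -> None:
        for side_name, side in (("substrate", self.substrates),
                                ("product", self.products)):
            ids = [t.compound_id for t in side]
            if len(ids) != len(set(ids)):
                raise ValueError(
                    f"reaction {self.id}: repeated compound on {side_name} side"
                )

    @property
    def compound_ids(self) -> set[str]:
        return {t.compound_id for t in self.substrates + self.products}


@dataclass(frozen=True)
class RPairRecord:
    """A curated reactant-pair annotation for one reaction.

    The pair is unordered for matching purposes; ``kotera_class`` is one
    of main/cofac/trans/leave/ligase/unknown.
    """

    reaction_id: str
    compound_a: str
    compound_b: str
    rclass_id: str | None = None
    kotera_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.compound_a == self.compound_b:
            raise ValueError(
                f"rpair for {self.reaction_id}: compound_a == compound_b "
                f"({self.compound_a})"
            )
        if self.kotera_class not in KOTERA_CLASSES:
            raise ValueError(f"unknown kotera class {self.kotera_class!r}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.compound_a, self.compound_b))


@dataclass(frozen=True)
class FilterPolicy:
    """Which dataset filters are active.

    Defaults enable the four curation filters plus the missing-weight
    guard; the mass-balance filter is off (1% relative tolerance when
    enabled).
    """

    glycan: bool = True
    ill_defined_coefficient: bool = True
    one_to_one: bool = True
    missing_weight: bool = True
    unbalanced: bool = False
    unbalanced_tol: float = 0.01


@dataclass
class FilterReport:
    """Exact partition of the input reactions into kept and dropped."""

    kept: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)


def _as_stream(stream: str | TextIO) -> TextIO:
    if isinstance(stream, str):
        return _io.StringIO(stream)
    return stream


# ---------------------------------------------------------------------------
# KEGG flat-file records

def _iter_flat_records(stream: TextIO):
    """Yield (first_line_number, {keyword: [data lines]}) per /// record."""
    record: dict[str, list[str]] = {}
    keyword = None
    start_line = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith("///"):
            if record:
                yield start_line, record
            record, keyword, start_line = {}, None, None
            continue
        if not line.strip():
            continue
        if start_line is None:
            start_line = lineno
        head = line[:12].strip()
        if head:
            keyword = head
            record.setdefault(keyword, [])
        if keyword is None:
            raise KeggIoError(f"line {lineno}: continuation before any keyword")
        record[keyword].append(line[12:].strip())
    if record:
        yield start_line, record


def _parse_weight(fields: Mapping[str, list[str]]) -> float | None:
    for key in ("MOL_WEIGHT", "EXACT_MASS", "MASS"):
        if key in fields and fields[key]:
            try:
                return float(fields[key][0])
            except ValueError:
                return None
    return None


# ---------------------------------------------------------------------------
# Compounds

def parse_compound_table(
    stream: str | TextIO, dialect: str = "tsv"
) -> dict[str, Compound]:
    """Parse a compound table into a catalog keyed by compound id.

    Entries lacking a numeric molecular weight are retained with
    ``mol_weight=None``.  Duplicate ids and unparseable records raise
    :class:`KeggIoError`.
    """
    handle = _as_stream(stream)
    catalog: dict[str, Compound] = {}

    def add(compound: Compound, where: str) -> None:
        if compound.id in catalog:
            raise KeggIoError(f"duplicate compound id {compound.id} ({where})")
        catalog[compound.id] = compound

    if dialect == "tsv":
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0].strip().lower() == "id":
                continue
            if len(cols) < 3:
                raise KeggIoError(
                    f"line {lineno}: expected 3 columns (id, formula, "
                    f"mol_weight), got {len(cols)}"
                )
            cid, formula, weight_s = (c.strip() for c in cols[:3])
            if not cid:
                raise KeggIoError(f"line {lineno}: empty compound id")
            weight: float | None
            if weight_s in ("", "-", "NA"):
                weight = None
            else:
                try:
                    weight = float(weight_s)
                except ValueError as exc:
                    raise KeggIoError(
                        f"line {lineno}: bad mol_weight {weight_s!r}"
                    ) from exc
            add(Compound(cid, formula or None, weight), f"line {lineno}")
    elif dialect == "kegg_flat":
        for lineno, fields in _iter_flat_records(handle):
            if "ENTRY" not in fields or not fields["ENTRY"]:
                raise KeggIoError(f"record at line {lineno}: missing ENTRY")
            cid = fields["ENTRY"][0].split()[0]
            formula = fields.get("FORMULA", [None])[0]
            add(Compound(cid, formula, _parse_weight(fields)),
                f"record at line {lineno}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return catalog


# ---------------------------------------------------------------------------
# Reactions

_COMPOUND_ID = re.compile(r"[A-Za-z][A-Za-z0-9_]*")
_INTEGER = re.compile(r"\d+")


def parse_equation(reaction_id: str, equation: str,
                   ecns: Iterable[str] = ()) -> Reaction:
    """Parse one ``lhs <=> rhs`` equation into a :class:`Reaction`.

    Terms are ``+``-separated with an optional leading integer
    coefficient.  Symbolic coefficients mark the reaction ``ill_defined``
    instead of failing: the dataset filter decides their fate.
    """
    if "<=>" not in equation:
        raise KeggIoError(f"reaction {reaction_id}: missing '<=>' separator")
    lhs, rhs = equation.split("<=>", 1)
    ill_defined = False

    def parse_side(text: str, side_name: str) -> tuple[ReactionTerm, ...]:
        nonlocal ill_defined
        terms: dict[str, int] = {}
        chunks = [c.strip() for c in text.split(" + ")]
        if chunks == [""]:
            raise KeggIoError(
                f"reaction {reaction_id}: empty {side_name} side"
            )
        for chunk in chunks:
            if not chunk:
                raise KeggIoError(
                    f"reaction {reaction_id}: empty term on {side_name} side"
                )
            pieces = chunk.split()
            coeff = 1
            if len(pieces) == 2 and _INTEGER.fullmatch(pieces[0]):
                coeff, cid = int(pieces[0]), pieces[1]
            elif len(pieces) == 1:
                cid = pieces[0]
            else:
                # "n C00001", "(n+1) C00404" ... keep the compound, flag it
                ill_defined = True
                cid = pieces[-1]
            if not _COMPOUND_ID.fullmatch(cid):
                # trailing symbolic subscript, e.g. "C00404(n)"
                match = _COMPOUND_ID.match(cid)
                if match and match.end() < len(cid):
                    ill_defined = True
                    cid = match.group(0)
                else:
                    raise KeggIoError(
                        f"reaction {reaction_id}: bad term {chunk!r}"
                    )
            terms[cid] = terms.get(cid, 0) + coeff
        return tuple(ReactionTerm(cid, n) for cid, n in terms.items())

    substrates = parse_side(lhs.strip(), "substrate")
    products = parse_side(rhs.strip(), "product")
    return Reaction(reaction_id, substrates, products, tuple(ecns),
                    ill_defined)


def _split_id_equation(line: str) -> tuple[str, str]:
    rid, sep, eq = line.partition(":")
    if not sep or not eq.strip():
        raise KeggIoError(f"cannot split {line!r} into 'id: equation'")
    return rid.strip(), eq.strip()


def parse_reaction_table(
    stream: str | TextIO, dialect: str = "tsv"
) -> list[Reaction]:
    """Parse a reaction table into a list of :class:`Reaction`.

    TSV columns: ``id, equation[, ecns]`` (ECs semicolon-joined); a line
    of the form ``"R00001: lhs <=> rhs"`` is also accepted.  The
    kegg_flat dialect reads ENTRY/EQUATION/ENZYME keywords.
    """
    handle = _as_stream(stream)
    reactions: list[Reaction] = []
    seen: set[str] = set()

    def add(rxn: Reaction, where: str) -> None:
        if rxn.id in seen:
            raise KeggIoError(f"duplicate reaction id {rxn.id} ({where})")
        seen.add(rxn.id)
        reactions.append(rxn)

    if dialect == "tsv":
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0].strip().lower() == "id":
                continue
            if len(cols) == 1:
                rid, equation = _split_id_equation(cols[0])
                ecns: tuple[str, ...] = ()
            else:
                rid, equation = cols[0].strip(), cols[1].strip()
                ecns = tuple(
                    e.strip() for e in cols[2].split(";") if e.strip()
                ) if len(cols) > 2 else ()
            add(parse_equation(rid, equation, ecns), f"line {lineno}")
    elif dialect == "kegg_flat":
        for lineno, fields in _iter_flat_records(handle):
            if "ENTRY" not in fields or not fields["ENTRY"]:
                raise KeggIoError(f"record at line {lineno}: missing ENTRY")
            rid = fields["ENTRY"][0].split()[0]
            if "EQUATION" not in fields:
                raise KeggIoError(f"reaction {rid}: missing EQUATION")
            equation = " ".join(fields["EQUATION"])
            ecns = tuple(
                ec for chunk in fields.get("ENZYME", []) for ec in chunk.split()
            )
            add(parse_equation(rid, equation, ecns), f"record at line {lineno}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return reactions


# ---------------------------------------------------------------------------
# Reactant pairs

def parse_rpair_table(
    stream: str | TextIO, require_rclass: bool = False
) -> list[RPairRecord]:
    """Parse a reactant-pair TSV into :class:`RPairRecord` rows.

    Unknown class strings map to ``unknown``; empty/``-`` rclass ids map
    to ``None`` and are excluded when ``require_rclass`` is set.  Exact
    duplicate rows are dropped (the count is logged).
    """
    handle = _as_stream(stream)
    records: list[RPairRecord] = []
    seen: set[tuple] = set()
    n_dup = 0
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = [c.strip() for c in line.split("\t")]
        if lineno == 1 and cols[0].lower() == "reaction_id":
            continue
        if len(cols) < 3:
            raise KeggIoError(
                f"row {lineno}: expected >= 3 columns, got {len(cols)}"
            )
        rid, ca, cb = cols[0], cols[1], cols[2]
        rclass = cols[3] if len(cols) > 3 and cols[3] not in ("", "-") else None
        klass = cols[4] if len(cols) > 4 and cols[4] else "unknown"
        if klass not in KOTERA_CLASSES:
            klass = "unknown"
        if ca == cb:
            raise KeggIoError(
                f"row {lineno}: compound_a == compound_b ({ca})"
            )
        if require_rclass and rclass is None:
            continue
        key = (rid, frozenset((ca, cb)), rclass, klass)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        records.append(RPairRecord(rid, ca, cb, rclass, klass))
    if n_dup:
        logger.info("parse_rpair_table: dropped %d duplicate rows", n_dup)
    return records


# ---------------------------------------------------------------------------
# Filtering

def filter_reactions(
    reactions: Iterable[Reaction],
    catalog: Mapping[str, Compound],
    policy: FilterPolicy = FilterPolicy(),
) -> FilterReport:
    """Apply the dataset filters; report-only, never raises per reaction.

    Drop reasons (first matching wins): ``ill_defined_coefficient``,
    ``glycan`` (any term id starting with ``G``), ``one_to_one`` (exactly
    one aggregated compound per side, isomerisations included),
    ``missing_weight``, and optionally ``unbalanced``.
    """
    report = FilterReport()
    for rxn in reactions:
        reason = None
        if policy.ill_defined_coefficient and rxn.ill_defined:
            reason = "ill_defined_coefficient"
        elif policy.glycan and any(
            cid.startswith("G") for cid in rxn.compound_ids
        ):
            reason = "glycan"
        elif policy.one_to_one and (
            len(rxn.substrates) == 1 and len(rxn.products) == 1
        ):
            reason = "one_to_one"
        elif policy.missing_weight and any(
            cid not in catalog or catalog[cid].mol_weight is None
            for cid in rxn.compound_ids
        ):
            reason = "missing_weight"
        elif policy.unbalanced:
            left = sum(
                t.coefficient * catalog[t.compound_id].mol_weight
                for t in rxn.substrates
            )
            right = sum(
                t.coefficient * catalog[t.compound_id].mol_weight
                for t in rxn.products
            )
            if abs(left - right) / max(left, right) > policy.unbalanced_tol:
                reason = "unbalanced"
        if reason is None:
            report.kept.append(rxn.id)
        else:
            report.dropped[rxn.id] = reason
    return report


# ---------------------------------------------------------------------------
# Writers (TSV dialects consumed by the parsers above)

def write_compound_tsv(catalog: Mapping[str, Compound], handle: TextIO) -> None:
    handle.write("id\tformula\tmol_weight\n")
    for cid in sorted(catalog):
        c = catalog[cid]
        weight = "" if c.mol_weight is None else repr(c.mol_weight)
        handle.write(f"{c.id}\t{c.formula or ''}\t{weight}\n")


def _format_side(terms: Iterable[ReactionTerm]) -> str:
    parts = []
    for t in terms:
        parts.append(f"{t.coefficient} {t.compound_id}"
                     if t.coefficient != 1 else t.compound_id)
    return " + ".join(parts)


def write_reaction_tsv(reactions: Iterable[Reaction], handle: TextIO) -> None:
    handle.write("id\tequation\tecns\n")
    for r in reactions:
        equation = f"{_format_side(r.substrates)} <=> {_format_side(r.products)}"
        handle.write(f"{r.id}\t{equation}\t{';'.join(r.ecns)}\n")


def write_rpair_tsv(records: Iterable[RPairRecord], handle: TextIO) -> None:
    handle.write("reaction_id\tcompound_a\tcompound_b\trclass_id\tclass\n")
    for rec in records:
        handle.write(
            f"{rec.reaction_id}\t{rec.compound_a}\t{rec.compound_b}\t"
            f"{rec.rclass_id or ''}\t{rec.kotera_class}\n"
        )


def write_filter_report(report: FilterReport, handle: TextIO) -> None:
    handle.write("reaction_id\tstatus\treason\n")
    for rid in report.kept:
        handle.write(f"{rid}\tkept\t\n")
    for rid, reason in report.dropped.items():
        handle.write(f"{rid}\tdropped\t{reason}\n")
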