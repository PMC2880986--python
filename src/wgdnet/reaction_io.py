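"""Parsing of reaction and enzyme-gene tables, and currency-metabolite filtering.

The reaction dialect is the KEGG ``reaction_mapformula.lst`` style::

    R00001: 00010: C00001 + C00002 => C00003

i.e. a reaction identifier, a pathway-map identifier and a formula whose
direction token is one of ``=>`` (forward), ``<=`` (reverse, normalized to
forward by swapping sides) or ``<=>`` (reversible).  Enzyme-to-gene
assignments come from an AraCyc-style TSV with a header row containing
``enzyme_id``, ``gene_id`` and optionally ``reaction_id``.

Ubiquitous "currency" metabolites (ATP, NADH, ...) take part in so many
reactions that leaving them in the graph creates spurious shortcuts between
otherwise unrelated enzymes; they are removed from both sides of every
reaction before network construction.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "ReactionRecord",
    "EnzymeGeneMap",
    "CurrencyFilter",
    "ReactionParseError",
    "CURRENCY_NAME_TO_KEGG",
    "parse_reaction_mapformula",
    "parse_enzyme_gene_table",
    "apply_currency_filter",
    "format_reaction_line",
    "write_reactions_tsv",
]

FORWARD = "forward"
REVERSIBLE = "reversible"

#: The 14 currency metabolites excluded from network construction, mapped to
#: KEGG compound identifiers.  "Glu" is interpreted as L-glutamate (its
#: currency role is amine-group carrier) and "pyrophosphate" as diphosphate.
CURRENCY_NAME_TO_KEGG: Mapping[str, str] = {
    "H+": "C00080",
    "NADH": "C00004",
    "NADP": "C00006",
    "NADPH": "C00005",
    "NH3": "C00014",
    "ATP": "C00002",
    "ADP": "C00008",
    "AMP": "C00020",
    "NAD": "C00003",
    "CoA": "C00010",
    "O2": "C00007",
    "CO2": "C00011",
    "Glu": "C00025",
    "pyrophosphate": "C00013",
}


class ReactionParseError(ValueError):
    """Raised for malformed reaction or table lines; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class ReactionRecord:
    """A normalized reaction: metabolite sets and a direction.

    ``direction`` is ``"forward"`` or ``"reversible"``; reverse input lines
    are normalized to forward with sides swapped before storage.
    ``filtered_empty`` flags records whose substrate or product side became
    empty under currency filtering (they yield no enzyme interactions but are
    retained for provenance).
    """

    reaction_id: str
    substrates: frozenset[str]
    products: frozenset[str]
    direction: str = FORWARD
    pathway_id: str | None = None
    filtered_empty: bool = False

    def __post_init__(self) -> None:
        if self.direction not in (FORWARD, REVERSIBLE):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def is_reversible(self) -> bool:
        return self.direction == REVERSIBLE


@dataclass
class EnzymeGeneMap:
    """One enzyme (EC-style id), its encoding genes and catalyzed reactions."""

    enzyme_id: str
    gene_ids: set[str] = field(default_factory=set)
    catalyzed_reaction_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"enzyme {self.enzyme_id} maps to zero genes")


@dataclass(frozen=True)
class CurrencyFilter:
    """Set of metabolite identifiers to strip from every reaction side."""

    excluded_metabolites: frozenset[str]

    @classmethod
    def default(cls) -> "CurrencyFilter":
        """The default 14-metabolite currency set (KEGG compound ids)."""
        return cls(frozenset(CURRENCY_NAME_TO_KEGG.values()))

    @classmethod
    def from_names(
        cls,
        names: Iterable[str],
        table: Mapping[str, str] = CURRENCY_NAME_TO_KEGG,
    ) -> "CurrencyFilter":
        """Build a filter from common names via a name→identifier table."""
        return cls(frozenset(table[n] for n in names))

    @classmethod
    def empty(cls) -> "CurrencyFilter":
        return cls(frozenset())


def _split_metabolites(side: str, line_number: int) -> frozenset[str]:
    mets = [tok.strip() for tok in side.split("+")]
    mets = [m for m in mets if m]
    if not mets:
        raise ReactionParseError("empty metabolite side", line_number)
    return frozenset(mets)


def parse_reaction_mapformula(lines: Iterable[str] | str) -> list[ReactionRecord]:
    """Parse mapformula-dialect lines into :class:`ReactionRecord` objects.

    Reverse (``<=``) lines are normalized to forward with sides swapped;
    duplicate (reaction, pathway) lines are deduplicated, keeping the first.
    Malformed lines raise :class:`ReactionParseError` naming the line number.
    """
    if isinstance(lines, str):
        lines = io.StringIO(lines)
    records: list[ReactionRecord] = []
    seen: set[tuple[str, str | None]] = set()
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(":", 2)
        if len(parts) != 3:
            raise ReactionParseError(
                "expected 'RID: PATHWAY: formula'", i
            )
        rid, pathway, formula = (p.strip() for p in parts)
        if not rid:
            raise ReactionParseError("missing reaction id", i)
        # order matters: "<=>" contains both "<=" and "=>"
        if "<=>" in formula:
            left, right = formula.split("<=>", 1)
            direction = REVERSIBLE
            subs, prods = left, right
        elif "=>" in formula:
            subs, prods = formula.split("=>", 1)
            direction = FORWARD
        elif "<=" in formula:
            # reverse: right side feeds the left side
            prods, subs = formula.split("<=", 1)
            direction = FORWARD
        else:
            raise ReactionParseError(
                f"unknown direction token in formula {formula!r}", i
            )
        record = ReactionRecord(
            reaction_id=rid,
            pathway_id=pathway or None,
            substrates=_split_metabolites(subs, i),
            products=_split_metabolites(prods, i),
            direction=direction,
        )
        key = (record.reaction_id, record.pathway_id)
        if key in seen:
            continue
        seen.add(key)
        records.append(record)
    return records


def format_reaction_line(record: ReactionRecord) -> str:
    """Serialize a record back to the mapformula dialect (sorted metabolites)."""
    token = "<=>" if record.is_reversible else "=>"
    subs = " + ".join(sorted(record.substrates))
    prods = " + ".join(sorted(record.products))
    pathway = record.pathway_id or ""
    return f"{record.reaction_id}: {pathway}: {subs} {token} {prods}"


def parse_enzyme_gene_table(lines: Iterable[str] | str) -> dict[str, EnzymeGeneMap]:
    """Parse the enzyme-gene TSV (header required) and group rows by enzyme."""
    if isinstance(lines, str):
        lines = io.StringIO(lines)
    reader = csv.DictReader(lines, delimiter="\t")
    if reader.fieldnames is None:
        return {}
    fields = [f.strip() for f in reader.fieldnames]
    if "enzyme_id" not in fields or "gene_id" not in fields:
        raise ReactionParseError(
            "header must contain 'enzyme_id' and 'gene_id' columns", 1
        )
    has_reaction = "reaction_id" in fields
    genes: dict[str, set[str]] = {}
    reactions: dict[str, set[str]] = {}
    for i, row in enumerate(reader, start=2):
        enzyme = (row.get("enzyme_id") or "").strip()
        gene = (row.get("gene_id") or "").strip()
        if not enzyme:
            raise ReactionParseError("missing enzyme_id", i)
        if not gene:
            raise ReactionParseError(f"enzyme {enzyme}: missing gene_id", i)
        genes.setdefault(enzyme, set()).add(gene)
        rset = reactions.setdefault(enzyme, set())
        if has_reaction:
            rid = (row.get("reaction_id") or "").strip()
            if rid:
                rset.add(rid)
    return {
        enz: EnzymeGeneMap(enz, genes[enz], reactions[enz]) for enz in genes
    }


def apply_currency_filter(
    records: Iterable[ReactionRecord], currency: CurrencyFilter
) -> list[ReactionRecord]:
    """Remove excluded metabolites from both sides of every record.

    Records are retained even if a side becomes empty; such records are
    flagged (``filtered_empty``) and contribute no enzyme interactions.
    Idempotent and independent of record order.
    """
    excluded = currency.excluded_metabolites
    out: list[ReactionRecord] = []
    for rec in records:
        subs = rec.substrates - excluded
        prods = rec.products - excluded
        out.append(
            replace(
                rec,
                substrates=subs,
                products=prods,
                filtered_empty=not subs or not prods,
            )
        )
    return out


def write_reactions_tsv(records: Iterable[ReactionRecord]) -> str:
    """Normalized reactions as TSV (metabolites ';'-joined)."""
    rows = ["reaction_id\tpathway_id\tdirection\tsubstrates\tproducts"]
    for r in records:
        rows.append(
            "\t".join(
                [
                    r.reaction_id,
                    r.pathway_id or "",
                    r.direction,
                    ";".join(sorted(r.substrates)),
                    ";".join(sorted(r.products)),
                ]
            )
        )
    return "\n".join(rows) + "\n"
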