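"""Substitution-rate handling: K2P distances, ortholog minima, enzyme means.

Coding-region Ka values are consumed from input tables.  For the 1000-bp
5'/3' flanking regions the Kimura two-parameter distance is computed from a
pairwise alignment:

    d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)

with P and Q the transition and transversion proportions over ungapped,
unambiguous columns.  When an *Arabidopsis* gene has several orthologs, the
smallest rate is selected per component; enzyme-level rates are arithmetic
means over the enzyme's rated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .reaction_io import EnzymeGeneMap

__all__ = [
    "RateRecord",
    "SaturationError",
    "k2p_distance",
    "select_min_rates",
    "aggregate_enzyme_rates",
    "age_flag",
    "read_rate_table",
    "read_ortholog_groups",
    "load_aligned_pair",
    "pair_equal_length",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")


class SaturationError(ValueError):
    """The K2P distance is undefined (log argument non-positive)."""


@dataclass(frozen=True)
class RateRecord:
    """Per-gene substitution rates; missing components are ``None``."""

    gene: str
    ka: float | None = None
    k5u: float | None = None
    k3u: float | None = None

    def __post_init__(self) -> None:
        for name in ("ka", "k5u", "k3u"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


def k2p_distance(aligned_a: str, aligned_b: str) -> float:
    """Kimura two-parameter distance between two aligned nucleotide strings.

    Columns containing a gap or an ambiguity code in either sequence are
    dropped before counting.  Raises :class:`SaturationError` when the
    distance is undefined and ``ValueError`` when no usable columns remain.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    transitions = transversions = usable = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in _BASES or y not in _BASES:
            continue
        usable += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if usable == 0:
        raise ValueError("no ungapped, unambiguous columns in the alignment")
    p = transitions / usable
    q = transversions / usable
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"substitution saturation: P={p:.3f}, Q={q:.3f} leave the K2P "
            "distance undefined"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def select_min_rates(gene: str, candidates: Iterable[RateRecord]) -> RateRecord:
    """Componentwise minimum over ortholog candidates (missing ignored)."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError(f"gene {gene}: no candidate rate records")

    def _min(name: str) -> float | None:
        values = [getattr(c, name) for c in candidates if getattr(c, name) is not None]
        return min(values) if values else None

    return RateRecord(gene, ka=_min("ka"), k5u=_min("k5u"), k3u=_min("k3u"))


def aggregate_enzyme_rates(
    records: Iterable[RateRecord], enzyme_map: Mapping[str, EnzymeGeneMap]
) -> pd.DataFrame:
    """Per-enzyme mean Ka, K5u, K3u over rated genes, with per-rate counts.

    Enzymes with no rated genes are absent from the result.
    """
    by_gene = {r.gene: r for r in records}
    rows = []
    for enz in sorted(enzyme_map):
        recs = [by_gene[g] for g in sorted(enzyme_map[enz].gene_ids) if g in by_gene]
        row: dict = {"enzyme_id": enz}
        present = False
        for name in ("ka", "k5u", "k3u"):
            values = [getattr(r, name) for r in recs if getattr(r, name) is not None]
            row[f"mean_{name}"] = sum(values) / len(values) if values else float("nan")
            row[f"n_{name}"] = len(values)
            present = present or bool(values)
        if present:
            rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["mean_ka", "n_ka", "mean_k5u", "n_k5u", "mean_k3u", "n_k3u"]
        )
    return pd.DataFrame(rows).set_index("enzyme_id")


def age_flag(
    enzyme: str,
    ortholog_table: pd.DataFrame,
    enzyme_map: Mapping[str, EnzymeGeneMap],
    native_species: str = "arabidopsis",
) -> bool:
    """Whether the enzyme has ≥1 encoding gene in a cross-species ortholog group.

    ``ortholog_table`` has columns (group_id, species, gene); a group counts
    when it spans the native species and at least one other.
    """
    if enzyme not in enzyme_map or ortholog_table.empty:
        return False
    genes = enzyme_map[enzyme].gene_ids
    for _gid, group in ortholog_table.groupby("group_id"):
        species = set(group["species"])
        if native_species not in species or len(species) < 2:
            continue
        native_genes = set(group.loc[group["species"] == native_species, "gene"])
        if native_genes & genes:
            return True
    return False


def read_rate_table(source) -> list[RateRecord]:
    """Rate table TSV (gene, Ka, K5u, K3u); empty cells allowed."""
    df = pd.read_csv(source, sep="\t")
    records = []
    for _, row in df.iterrows():
        def _get(col: str) -> float | None:
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        records.append(
            RateRecord(str(row["gene"]), ka=_get("Ka"), k5u=_get("K5u"), k3u=_get("K3u"))
        )
    return records


def read_ortholog_groups(source) -> pd.DataFrame:
    """Ortholog groups TSV with columns (group_id, species, gene)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = {"group_id", "species", "gene"} - set(df.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
    return df


def load_aligned_pair(source) -> tuple[str, str]:
    """Read exactly two aligned sequences from a FASTA file."""
    records = list(SeqIO.parse(source, "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 aligned sequences, got {len(records)}")
    a, b = (str(r.seq) for r in records)
    if len(a) != len(b):
        raise ValueError("aligned FASTA sequences differ in length")
    return a, b


def pair_equal_length(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Trivial gap-free 'alignment' of two equal-length sequences (tests only)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("the trivial aligner requires equal-length sequences")
    return seq_a, seq_b
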