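"""Gene lists annotated with Alu insertion types.

A TranspoGene-style annotation maps each protein-coding gene symbol to the
set of Alu insertion types it carries (exonic, exonized, intronic,
promoter). A single gene may be inserted by several Alu copies with
different types, so the "all"-type gene count is smaller than the sum of
the per-type counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Set, Tuple

import pandas as pd

__all__ = ["INSERTION_TYPES", "AluInsertionTable", "load_insertion_table", "genes_with_type"]

#: Valid insertion types, in conventional reporting order.
INSERTION_TYPES: Tuple[str, ...] = ("exonic", "exonized", "intronic", "promoter")


@dataclass(frozen=True)
class AluInsertionTable:
    """Map from uppercased gene symbol to its non-empty set of insertion types."""

    entries: Mapping[str, FrozenSet[str]]

    def __post_init__(self):
        clean: Dict[str, FrozenSet[str]] = {}
        for gene, types in self.entries.items():
            types = frozenset(types)
            if not types:
                raise ValueError(f"gene {gene!r} has an empty insertion-type set")
            bad = types - set(INSERTION_TYPES)
            if bad:
                raise ValueError(f"gene {gene!r} has unknown insertion types {sorted(bad)}")
            clean[str(gene).upper()] = types
        object.__setattr__(self, "entries", clean)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in self.entries

    @property
    def genes(self) -> Set[str]:
        return set(self.entries)

    def genes_with_type(self, insertion_type: str) -> Set[str]:
        """Genes carrying the given type; "all" returns every annotated gene."""
        if insertion_type == "all":
            return set(self.entries)
        if insertion_type not in INSERTION_TYPES:
            raise ValueError(
                f"invalid insertion type {insertion_type!r}; "
                f"expected one of {INSERTION_TYPES + ('all',)}"
            )
        return {g for g, types in self.entries.items() if insertion_type in types}

    def counts(self) -> Dict[str, int]:
        """Gene counts per type, plus the distinct-gene total under 'all'."""
        out = {t: len(self.genes_with_type(t)) for t in INSERTION_TYPES}
        out["all"] = len(self.entries)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long form: one row per (gene, insertion_type), sorted."""
        rows = [
            (gene, t)
            for gene in sorted(self.entries)
            for t in sorted(self.entries[gene])
        ]
        return pd.DataFrame(rows, columns=["gene", "insertion_type"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "AluInsertionTable":
        """Collapse (gene, type) pairs: symbols uppercased, duplicates merged."""
        entries: Dict[str, Set[str]] = {}
        for gene, t in pairs:
            entries.setdefault(str(gene).upper(), set()).add(str(t).lower())
        return cls({g: frozenset(ts) for g, ts in entries.items()})


def load_insertion_table(path) -> AluInsertionTable:
    """Read a two-column TSV ("gene", "insertion_type"; one row per pair).

    Types are case-insensitive; duplicate rows collapse. An unknown type
    raises a ValueError naming the offending row; an empty file raises.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "insertion_type"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: annotation file contains no rows")
    types = df["insertion_type"].str.strip().str.lower()
    bad = ~types.isin(INSERTION_TYPES)
    if bad.any():
        i = int(bad.idxmax())
        raise ValueError(
            f"{path}: row {i + 2} has unknown insertion type "
            f"{df['insertion_type'].iloc[i]!r} for gene {df['gene'].iloc[i]!r}"
        )
    return AluInsertionTable.from_pairs(zip(df["gene"].str.strip(), types))


def genes_with_type(table: AluInsertionTable, insertion_type: str) -> Set[str]:
    """Module-level convenience wrapper over AluInsertionTable.genes_with_type."""
    return table.genes_with_type(insertion_type)
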