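"""Orthologue tables linking two species' gene universes.

A table is a list of ``(gene_a, gene_b)`` pairs; genes may appear in several
rows (many-to-many orthology). The one-to-one view — the rows whose two genes
each occur exactly once in the whole table — is the basis of every
cross-species operation in :mod:`nbtme.xspecies`.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

__all__ = ["OrthologueTable", "one_to_one_filter"]


class OrthologueTable:
    """Pairs of orthologous gene identifiers between species A and B."""

    def __init__(self, pairs: pd.DataFrame | Iterable[tuple[str, str]]):
        if not isinstance(pairs, pd.DataFrame):
            pairs = pd.DataFrame(list(pairs), columns=["gene_a", "gene_b"])
        if list(pairs.columns[:2]) != ["gene_a", "gene_b"]:
            pairs = pairs.rename(
                columns=dict(zip(pairs.columns[:2], ["gene_a", "gene_b"]))
            )
        self.pairs = pairs[["gene_a", "gene_b"]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def __repr__(self) -> str:
        return f"OrthologueTable({len(self)} pairs, {len(self.one_to_one())} one-to-one)"

    def one_to_one(self) -> "OrthologueTable":
        """Rows in which both genes occur exactly once in the table."""
        return one_to_one_filter(self)

    def a_to_b(self) -> Mapping[str, str]:
        """gene_a -> gene_b mapping over the one-to-one view."""
        o = self.one_to_one().pairs
        return dict(zip(o["gene_a"], o["gene_b"]))

    def b_to_a(self) -> Mapping[str, str]:
        o = self.one_to_one().pairs
        return dict(zip(o["gene_b"], o["gene_a"]))

    def rename(
        self,
        aliases_a: Mapping[str, str] | None = None,
        aliases_b: Mapping[str, str] | None = None,
    ) -> "OrthologueTable":
        """Return a table with gene identifiers substituted per species."""
        pairs = self.pairs.copy()
        if aliases_a:
            pairs["gene_a"] = pairs["gene_a"].map(lambda g: aliases_a.get(g, g))
        if aliases_b:
            pairs["gene_b"] = pairs["gene_b"].map(lambda g: aliases_b.get(g, g))
        return OrthologueTable(pairs)

    @classmethod
    def read_tsv(cls, path) -> "OrthologueTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    def equals(self, other: "OrthologueTable") -> bool:
        return self.pairs.equals(other.pairs)


def one_to_one_filter(table: OrthologueTable) -> OrthologueTable:
    """Retain exactly the rows whose both genes occur once in the input.

    Idempotent: applying it twice gives the same table.
    """
    pairs = table.pairs
    counts_a = pairs["gene_a"].value_counts()
    counts_b = pairs["gene_b"].value_counts()
    keep = (pairs["gene_a"].map(counts_a) == 1) & (pairs["gene_b"].map(counts_b) == 1)
    return OrthologueTable(pairs[keep].reset_index(drop=True))
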