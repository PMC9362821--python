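"""Gene sets, control-matched module scoring and signature-based splitting.

The per-cell signature score is the binned-control module score: all genes
are ranked by their average log-normalized expression and divided into
``n_bins`` equal-frequency bins; each signature gene contributes up to
``n_ctrl`` control genes sampled (seeded, without replacement) from its own
bin, and the score is

    score(cell) = mean expr of signature genes - mean expr of control genes,

so a signature is measured against expression-matched background rather than
raw abundance. Signature genes missing from a matrix are dropped with a
warning (the normal situation when a signature crosses species); an optional
case-folding layer matches mouse/human symbol capitalization (Apoe / APOE).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import LogNormMatrix

__all__ = [
    "GeneSet",
    "SignatureRegistry",
    "ScoreVector",
    "load_signatures",
    "score_signature",
    "score_registry",
    "split_by_signatures",
    "receptor_coverage",
]


@dataclass
class GeneSet:
    """A named, ordered gene list (a signature)."""

    name: str
    genes: list[str]
    species: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.genes = list(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


class SignatureRegistry:
    """Named collection of :class:`GeneSet`, preserving insertion order."""

    def __init__(self, entries: Iterable[GeneSet] = ()):
        self.entries: dict[str, GeneSet] = {}
        for gs in entries:
            self.add(gs)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.entries:
            raise ValueError(f"duplicate signature name {gene_set.name!r}")
        self.entries[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> GeneSet:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def read_json(cls, path) -> "SignatureRegistry":
        with open(path) as fh:
            raw = json.load(fh)
        reg = cls()
        for name, entry in raw.items():
            reg.add(
                GeneSet(
                    name=name,
                    genes=entry["genes"],
                    species=entry.get("species"),
                    source=entry.get("source"),
                )
            )
        return reg

    @classmethod
    def read_tsv(cls, path) -> "SignatureRegistry":
        """Two-column TSV (set name, gene), rows grouped by set."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        name_col, gene_col = df.columns[:2]
        reg = cls()
        for name, group in df.groupby(name_col, sort=False):
            reg.add(GeneSet(name=str(name), genes=group[gene_col].tolist()))
        return reg

    def to_json(self, path) -> None:
        raw = {
            name: {
                "genes": gs.genes,
                **({"species": gs.species} if gs.species else {}),
                **({"source": gs.source} if gs.source else {}),
            }
            for name, gs in self.entries.items()
        }
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=1)


def load_signatures(species: str) -> SignatureRegistry:
    """Bundled signature fixtures for ``"mouse"`` or ``"human"``.

    Mouse: the common macrophage program, the three macrophage-subset short
    signatures (Pecam1+/Ccr2+/Apoe+), the MDSC markers, the dPVL/imPVL
    perivascular sets and the conserved MDSC genes. Human: inhibitory
    receptors, conserved MDSC genes and the PVL sets in human symbols.
    External published signatures (M1/M2, activated PMN-MDSC, CAF-S1/S4,
    iCAF) are user-supplied via :meth:`SignatureRegistry.read_json` /
    :meth:`read_tsv`.
    """
    from importlib import resources

    ref = resources.files("nbtme.data").joinpath(f"signatures_{species}.json")
    if not ref.is_file():
        raise ValueError(f"no bundled signatures for species {species!r}")
    with resources.as_file(ref) as path:
        return SignatureRegistry.read_json(path)


@dataclass
class ScoreVector:
    """Per-cell signature scores plus the parameters that produced them."""

    scores: pd.Series
    signature: str
    n_bins: int
    n_ctrl: int
    seed: int
    missing_genes: list[str] = field(default_factory=list)


def _match_genes(
    genes: Sequence[str], universe: pd.Index, case_insensitive: bool
) -> tuple[list[str], list[str]]:
    """Map requested gene ids onto the matrix universe; return (present, missing)."""
    present, missing = [], []
    folded = None
    if case_insensitive:
        folded = {}
        for g in universe:
            folded.setdefault(str(g).casefold(), g)
    for g in genes:
        if g in universe:
            present.append(g)
        elif folded is not None and g.casefold() in folded:
            present.append(folded[g.casefold()])
        else:
            missing.append(g)
    return present, missing


def score_signature(
    lognorm: LogNormMatrix,
    gene_set: GeneSet | Sequence[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    case_insensitive: bool = False,
) -> ScoreVector:
    """Binned-control module score of a signature for every cell.

    Control genes are drawn per signature gene from the same
    average-expression bin: ``min(n_ctrl, bin size)`` genes sampled without
    replacement, seeded. Missing signature genes are dropped with a warning;
    if none is present an error lists them all.
    """
    genes = list(gene_set.genes) if isinstance(gene_set, GeneSet) else list(gene_set)
    sig_name = gene_set.name if isinstance(gene_set, GeneSet) else "signature"
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be >= 1")
    present, missing = _match_genes(genes, lognorm.genes, case_insensitive)
    if not present:
        raise ValueError(
            f"no gene of signature {sig_name!r} is present in the matrix; "
            f"missing: {missing}"
        )
    if missing:
        warnings.warn(
            f"signature {sig_name!r}: {len(missing)} gene(s) absent from matrix: "
            f"{missing[:10]}",
            stacklevel=2,
        )

    X = lognorm.values
    avg = X.mean(axis=1)
    # equal-frequency bins over gene average expression, ties broken by order
    rank = avg.rank(method="first") - 1
    bin_of = np.floor(rank * n_bins / len(avg)).astype(int)
    bin_members = {b: idx.tolist() for b, idx in avg.groupby(bin_of).groups.items()}

    rng = np.random.default_rng(seed)
    ctrl: list[str] = []
    for g in present:
        members = bin_members[int(bin_of[g])]
        if len(members) <= n_ctrl:
            ctrl.extend(members)
        else:
            pick = rng.choice(len(members), size=n_ctrl, replace=False)
            ctrl.extend(members[i] for i in np.sort(pick))
    sig_mean = X.loc[present].mean(axis=0)
    ctrl_mean = X.loc[ctrl].mean(axis=0)
    scores = (sig_mean - ctrl_mean).rename(sig_name)
    return ScoreVector(
        scores=scores,
        signature=sig_name,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        missing_genes=missing,
    )


def score_registry(
    lognorm: LogNormMatrix,
    registry: SignatureRegistry,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    case_insensitive: bool = False,
) -> pd.DataFrame:
    """Score every registry signature; failures are collected, not fatal.

    Returns a cell x signature DataFrame in registry order; signatures that
    cannot be scored (no gene present) yield a column of NaN and a warning.
    """
    columns = {}
    for name in registry.names():
        try:
            columns[name] = score_signature(
                lognorm,
                registry[name],
                n_bins=n_bins,
                n_ctrl=n_ctrl,
                seed=seed,
                case_insensitive=case_insensitive,
            ).scores
        except ValueError as err:
            warnings.warn(f"signature {name!r} not scored: {err}", stacklevel=2)
            columns[name] = pd.Series(np.nan, index=lognorm.cells)
    return pd.DataFrame(columns, index=lognorm.cells)


def split_by_signatures(
    lognorm: LogNormMatrix,
    cells_subset: Sequence[str],
    sig_a: GeneSet,
    sig_b: GeneSet,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    case_insensitive: bool = False,
) -> pd.Series:
    """Split a cell subset between two signatures.

    A cell is labeled with ``sig_a.name`` when its A score exceeds both the
    B score and zero (symmetrically for B), otherwise ``"unassigned"``.
    Scoring is restricted to the subset so control bins reflect the
    sub-population being split.
    """
    cells_subset = list(cells_subset)
    if not cells_subset:
        raise ValueError("cells_subset is empty")
    sub = lognorm.subset_cells(cells_subset)
    kwargs = dict(
        n_bins=n_bins, n_ctrl=n_ctrl, seed=seed, case_insensitive=case_insensitive
    )
    score_a = score_signature(sub, sig_a, **kwargs).scores
    score_b = score_signature(sub, sig_b, **kwargs).scores
    out = pd.Series("unassigned", index=sub.cells, dtype=object, name="split")
    out[(score_a > score_b) & (score_a > 0)] = sig_a.name
    out[(score_b > score_a) & (score_b > 0)] = sig_b.name
    return out


def receptor_coverage(
    lognorm: LogNormMatrix,
    receptor_set: GeneSet | Sequence[str],
    cells_subset: Sequence[str] | None = None,
    expr_threshold: float = 0.0,
    case_insensitive: bool = False,
) -> tuple[pd.Series, float]:
    """Fraction of cells expressing at least one receptor above threshold.

    Emulates the exhaustion readout: a T cell counts as covered when any of
    the inhibitory receptors (LAG3, TIGIT, CTLA4, HAVCR2, PDCD1) exceeds
    ``expr_threshold`` in log-normalized expression. Returns the per-cell
    indicator and the covered fraction.
    """
    receptors = (
        list(receptor_set.genes) if isinstance(receptor_set, GeneSet) else list(receptor_set)
    )
    cells = list(cells_subset) if cells_subset is not None else list(lognorm.cells)
    if not cells:
        raise ValueError("cells_subset is empty")
    present, missing = _match_genes(receptors, lognorm.genes, case_insensitive)
    if not present:
        raise ValueError(f"no receptor gene present in matrix; missing: {missing}")
    if missing:
        warnings.warn(
            f"receptor genes absent from matrix: {missing}", stacklevel=2
        )
    sub = lognorm.values.loc[present, cells]
    positive = (sub > expr_threshold).any(axis=0).rename("any_receptor")
    return positive, float(positive.mean())
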