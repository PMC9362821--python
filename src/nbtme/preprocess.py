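"""Normalization, feature selection, clustering and cluster annotation.

The pipeline mirrors the standard droplet workflow: per-cell depth
normalization to a fixed total followed by log1p, dispersion-based selection
of highly variable genes, per-gene standardization with clipping, PCA, and
either k-means (``k`` given) or Leiden community detection on a kNN graph
(``resolution`` given). Clusters are then annotated against a registry of
canonical cell-type markers (e.g. Cd3e for T cells, Cd68 for macrophages,
Phox2b for neuroblastoma tumour cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import CountMatrix, LogNormMatrix

__all__ = [
    "ClusterLabels",
    "MarkerRegistry",
    "Annotation",
    "lognormalize",
    "select_hvg",
    "scale_genes",
    "cluster_cells",
    "annotate_clusters",
    "load_marker_registry",
]

SENSES = ("high", "intermediate", "absent")


@dataclass
class ClusterLabels:
    """Per-cell cluster assignment with optional cluster -> cell-type names."""

    labels: pd.Series  # cell id -> small int, contiguous from 0
    names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        uniq = np.sort(self.labels.unique())
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster ids must be contiguous integers from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def cell_types(self) -> pd.Series:
        """Per-cell cell-type names (requires ``names``)."""
        if self.names is None:
            raise ValueError("no cluster -> cell-type names attached")
        return self.labels.map(self.names).rename("cell_type")

    def with_names(self, names: Mapping[int, str]) -> "ClusterLabels":
        return ClusterLabels(self.labels, dict(names))


class MarkerRegistry:
    """Canonical-marker registry: cell-type name -> [(gene, sense)].

    ``sense`` is ``high`` (marker expressed), ``absent`` (marker depleted) or
    ``intermediate`` (marker at mid-range level, as for CD14 on non-classical
    monocytes).
    """

    def __init__(self, entries: Mapping[str, Sequence[tuple[str, str]]]):
        self.entries: dict[str, list[tuple[str, str]]] = {}
        for cell_type, markers in entries.items():
            markers = [(g, s) for g, s in markers]
            if not markers:
                raise ValueError(f"registry entry {cell_type!r} has no genes")
            for g, s in markers:
                if s not in SENSES:
                    raise ValueError(f"unknown sense {s!r} for gene {g!r}")
            self.entries[cell_type] = markers

    def __len__(self) -> int:
        return len(self.entries)

    def cell_types(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def read_tsv(cls, path) -> "MarkerRegistry":
        df = pd.read_csv(path, sep="\t", dtype=str)
        entries: dict[str, list[tuple[str, str]]] = {}
        for row in df.itertuples(index=False):
            entries.setdefault(row.cell_type, []).append((row.gene, row.sense))
        return cls(entries)

    def to_tsv(self, path) -> None:
        rows = [
            {"cell_type": ct, "gene": g, "sense": s}
            for ct, markers in self.entries.items()
            for g, s in markers
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_marker_registry(species: str) -> MarkerRegistry:
    """Load the bundled canonical-marker registry for ``"mouse"`` or ``"human"``."""
    from importlib import resources

    fname = f"marker_registry_{species}.tsv"
    ref = resources.files("nbtme.data").joinpath(fname)
    if not ref.is_file():
        raise ValueError(f"no bundled registry for species {species!r}")
    with resources.as_file(ref) as path:
        return MarkerRegistry.read_tsv(path)


def lognormalize(counts: CountMatrix, scale_factor: float = 1e4) -> LogNormMatrix:
    """Depth-normalize to ``scale_factor`` counts per cell, then log1p.

    Every cell must have at least one count; each cell's values depend only
    on its own column, so duplicating a cell duplicates its normalized
    profile exactly.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = counts.cell_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"cells with zero total counts cannot be normalized: "
            f"{zero.index.tolist()[:5]}"
        )
    dense = counts.matrix.toarray().astype(float)
    values = np.log1p(dense * (scale_factor / totals.to_numpy())[None, :])
    return LogNormMatrix(
        pd.DataFrame(values, index=counts.genes, columns=counts.cells),
        scale_factor=scale_factor,
    )


def select_hvg(lognorm: LogNormMatrix, n_top: int) -> list[str]:
    """Top ``n_top`` genes by variance-to-mean dispersion.

    Dispersion is computed on the de-logged depth-normalized expression
    (``expm1`` of the log values), where technical noise is near-Poisson and
    the ratio is roughly flat in the mean, so genes with real
    between-population variation stand out at any expression level. Genes
    with zero mean get dispersion 0. Ties are broken by lexicographic gene
    id, making the selection deterministic.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > lognorm.n_genes:
        raise ValueError(f"n_top={n_top} exceeds {lognorm.n_genes} genes")
    X = np.expm1(lognorm.values.to_numpy())
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1) if X.shape[1] > 1 else np.zeros(X.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = sorted(
        range(lognorm.n_genes), key=lambda i: (-disp[i], lognorm.genes[i])
    )
    return [lognorm.genes[i] for i in order[:n_top]]


def scale_genes(lognorm: LogNormMatrix, cap: float = 10.0) -> pd.DataFrame:
    """Center each gene to mean 0 and unit variance (sample sd, n-1), clip to ±cap.

    Zero-variance genes map to all-zero rows.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    X = lognorm.values.to_numpy()
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True) if X.shape[1] > 1 else np.ones_like(mean)
    centered = X - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(
        np.clip(scaled, -cap, cap), index=lognorm.genes, columns=lognorm.cells
    )


def cluster_cells(
    scaled: pd.DataFrame,
    n_pcs: int = 20,
    k: int | None = None,
    resolution: float | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
) -> ClusterLabels:
    """PCA then k-means (``k``) or Leiden graph communities (``resolution``).

    Exactly one of ``k`` and ``resolution`` must be given. Deterministic for
    a fixed seed; cluster ids are relabeled contiguously by decreasing size.
    """
    n_genes, n_cells = scaled.shape
    if (k is None) == (resolution is None):
        raise ValueError("give exactly one of k (k-means) or resolution (Leiden)")
    if n_pcs > min(n_genes, n_cells):
        raise ValueError("n_pcs exceeds min(n_genes, n_cells)")
    if k is not None and k > n_cells:
        raise ValueError(f"k={k} exceeds {n_cells} cells")

    from sklearn.decomposition import PCA

    X = scaled.to_numpy().T  # cells x genes
    if k == 1:
        assignments = np.zeros(n_cells, dtype=int)
    else:
        pcs = PCA(
            n_components=n_pcs, svd_solver="full" if min(X.shape) < 1000 else "randomized",
            random_state=seed,
        ).fit_transform(X)
        if k is not None:
            from sklearn.cluster import KMeans

            assignments = KMeans(
                n_clusters=k, random_state=seed, n_init=10
            ).fit_predict(pcs)
        else:
            assignments = _leiden(pcs, resolution, seed, n_neighbors)

    # relabel contiguously, largest cluster first (stable for determinism)
    order = (
        pd.Series(assignments).value_counts(sort=True).index.to_list()
    )
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series(
        [remap[a] for a in assignments], index=scaled.columns, name="cluster"
    )
    return ClusterLabels(labels)


def _leiden(pcs: np.ndarray, resolution: float, seed: int, n_neighbors: int):
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, len(pcs))).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = {
        (min(i, j), max(i, j))
        for i, row in enumerate(idx)
        for j in row[1:]
    }
    graph = igraph.Graph(n=len(pcs), edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.array(part.membership)


@dataclass
class Annotation:
    """Cluster -> cell-type assignment with marker-evidence scores."""

    cluster_types: dict[int, str]
    scores: pd.DataFrame  # cluster x cell type, marker-evidence score
    margins: pd.Series  # cluster -> best minus second-best score
    margin_threshold: float


def annotate_clusters(
    lognorm: LogNormMatrix,
    labels: ClusterLabels,
    registry: MarkerRegistry,
    margin_threshold: float = 0.05,
) -> Annotation:
    """Assign each cluster the registry cell type with the best marker evidence.

    Cluster mean expression is z-scored per gene across clusters; a cell
    type's evidence in a cluster is the mean of ``+z`` over its "high"
    markers, ``-z`` over "absent" markers and ``-|z|`` over "intermediate"
    markers (mid-range proximity). Clusters whose margin (best minus
    second-best evidence; the best score itself when only one cell type is
    scoreable) falls below ``margin_threshold`` are labeled ``"undefined"``.
    Registry genes absent from the matrix are skipped with a warning.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    clusters = np.sort(labels.labels.unique())
    means = pd.DataFrame(
        {
            c: lognorm.values.loc[:, labels.labels[labels.labels == c].index].mean(axis=1)
            for c in clusters
        }
    )
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1) if means.shape[1] > 1 else pd.Series(0.0, index=means.index)
    z = means.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    z[sd <= 0] = 0.0

    missing: list[str] = []
    scores = pd.DataFrame(index=clusters, columns=registry.cell_types(), dtype=float)
    for cell_type, markers in registry.entries.items():
        contribs = []
        for gene, sense in markers:
            if gene not in z.index:
                missing.append(gene)
                continue
            row = z.loc[gene]
            if sense == "high":
                contribs.append(row)
            elif sense == "absent":
                contribs.append(-row)
            else:  # intermediate: proximity to mid-range
                contribs.append(-row.abs())
        if contribs:
            scores[cell_type] = pd.concat(contribs, axis=1).mean(axis=1)
    if missing:
        warnings.warn(
            f"registry genes absent from matrix were skipped: {sorted(set(missing))[:10]}",
            stacklevel=2,
        )

    cluster_types: dict[int, str] = {}
    margins = pd.Series(index=clusters, dtype=float)
    for c in clusters:
        row = scores.loc[c].dropna()
        if row.empty:
            cluster_types[int(c)] = "undefined"
            margins[c] = np.nan
            continue
        ranked = row.sort_values(ascending=False)
        margin = (
            ranked.iloc[0] - ranked.iloc[1] if len(ranked) > 1 else ranked.iloc[0]
        )
        margins[c] = margin
        cluster_types[int(c)] = (
            str(ranked.index[0]) if margin >= margin_threshold else "undefined"
        )
    return Annotation(cluster_types, scores, margins, margin_threshold)
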