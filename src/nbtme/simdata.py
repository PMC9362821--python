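"""Synthetic paired-species droplet cohorts with planted ground truth.

The generator emulates the structure of a two-species tumour-microenvironment
study: each species has a gene universe partially linked to the other by an
orthologue table, a set of cell populations defined by marker-gene programs,
and a list of samples with configured cell-type composition (optionally
differing between clinical groups). Counts follow a negative-binomial law:

    count[g, c] ~ NB(mean = baseline(g) * fold(g, pop(c)) * libfactor(c),
                     dispersion = theta)

with gene baseline means drawn from a gamma law, log-normal per-cell library
size factors, and a single global dispersion ``theta`` (variance
``mu + mu^2 / theta``). Marker genes of the cell's population have their mean
multiplied by the program's fold change. Everything is seeded and
deterministic; the full ground truth (labels, sample of origin, marker sets,
orthologue table, cognate pairs, per-sample composition) is returned next to
the count matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import CountMatrix
from .ortho import OrthologueTable

__all__ = [
    "PopulationProgram",
    "SampleSpec",
    "SpeciesDesign",
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "build_orthologue_map",
    "simulate_tme",
]

MYCN_STATUSES = ("amplified", "non_amplified")
TIMEPOINTS = ("diagnosis", "relapse")


@dataclass
class PopulationProgram:
    """A cell population defined by a marker-gene program.

    ``fold_change`` multiplies the baseline mean of every marker gene;
    ``fold_overrides`` lets individual genes deviate (e.g. an "intermediate"
    marker planted at a lower fold). ``shared_with`` names the cognate
    population in the other species whose program maps through the
    one-to-one orthologue table.
    """

    name: str
    marker_genes: list[str]
    fold_change: float = 6.0
    shared_with: str | None = None
    fold_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.marker_genes:
            raise ValueError(f"population {self.name!r}: marker_genes is empty")
        if self.fold_change < 1:
            raise ValueError(f"population {self.name!r}: fold_change must be >= 1")
        if any(f < 1 for f in self.fold_overrides.values()):
            raise ValueError(f"population {self.name!r}: fold overrides must be >= 1")
        if len(set(self.marker_genes)) != len(self.marker_genes):
            raise ValueError(f"population {self.name!r}: duplicate marker genes")

    def fold_for(self, gene: str) -> float:
        return self.fold_overrides.get(gene, self.fold_change)


@dataclass
class SampleSpec:
    """One biological sample: clinical labels, size and composition."""

    sample_id: str
    mycn_status: str
    timepoint: str
    n_cells: int
    composition: dict[str, float]

    def __post_init__(self) -> None:
        if self.mycn_status not in MYCN_STATUSES:
            raise ValueError(f"mycn_status must be one of {MYCN_STATUSES}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        props = np.array(list(self.composition.values()), dtype=float)
        if (props < 0).any():
            raise ValueError("composition proportions must be non-negative")
        if self.composition and abs(props.sum() - 1.0) > 1e-8:
            raise ValueError(
                f"sample {self.sample_id}: composition sums to {props.sum():.6f}, not 1"
            )


@dataclass
class SpeciesDesign:
    """Gene universe, populations and samples for one species."""

    name: str
    genes: list[str]
    populations: list[PopulationProgram]
    samples: list[SampleSpec]

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError(f"species {self.name!r}: populations list is empty")
        universe = set(self.genes)
        if len(universe) != len(self.genes):
            raise ValueError(f"species {self.name!r}: duplicate gene ids")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError(f"species {self.name!r}: duplicate population names")
        for pop in self.populations:
            stray = set(pop.marker_genes) - universe
            if stray:
                raise ValueError(
                    f"population {pop.name!r}: markers outside the gene universe: "
                    f"{sorted(stray)[:5]}"
                )
        for smp in self.samples:
            stray = set(smp.composition) - set(names)
            if stray:
                raise ValueError(
                    f"sample {smp.sample_id}: unknown populations {sorted(stray)}"
                )

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def marker_sets(self) -> dict[str, list[str]]:
        return {p.name: list(p.marker_genes) for p in self.populations}


@dataclass
class SimConfig:
    """Full description of a (possibly paired-species) simulation.

    ``species_b`` and ``orthologues`` are ``None`` for a single-species run.
    ``exact_composition`` allocates cells to populations deterministically in
    the configured proportions instead of drawing them multinomially.
    """

    species_a: SpeciesDesign
    species_b: SpeciesDesign | None = None
    orthologues: OrthologueTable | None = None
    baseline_mean_shape: float = 0.5
    baseline_mean_scale: float = 1.0
    marker_baseline_min: float = 0.25
    nb_dispersion: float = 2.0
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.3
    exact_composition: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in [
            ("baseline_mean_shape", self.baseline_mean_shape),
            ("baseline_mean_scale", self.baseline_mean_scale),
            ("nb_dispersion", self.nb_dispersion),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.species_b is not None and self.orthologues is None:
            raise ValueError("paired-species config requires an orthologue table")

    @property
    def designs(self) -> list[SpeciesDesign]:
        out = [self.species_a]
        if self.species_b is not None:
            out.append(self.species_b)
        return out

    def cognate_pairs(self) -> list[tuple[str, str]]:
        """(population_a, population_b) pairs declared via ``shared_with``."""
        if self.species_b is None:
            return []
        names_b = set(self.species_b.population_names)
        pairs = []
        for pop in self.species_a.populations:
            if pop.shared_with is not None:
                if pop.shared_with not in names_b:
                    raise ValueError(
                        f"population {pop.name!r}: cognate {pop.shared_with!r} "
                        "not found in species B"
                    )
                pairs.append((pop.name, pop.shared_with))
        return pairs


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the simulated counts."""

    labels: dict[str, pd.Series]
    sample_of: dict[str, pd.Series]
    marker_sets: dict[str, dict[str, list[str]]]
    orthologues: OrthologueTable | None
    cognate_pairs: list[tuple[str, str]]
    composition: dict[str, pd.DataFrame]


@dataclass
class SimResult:
    counts: dict[str, CountMatrix]
    truth: GroundTruth


def build_orthologue_map(
    n_one_to_one: int,
    n_multi_mapped: int,
    n_unmapped_a: int = 0,
    n_unmapped_b: int = 0,
    seed: int = 0,
    prefix_a: str = "mmA",
    prefix_b: str = "hsB",
    multi_degree: int = 2,
) -> tuple[OrthologueTable, list[str], list[str]]:
    """Construct a synthetic orthologue table and the two gene universes.

    Returns ``(table, genes_a, genes_b)``. The table holds exactly
    ``n_one_to_one`` pairs in which both genes occur once, plus
    ``n_multi_mapped`` species-A genes each paired with ``multi_degree``
    species-B genes. Unmapped genes are members of the universes but absent
    from the table. Deterministic for a fixed seed.
    """
    for name, value in [
        ("n_one_to_one", n_one_to_one),
        ("n_multi_mapped", n_multi_mapped),
        ("n_unmapped_a", n_unmapped_a),
        ("n_unmapped_b", n_unmapped_b),
    ]:
        if value < 0:
            raise ValueError(f"{name} must be >= 0")
    if multi_degree < 2:
        raise ValueError("multi_degree must be >= 2")
    rng = np.random.default_rng(seed)

    o2o_a = [f"{prefix_a}{i:04d}" for i in range(1, n_one_to_one + 1)]
    o2o_b = [f"{prefix_b}{i:04d}" for i in range(1, n_one_to_one + 1)]
    multi_a = [f"{prefix_a}M{i:03d}" for i in range(1, n_multi_mapped + 1)]
    multi_b = [
        f"{prefix_b}M{i:03d}{chr(ord('a') + j)}"
        for i in range(1, n_multi_mapped + 1)
        for j in range(multi_degree)
    ]
    unmapped_a = [f"{prefix_a}U{i:04d}" for i in range(1, n_unmapped_a + 1)]
    unmapped_b = [f"{prefix_b}U{i:04d}" for i in range(1, n_unmapped_b + 1)]

    perm = rng.permutation(n_one_to_one)
    rows = [(o2o_a[i], o2o_b[perm[i]]) for i in range(n_one_to_one)]
    for i, gene_a in enumerate(multi_a):
        for j in range(multi_degree):
            rows.append((gene_a, multi_b[i * multi_degree + j]))
    table = OrthologueTable(rows)
    genes_a = o2o_a + multi_a + unmapped_a
    genes_b = o2o_b + multi_b + unmapped_b
    return table, genes_a, genes_b


def _draw_labels(
    rng: np.random.Generator,
    populations: Sequence[str],
    composition: Mapping[str, float],
    n_cells: int,
    exact: bool,
) -> np.ndarray:
    names = [p for p in populations if composition.get(p, 0.0) > 0]
    probs = np.array([composition[p] for p in names], dtype=float)
    probs = probs / probs.sum()
    if n_cells == 0:
        return np.array([], dtype=object)
    if exact:
        counts = np.floor(probs * n_cells).astype(int)
        # distribute the remainder by largest fractional part, ties by order
        rem = n_cells - counts.sum()
        frac_order = np.argsort(-(probs * n_cells - counts), kind="stable")
        counts[frac_order[:rem]] += 1
        labels = np.repeat(np.array(names, dtype=object), counts)
        rng.shuffle(labels)
        return labels
    return rng.choice(np.array(names, dtype=object), size=n_cells, p=probs)


def _simulate_species(
    rng: np.random.Generator, design: SpeciesDesign, config: SimConfig
) -> tuple[CountMatrix, pd.Series, pd.Series, pd.DataFrame]:
    genes = pd.Index(design.genes)
    n_genes = len(genes)

    baseline = rng.gamma(
        config.baseline_mean_shape, config.baseline_mean_scale, size=n_genes
    )
    # canonical markers are detectably expressed: floor their baseline mean
    marker_union = sorted({g for p in design.populations for g in p.marker_genes})
    marker_idx = genes.get_indexer(marker_union)
    baseline[marker_idx] = np.maximum(baseline[marker_idx], config.marker_baseline_min)

    fold = {}
    for pop in design.populations:
        vec = np.ones(n_genes)
        for g in pop.marker_genes:
            vec[genes.get_loc(g)] = pop.fold_for(g)
        fold[pop.name] = vec

    blocks, all_cells, all_labels, all_samples = [], [], [], []
    theta = config.nb_dispersion
    for smp in design.samples:
        labels = _draw_labels(
            rng, design.population_names, smp.composition, smp.n_cells,
            config.exact_composition,
        )
        n = len(labels)
        cells = [f"{smp.sample_id}-{i + 1:05d}" for i in range(n)]
        if n == 0:
            continue
        lib = np.exp(rng.normal(config.libsize_log_mean, config.libsize_log_sd, n))
        mean = np.empty((n_genes, n))
        for j, (lab, lf) in enumerate(zip(labels, lib)):
            mean[:, j] = baseline * fold[lab] * lf
        lam = rng.gamma(theta, mean / theta)
        counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))
        all_cells.extend(cells)
        all_labels.extend(labels)
        all_samples.extend([smp.sample_id] * n)

    if blocks:
        matrix = sp.hstack(blocks, format="csr")
    else:
        matrix = sp.csr_matrix((n_genes, 0), dtype=np.int64)
    cells = pd.Index(all_cells)
    counts_out = CountMatrix(matrix, genes, cells)
    label_series = pd.Series(all_labels, index=cells, name="population", dtype=object)
    sample_series = pd.Series(all_samples, index=cells, name="sample_id", dtype=object)
    comp = pd.DataFrame(
        [s.composition for s in design.samples],
        index=pd.Index([s.sample_id for s in design.samples], name="sample_id"),
    ).fillna(0.0)
    return counts_out, label_series, sample_series, comp


def simulate_tme(config: SimConfig) -> SimResult:
    """Simulate droplet counts for one or two species from a config.

    Identical configs (including seed) yield identical output. The returned
    :class:`GroundTruth` carries per-cell population labels and sample ids
    consistent with the emitted matrices.
    """
    rng = np.random.default_rng(config.seed)
    counts, labels, sample_of, composition = {}, {}, {}, {}
    for design in config.designs:
        cm, lab, smp, comp = _simulate_species(rng, design, config)
        counts[design.name] = cm
        labels[design.name] = lab
        sample_of[design.name] = smp
        composition[design.name] = comp

    if config.species_b is not None:
        _check_cognate_consistency(config)

    truth = GroundTruth(
        labels=labels,
        sample_of=sample_of,
        marker_sets={d.name: d.marker_sets() for d in config.designs},
        orthologues=config.orthologues,
        cognate_pairs=config.cognate_pairs(),
        composition=composition,
    )
    return SimResult(counts=counts, truth=truth)


def config_from_dict(raw: Mapping) -> SimConfig:
    """Build a :class:`SimConfig` from a plain dict (YAML/JSON payload)."""

    def _pop(p: Mapping) -> PopulationProgram:
        return PopulationProgram(
            name=p["name"],
            marker_genes=list(p["marker_genes"]),
            fold_change=float(p.get("fold_change", 6.0)),
            shared_with=p.get("shared_with"),
            fold_overrides=dict(p.get("fold_overrides", {})),
        )

    def _design(sd: Mapping) -> SpeciesDesign:
        return SpeciesDesign(
            name=sd["name"],
            genes=list(sd["genes"]),
            populations=[_pop(p) for p in sd["populations"]],
            samples=[SampleSpec(**s) for s in sd["samples"]],
        )

    orth = raw.get("orthologues")
    scalars = {
        k: raw[k]
        for k in (
            "baseline_mean_shape", "baseline_mean_scale", "marker_baseline_min",
            "nb_dispersion", "libsize_log_mean", "libsize_log_sd",
            "exact_composition", "seed",
        )
        if k in raw
    }
    return SimConfig(
        species_a=_design(raw["species_a"]),
        species_b=_design(raw["species_b"]) if raw.get("species_b") else None,
        orthologues=OrthologueTable([tuple(p) for p in orth]) if orth else None,
        **scalars,
    )


def config_to_dict(config: SimConfig) -> dict:
    """Inverse of :func:`config_from_dict`."""

    def _pop(p: PopulationProgram) -> dict:
        d = {"name": p.name, "marker_genes": p.marker_genes, "fold_change": p.fold_change}
        if p.shared_with:
            d["shared_with"] = p.shared_with
        if p.fold_overrides:
            d["fold_overrides"] = p.fold_overrides
        return d

    def _design(sd: SpeciesDesign) -> dict:
        return {
            "name": sd.name,
            "genes": sd.genes,
            "populations": [_pop(p) for p in sd.populations],
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "mycn_status": s.mycn_status,
                    "timepoint": s.timepoint,
                    "n_cells": s.n_cells,
                    "composition": s.composition,
                }
                for s in sd.samples
            ],
        }

    out = {
        "species_a": _design(config.species_a),
        "baseline_mean_shape": config.baseline_mean_shape,
        "baseline_mean_scale": config.baseline_mean_scale,
        "marker_baseline_min": config.marker_baseline_min,
        "nb_dispersion": config.nb_dispersion,
        "libsize_log_mean": config.libsize_log_mean,
        "libsize_log_sd": config.libsize_log_sd,
        "exact_composition": config.exact_composition,
        "seed": config.seed,
    }
    if config.species_b is not None:
        out["species_b"] = _design(config.species_b)
        out["orthologues"] = [list(r) for r in config.orthologues.pairs.itertuples(index=False)]
    return out


def _check_cognate_consistency(config: SimConfig) -> None:
    """Warn when cognate programs share no one-to-one orthologue pair."""
    a_to_b = config.orthologues.a_to_b()
    pops_b = {p.name: p for p in config.species_b.populations}
    for pop in config.species_a.populations:
        if pop.shared_with is None:
            continue
        mapped = {a_to_b.get(g) for g in pop.marker_genes} - {None}
        partner = set(pops_b[pop.shared_with].marker_genes)
        if not mapped & partner:
            warnings.warn(
                f"cognate populations {pop.name!r}/{pop.shared_with!r} share no "
                "orthologue-mapped marker gene",
                stacklevel=3,
            )
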