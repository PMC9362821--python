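"""Ready-made simulation configs emulating a mouse/human TME study.

``mouse_human_cohort`` is the full paired design: three MYCN-driven mouse
tumours (~1,900 cells each) and a ten-biopsy human cohort balanced for MYCN
amplification (5/5) and diagnosis vs relapse (5/5), with eleven cell
populations per species whose programs carry the canonical marker symbols
(Phox2b, Cd68, S100a8/S100A8, ...) on one-to-one orthologue slots, so the
bundled registries and signatures apply verbatim. The cohort plants the
composition shifts of interest: MDSC proportion 0.05 at diagnosis vs 0.15 at
relapse, and more non-classical monocytes in MYCN-amplified biopsies.

The remaining presets are reduced designs for focused benchmarks: a
single-species marker-recovery panel, a paired 6-shared + 2-species-specific
design for the cluster-correspondence procedure, a two-program fibroblast
mixture for signature splitting, and a light cohort for composition
statistics.
"""

from __future__ import annotations

from .ortho import OrthologueTable
from .simdata import (
    PopulationProgram,
    SampleSpec,
    SimConfig,
    SpeciesDesign,
    build_orthologue_map,
)

__all__ = [
    "mouse_human_cohort",
    "marker_recovery",
    "xspecies_benchmark",
    "caf_split_mixture",
    "cohort_composition",
    "PRESETS",
]

# canonical (mouse, human) symbols occupying one-to-one orthologue slots
_ALIAS_PAIRS = [
    ("Phox2b", "PHOX2B"), ("Gata3", "GATA3"),
    ("Cd68", "CD68"), ("Csf1r", "CSF1R"), ("Cd86", "CD86"),
    ("Adgre1", "ADGRE1"), ("Lgals3", "LGALS3"),
    ("Cd300e", "CD300E"), ("Cd82", "CD82"), ("Pecam1", "PECAM1"),
    ("Il10", "IL10"), ("Cd274", "CD274"), ("Pglyrp1", "PGLYRP1"), ("Pag1", "PAG1"),
    ("Ccr2", "CCR2"), ("Sell", "SELL"), ("Vcan", "VCAN"),
    ("Fn1", "FN1"), ("F13a1", "F13A1"),
    ("Apoe", "APOE"), ("C1qb", "C1QB"), ("Cd63", "CD63"),
    ("S100a8", "S100A8"), ("S100a9", "S100A9"), ("Mmp9", "MMP9"),
    ("Cd14", "CD14"), ("Il1b", "IL1B"), ("Arg2", "ARG2"),
    ("Cebpb", "CEBPB"), ("Cxcr2", "CXCR2"), ("Trem1", "TREM1"),
    ("Hif1a", "HIF1A"), ("Ptgs2", "PTGS2"),
    ("Cd3e", "CD3E"), ("Cd3d", "CD3D"), ("Cd4", "CD4"), ("Cd8a", "CD8A"),
    ("Lag3", "LAG3"), ("Tigit", "TIGIT"), ("Ctla4", "CTLA4"),
    ("Havcr2", "HAVCR2"), ("Pdcd1", "PDCD1"),
    ("Cd79a", "CD79A"), ("Ms4a1", "MS4A1"),
    ("Nkg7", "NKG7"), ("Gzmb", "GZMB"),
    ("Irf8", "IRF8"), ("Flt3", "FLT3"),
    ("Col1a1", "COL1A1"), ("Col1a2", "COL1A2"),
    ("Pdgfrb", "PDGFRB"), ("Acta2", "ACTA2"),
    ("Vwf", "VWF"), ("Eng", "ENG"), ("Cdh5", "CDH5"),
    ("Tagln", "TAGLN"), ("Cd9", "CD9"), ("Mylk", "MYLK"), ("Cnn1", "CNN1"),
    ("Cd36", "CD36"), ("Notch3", "NOTCH3"), ("Rgs5", "RGS5"),
    ("Rhob", "RHOB"), ("Itga1", "ITGA1"),
]
_MOUSE_ONLY = ["Ly6c2"]
_HUMAN_ONLY = ["FCGR3A", "FCGR3B", "CD1C", "FOLR2"]

_MDSC_PAIRS = [
    ("S100a8", "S100A8"), ("S100a9", "S100A9"), ("Mmp9", "MMP9"),
    ("Cebpb", "CEBPB"), ("Cxcr2", "CXCR2"), ("Trem1", "TREM1"),
    ("Hif1a", "HIF1A"), ("Ptgs2", "PTGS2"), ("Il1b", "IL1B"), ("Arg2", "ARG2"),
]

# canonical marker programs; synthetic one-to-one genes top them up
_MOUSE_PROGRAMS: dict[str, list[str]] = {
    "tumor": ["Phox2b", "Gata3"],
    "macrophage_pecam1": ["Cd68", "Csf1r", "Cd86", "Adgre1", "Lgals3",
                          "Cd300e", "Cd82", "Pecam1", "Il10", "Cd274",
                          "Pglyrp1", "Pag1"],
    "macrophage_ccr2": ["Cd68", "Csf1r", "Cd86", "Adgre1", "Lgals3",
                        "Ccr2", "Sell", "Vcan", "Ly6c2", "Fn1", "F13a1"],
    "macrophage_apoe": ["Cd68", "Csf1r", "Cd86", "Adgre1", "Lgals3",
                        "Apoe", "C1qb", "Cd63"],
    "mdsc": ["S100a8", "S100a9", "Mmp9", "Cd14", "Il1b", "Arg2",
             "Cebpb", "Cxcr2", "Trem1", "Hif1a", "Ptgs2"],
    "t_cell": ["Cd3e", "Cd3d", "Cd4", "Cd8a", "Lag3", "Tigit",
               "Ctla4", "Havcr2", "Pdcd1"],
    "b_cell": ["Cd79a", "Ms4a1"],
    "nk": ["Nkg7", "Gzmb"],
    "dc": ["Irf8", "Flt3"],
    "caf": ["Col1a1", "Col1a2", "Pdgfrb", "Acta2", "Fn1"],
    "endothelial": ["Vwf", "Eng", "Cdh5"],
}

_HUMAN_PROGRAMS: dict[str, list[str]] = {
    "tumor": ["PHOX2B", "GATA3"],
    "nc_monocyte": ["FCGR3A", "CD300E", "CD82", "PAG1", "CD274", "CD14"],
    "monocyte": ["CD14", "CCR2", "SELL", "VCAN", "FN1", "F13A1"],
    "macrophage": ["CD68", "CSF1R", "CD86", "LGALS3", "APOE", "C1QB",
                   "CD63", "FOLR2"],
    "mdsc": ["S100A8", "S100A9", "MMP9", "FCGR3B", "CD14", "IL1B", "ARG2",
             "CEBPB", "CXCR2", "TREM1", "HIF1A", "PTGS2"],
    "t_cell": ["CD3E", "CD3D", "CD4", "CD8A", "LAG3", "TIGIT",
               "CTLA4", "HAVCR2", "PDCD1"],
    "b_cell": ["CD79A", "MS4A1"],
    "nk": ["NKG7", "GZMB"],
    "cdc": ["CD1C", "IRF8", "FLT3"],
    "caf": ["COL1A1", "COL1A2", "PDGFRB", "ACTA2", "FN1"],
    "endothelial": ["VWF", "ENG", "CDH5"],
}

# mouse population -> human cognate (the correspondence the design plants)
_COGNATES = {
    "tumor": "tumor",
    "macrophage_pecam1": "nc_monocyte",
    "macrophage_ccr2": "monocyte",
    "macrophage_apoe": "macrophage",
    "mdsc": "mdsc",
    "t_cell": "t_cell",
    "b_cell": "b_cell",
    "nk": "nk",
    "dc": "cdc",
    "caf": "caf",
    "endothelial": "endothelial",
}

# subset-defining short-signature genes are strongly expressed in their
# subset (they were chosen as defining markers precisely for that reason),
# so they carry a higher planted fold than the rest of the program
_SUBSET_FOLD = 12.0
_MOUSE_FOLD_OVERRIDES = {
    "macrophage_pecam1": {g: _SUBSET_FOLD for g in
                          ["Cd300e", "Cd82", "Pecam1", "Il10", "Cd274",
                           "Pglyrp1", "Pag1"]},
    "macrophage_ccr2": {g: _SUBSET_FOLD for g in
                        ["Ccr2", "Sell", "Vcan", "Ly6c2", "Fn1", "F13a1"]},
    "macrophage_apoe": {g: _SUBSET_FOLD for g in ["Apoe", "C1qb", "Cd63"]},
    "mdsc": {g: _SUBSET_FOLD for g in ["S100a8", "S100a9", "Mmp9"]},
}
# intermediate CD14 on non-classical monocytes
_HUMAN_FOLD_OVERRIDES = {
    "nc_monocyte": {"CD14": 2.0,
                    **{g: _SUBSET_FOLD for g in
                       ["CD300E", "CD82", "PAG1", "CD274"]}},
    "monocyte": {g: _SUBSET_FOLD for g in
                 ["CCR2", "SELL", "VCAN", "FN1", "F13A1"]},
    "macrophage": {g: _SUBSET_FOLD for g in ["APOE", "C1QB", "CD63"]},
    "mdsc": {g: _SUBSET_FOLD for g in ["S100A8", "S100A9", "MMP9", "FCGR3B"]},
}

_MOUSE_COMPOSITION = {
    "tumor": 0.40, "macrophage_apoe": 0.10, "macrophage_ccr2": 0.08,
    "macrophage_pecam1": 0.07, "mdsc": 0.12, "t_cell": 0.05, "b_cell": 0.04,
    "nk": 0.03, "dc": 0.03, "caf": 0.04, "endothelial": 0.04,
}

_HUMAN_BASE_COMPOSITION = {
    "tumor": 0.35, "macrophage": 0.12, "monocyte": 0.10, "nc_monocyte": 0.05,
    "mdsc": 0.05, "t_cell": 0.12, "b_cell": 0.05, "nk": 0.04, "cdc": 0.03,
    "caf": 0.05, "endothelial": 0.04,
}
MDSC_RELAPSE_PROPORTION = 0.15  # vs 0.05 at diagnosis; delta comes out of tumor
NC_MONOCYTE_AMPLIFIED_EXTRA = 0.03

# (sample_id, mycn_status, timepoint): 5/5 on both factors, not confounded
_HUMAN_SAMPLES = [
    ("P01", "amplified", "diagnosis"), ("P02", "amplified", "diagnosis"),
    ("P03", "non_amplified", "diagnosis"), ("P04", "non_amplified", "diagnosis"),
    ("P05", "non_amplified", "diagnosis"),
    ("P06", "amplified", "relapse"), ("P07", "amplified", "relapse"),
    ("P08", "amplified", "relapse"), ("P09", "non_amplified", "relapse"),
    ("P10", "non_amplified", "relapse"),
]


def human_sample_composition(mycn_status: str, timepoint: str) -> dict[str, float]:
    """Planted composition for one human biopsy given its clinical group."""
    comp = dict(_HUMAN_BASE_COMPOSITION)
    if timepoint == "relapse":
        delta = MDSC_RELAPSE_PROPORTION - comp["mdsc"]
        comp["mdsc"] = MDSC_RELAPSE_PROPORTION
        comp["tumor"] -= delta
    if mycn_status == "amplified":
        comp["nc_monocyte"] += NC_MONOCYTE_AMPLIFIED_EXTRA
        comp["tumor"] -= NC_MONOCYTE_AMPLIFIED_EXTRA
    return comp


def human_sample_specs(cells_per_sample: int = 400) -> list[SampleSpec]:
    return [
        SampleSpec(
            sample_id=sid,
            mycn_status=status,
            timepoint=tp,
            n_cells=cells_per_sample,
            composition=human_sample_composition(status, tp),
        )
        for sid, status, tp in _HUMAN_SAMPLES
    ]


def _aliased_map(
    n_one_to_one: int,
    n_multi_mapped: int,
    n_unmapped_a: int,
    n_unmapped_b: int,
    seed: int,
) -> tuple[OrthologueTable, list[str], list[str], list[tuple[str, str]]]:
    """Orthologue map with canonical symbols substituted onto real slots.

    Returns the renamed table and universes plus the remaining (unaliased)
    one-to-one pairs available as synthetic marker slots.
    """
    table, genes_a, genes_b = build_orthologue_map(
        n_one_to_one, n_multi_mapped, n_unmapped_a, n_unmapped_b,
        seed=seed, prefix_a="mm", prefix_b="hs",
    )
    o2o = table.one_to_one().pairs
    if len(o2o) < len(_ALIAS_PAIRS):
        raise ValueError("gene universe too small for the canonical alias set")
    amap = {o2o.iloc[i]["gene_a"]: m for i, (m, _) in enumerate(_ALIAS_PAIRS)}
    bmap = {o2o.iloc[i]["gene_b"]: h for i, (_, h) in enumerate(_ALIAS_PAIRS)}
    for i, name in enumerate(_MOUSE_ONLY):
        amap[f"mmU{i + 1:04d}"] = name
    for i, name in enumerate(_HUMAN_ONLY):
        bmap[f"hsU{i + 1:04d}"] = name
    if len(_MOUSE_ONLY) > n_unmapped_a or len(_HUMAN_ONLY) > n_unmapped_b:
        raise ValueError("not enough unmapped genes for species-only symbols")
    table = table.rename(amap, bmap)
    genes_a = [amap.get(g, g) for g in genes_a]
    genes_b = [bmap.get(g, g) for g in genes_b]
    spare = [
        (r.gene_a, r.gene_b)
        for r in table.one_to_one().pairs.iloc[len(_ALIAS_PAIRS):].itertuples()
    ]
    return table, genes_a, genes_b, spare


def mouse_human_cohort(
    seed: int = 0,
    n_genes: int = 2000,
    n_one_to_one: int = 1500,
    n_multi_mapped: int = 100,
    fold_change: float = 6.0,
    synthetic_markers_per_population: int = 8,
    mouse_cells_per_sample: int = 1900,
    human_cells_per_sample: int = 400,
) -> SimConfig:
    """The full paired mouse/human study design (see module docstring)."""
    n_unmapped_a = n_genes - n_one_to_one - n_multi_mapped
    n_unmapped_b = n_genes - n_one_to_one - 2 * n_multi_mapped
    table, genes_a, genes_b, spare = _aliased_map(
        n_one_to_one, n_multi_mapped, n_unmapped_a, n_unmapped_b, seed
    )

    pops_a, pops_b = [], []
    cursor = 0
    for mouse_name, human_name in _COGNATES.items():
        chunk = spare[cursor:cursor + synthetic_markers_per_population]
        cursor += synthetic_markers_per_population
        pops_a.append(
            PopulationProgram(
                name=mouse_name,
                marker_genes=_MOUSE_PROGRAMS[mouse_name] + [p[0] for p in chunk],
                fold_change=fold_change,
                shared_with=human_name,
                fold_overrides=_MOUSE_FOLD_OVERRIDES.get(mouse_name, {}),
            )
        )
        pops_b.append(
            PopulationProgram(
                name=human_name,
                marker_genes=_HUMAN_PROGRAMS[human_name] + [p[1] for p in chunk],
                fold_change=fold_change,
                fold_overrides=_HUMAN_FOLD_OVERRIDES.get(human_name, {}),
            )
        )

    mouse_samples = [
        SampleSpec(
            sample_id=f"T{i}",
            mycn_status="amplified",
            timepoint="diagnosis",
            n_cells=mouse_cells_per_sample,
            composition=dict(_MOUSE_COMPOSITION),
        )
        for i in (1, 2, 3)
    ]
    return SimConfig(
        species_a=SpeciesDesign("mouse", genes_a, pops_a, mouse_samples),
        species_b=SpeciesDesign(
            "human", genes_b, pops_b, human_sample_specs(human_cells_per_sample)
        ),
        orthologues=table,
        seed=seed,
    )


def marker_recovery(
    seed: int = 0,
    fold_change: float = 4.0,
    n_populations: int = 8,
    cells_per_population: int = 200,
    n_genes: int = 1000,
    markers_per_population: int = 20,
) -> SimConfig:
    """Single-species panel for marker-detection benchmarks.

    ``n_populations`` equally sized populations with disjoint planted marker
    programs; ``fold_change=1`` gives the matched null design (no gene
    differs between populations).
    """
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    pops = []
    for p in range(n_populations):
        start = p * markers_per_population
        pops.append(
            PopulationProgram(
                name=f"pop{p}",
                marker_genes=genes[start:start + markers_per_population],
                fold_change=fold_change,
            )
        )
    n_cells = n_populations * cells_per_population
    sample = SampleSpec(
        sample_id="S1",
        mycn_status="amplified",
        timepoint="diagnosis",
        n_cells=n_cells,
        composition={p.name: 1.0 / n_populations for p in pops},
    )
    return SimConfig(
        species_a=SpeciesDesign("panel", genes, pops, [sample]),
        exact_composition=True,
        seed=seed,
    )


def xspecies_benchmark(
    seed: int = 0,
    n_shared: int = 6,
    n_specific: int = 2,
    fold_change: float = 4.0,
    cells_per_population: int = 150,
    n_genes: int = 1000,
    n_one_to_one: int = 800,
    n_multi_mapped: int = 50,
    markers_per_population: int = 20,
) -> SimConfig:
    """Paired design with shared (cognate) and species-specific populations.

    The first shared population is an MDSC-like program carrying the
    canonical mouse/human MDSC symbols; the remaining shared programs are
    synthetic orthologue pairs. Species-specific populations are modelled as
    related variants of shared cell types: half of each program overlaps a
    shared program of its own species (a different one per specific
    population and per species) and half comes from unmapped genes, so the
    population resembles an existing type without having any cognate. One
    sample per species with exact uniform composition.
    """
    if n_shared < 1:
        raise ValueError("need at least one shared population")
    if n_specific and n_shared < 2 * n_specific + 1:
        raise ValueError("need n_shared >= 2 * n_specific + 1 for distinct relatives")
    n_unmapped_a = n_genes - n_one_to_one - n_multi_mapped
    n_unmapped_b = n_genes - n_one_to_one - 2 * n_multi_mapped
    table, genes_a, genes_b, spare = _aliased_map(
        n_one_to_one, n_multi_mapped, n_unmapped_a, n_unmapped_b, seed
    )

    pops_a, pops_b = [], []
    cursor = 0
    for s in range(n_shared):
        if s == 0:
            name = "mdsc"
            canon_a = [p[0] for p in _MDSC_PAIRS]
            canon_b = [p[1] for p in _MDSC_PAIRS]
        else:
            name = f"shared{s}"
            canon_a, canon_b = [], []
        n_extra = markers_per_population - len(canon_a)
        chunk = spare[cursor:cursor + n_extra]
        cursor += n_extra
        pops_a.append(
            PopulationProgram(
                name=name,
                marker_genes=canon_a + [p[0] for p in chunk],
                fold_change=fold_change,
                shared_with=name,
            )
        )
        pops_b.append(
            PopulationProgram(
                name=name,
                marker_genes=canon_b + [p[1] for p in chunk],
                fold_change=fold_change,
            )
        )
    # species-specific programs: half a shared program + unmapped genes
    # (skip species-only canonical aliases when slicing unmapped pools)
    un_a = [g for g in genes_a if g.startswith("mmU")]
    un_b = [g for g in genes_b if g.startswith("hsU")]
    n_half = markers_per_population // 2
    n_rest = markers_per_population - n_half
    for s in range(n_specific):
        # relatives differ between populations and species; the MDSC-like
        # program (index 0) is left untouched for projection benchmarks
        rel_a = pops_a[1 + 2 * s]
        rel_b = pops_b[2 + 2 * s]
        pops_a.append(
            PopulationProgram(
                name=f"mouse_only{s + 1}",
                marker_genes=rel_a.marker_genes[:n_half]
                + un_a[s * n_rest:(s + 1) * n_rest],
                fold_change=fold_change,
            )
        )
        pops_b.append(
            PopulationProgram(
                name=f"human_only{s + 1}",
                marker_genes=rel_b.marker_genes[:n_half]
                + un_b[s * n_rest:(s + 1) * n_rest],
                fold_change=fold_change,
            )
        )

    def one_sample(sid: str, pops: list[PopulationProgram]) -> SampleSpec:
        return SampleSpec(
            sample_id=sid,
            mycn_status="amplified",
            timepoint="diagnosis",
            n_cells=cells_per_population * len(pops),
            composition={p.name: 1.0 / len(pops) for p in pops},
        )

    return SimConfig(
        species_a=SpeciesDesign("mouse", genes_a, pops_a, [one_sample("mmT1", pops_a)]),
        species_b=SpeciesDesign("human", genes_b, pops_b, [one_sample("hsT1", pops_b)]),
        orthologues=table,
        exact_composition=True,
        seed=seed,
    )


_DPVL = ["Tagln", "Cd9", "Mylk", "Cnn1"]
_IMPVL = ["Cd36", "Notch3", "Rgs5", "Rhob", "Itga1"]


def caf_split_mixture(
    seed: int = 0,
    fold_change: float = 4.0,
    cells_per_population: int = 200,
    n_genes: int = 300,
    markers_per_population: int = 20,
) -> SimConfig:
    """Two-program fibroblast mixture for signature-based splitting.

    One program carries the differentiated-PVL markers (Tagln, Cd9, Mylk,
    Cnn1), the other the immature-PVL markers (Cd36, Notch3, Rgs5, Rhob,
    Itga1), each topped up with synthetic genes to the usual program size —
    the planted programs stand in for the published multi-gene subset
    signatures a user would supply for splitting.
    """
    synth = [f"g{i:04d}" for i in range(1, n_genes - len(_DPVL) - len(_IMPVL) + 1)]
    genes = _DPVL + _IMPVL + synth
    n_d = markers_per_population - len(_DPVL)
    n_i = markers_per_population - len(_IMPVL)
    pops = [
        PopulationProgram(
            name="caf_dpvl",
            marker_genes=_DPVL + synth[:n_d],
            fold_change=fold_change,
        ),
        PopulationProgram(
            name="caf_impvl",
            marker_genes=_IMPVL + synth[n_d:n_d + n_i],
            fold_change=fold_change,
        ),
    ]
    sample = SampleSpec(
        sample_id="F1",
        mycn_status="amplified",
        timepoint="diagnosis",
        n_cells=2 * cells_per_population,
        composition={"caf_dpvl": 0.5, "caf_impvl": 0.5},
    )
    return SimConfig(
        species_a=SpeciesDesign("fibroblasts", genes, pops, [sample]),
        exact_composition=True,
        seed=seed,
    )


def cohort_composition(
    seed: int = 0,
    cells_per_sample: int = 400,
    markers_per_population: int = 3,
) -> SimConfig:
    """Light human-cohort design for composition statistics.

    Same samples, clinical groups and planted composition shifts as
    :func:`mouse_human_cohort`, with a minimal gene universe — composition
    estimates depend only on the cell labels.
    """
    names = list(_HUMAN_BASE_COMPOSITION)
    n_genes = markers_per_population * len(names) + 10
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    pops = [
        PopulationProgram(
            name=name,
            marker_genes=genes[i * markers_per_population:(i + 1) * markers_per_population],
            fold_change=6.0,
        )
        for i, name in enumerate(names)
    ]
    return SimConfig(
        species_a=SpeciesDesign(
            "human", genes, pops, human_sample_specs(cells_per_sample)
        ),
        seed=seed,
    )


PRESETS = {
    "mouse_human_cohort": mouse_human_cohort,
    "marker_recovery": marker_recovery,
    "xspecies_benchmark": xspecies_benchmark,
    "caf_split_mixture": caf_split_mixture,
    "cohort_composition": cohort_composition,
}
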