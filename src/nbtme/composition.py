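"""Per-sample cell-type composition and group-wise comparison.

Proportions are computed per sample (optionally excluding tumour cells so
only the microenvironment is compared) and clinical groups — MYCN status or
diagnosis vs relapse — are compared descriptively: difference of group mean
proportions per cell type with a seeded percentile bootstrap over samples.
No hypothesis test is emitted; with cohorts of ~5 samples per group the
honest output is an effect estimate with resampling uncertainty.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["read_sample_metadata", "cluster_proportions", "compare_groups"]


def read_sample_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with a ``sample_id`` column as index."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return meta.set_index("sample_id")


def cluster_proportions(
    cell_types: pd.Series,
    cell_to_sample: pd.Series,
    scope: str = "all",
    tumor_labels: Sequence[str] = ("tumor",),
) -> pd.DataFrame:
    """Per-sample cell-type proportions.

    ``scope="tme"`` drops cells labeled with any of ``tumor_labels`` before
    normalizing, so proportions describe the microenvironment only. Samples
    left with zero in-scope cells are dropped with a warning. Rows sum to 1
    within 1e-12.
    """
    if scope not in ("all", "tme"):
        raise ValueError("scope must be 'all' or 'tme'")
    aligned = cell_to_sample.reindex(cell_types.index)
    if aligned.isna().any():
        missing = cell_types.index[aligned.isna()].tolist()
        raise ValueError(f"cells without a sample mapping: {missing[:5]}")
    df = pd.DataFrame({"cell_type": cell_types, "sample_id": aligned})
    if scope == "tme":
        df = df[~df["cell_type"].isin(set(tumor_labels))]
        dropped = set(aligned.unique()) - set(df["sample_id"].unique())
        if dropped:
            warnings.warn(
                f"samples with no in-scope cells dropped: {sorted(dropped)}",
                stacklevel=2,
            )
    counts = pd.crosstab(df["sample_id"], df["cell_type"])
    props = counts.div(counts.sum(axis=1), axis=0)
    props.index.name = "sample_id"
    return props


def compare_groups(
    proportions: pd.DataFrame,
    metadata: pd.DataFrame,
    group_field: str,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Descriptive group comparison of per-sample proportions.

    Groups are the two values of ``metadata[group_field]`` in sorted order
    (g0, g1); the reported difference is ``mean(g1) - mean(g0)`` per cell
    type with a seeded percentile bootstrap CI over samples (resampling
    within each group). ``direction`` is the sign of the difference. A group
    with a single sample yields an undefined CI and ``ci_defined=False``.
    """
    groups = metadata.loc[proportions.index, group_field]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"{group_field!r} must have exactly 2 levels, got {levels}")
    g0, g1 = levels
    if (groups == g0).sum() == 0 or (groups == g1).sum() == 0:
        raise ValueError("both groups must be non-empty")

    # sort samples within groups so output is invariant to input row order
    X0 = proportions.loc[groups[groups == g0].index.sort_values()].to_numpy(dtype=float)
    X1 = proportions.loc[groups[groups == g1].index.sort_values()].to_numpy(dtype=float)
    diff = X1.mean(axis=0) - X0.mean(axis=0)

    ci_defined = len(X0) > 1 and len(X1) > 1
    if ci_defined:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, proportions.shape[1]))
        for b in range(n_boot):
            i0 = rng.integers(0, len(X0), size=len(X0))
            i1 = rng.integers(0, len(X1), size=len(X1))
            boots[b] = X1[i1].mean(axis=0) - X0[i0].mean(axis=0)
        alpha = (1.0 - ci_level) / 2.0
        ci_low = np.quantile(boots, alpha, axis=0)
        ci_high = np.quantile(boots, 1.0 - alpha, axis=0)
    else:
        warnings.warn(
            "a group has a single sample: bootstrap CI undefined", stacklevel=2
        )
        ci_low = np.full(proportions.shape[1], np.nan)
        ci_high = np.full(proportions.shape[1], np.nan)

    return pd.DataFrame(
        {
            "group_low": g0,
            "group_high": g1,
            "mean_low": X0.mean(axis=0),
            "mean_high": X1.mean(axis=0),
            "difference": diff,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "direction": np.sign(diff).astype(int),
            "ci_defined": ci_defined,
        },
        index=pd.Index(proportions.columns, name="cell_type"),
    )
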