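"""Leaf-measurement ingest: whole-leaf LMA, petiole correction, outlier
filtering, and aggregation to tree / population / plot values.

LMA is computed per leaf on a whole-leaf basis (lamina plus petiole; the
rachis of compound leaves is treated as petiole).  Zero petiole dry masses
(balance precision) are corrected with the plot-level fresh:dry petiole
mass ratio.  Leaves that push a tree-branch above a variance threshold
(default 2000 g²·m⁻⁴) are removed one-per-tree as suspected measurement
error.  All plot- and species-level values are means of tree values, never
of pooled leaves; sun and shade branches are never pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_leaf_lma",
    "correct_petiole_mass",
    "filter_outlier_leaves",
    "aggregate_to_trees",
    "population_means",
    "plot_means",
    "DEFAULT_VARIANCE_THRESHOLD",
]

DEFAULT_VARIANCE_THRESHOLD = 2000.0  # g^2 m^-4, tree-level leaf-LMA variance
_BRANCH_KEYS = ["plot_id", "tree_id", "layer"]


def compute_leaf_lma(leaf_table: pd.DataFrame) -> pd.Series:
    """Whole-leaf LMA (g·m⁻²) per record: total dry mass / total fresh area.

    Raises ``ValueError`` naming the offending leaves when a record has
    zero total fresh area.
    """
    area = leaf_table["lamina_fresh_area"] + leaf_table["petiole_fresh_area"]
    bad = area <= 0
    if bad.any():
        ids = leaf_table.loc[bad, "leaf_id"].tolist()
        raise ValueError(f"zero total fresh area for leaves: {ids}")
    mass = leaf_table["lamina_dry_mass"] + leaf_table["petiole_dry_mass"]
    return (mass / area).rename("lma")


def correct_petiole_mass(leaf_table: pd.DataFrame) -> pd.DataFrame:
    """Fill zero petiole dry masses from the plot fresh:dry petiole ratio.

    For each plot, R_plot = (sum petiole fresh mass) / (sum petiole dry
    mass) over that plot's records with both masses positive (ratio of
    sums: robust to tiny masses).  Records with ``petiole_dry_mass == 0``
    and positive fresh mass get ``petiole_fresh_mass / R_plot``.  Plots
    with no valid petiole pair keep their zeros and the affected records
    are flagged in the returned column ``petiole_uncorrectable``.
    """
    out = leaf_table.copy(deep=True)
    out["petiole_corrected"] = False
    out["petiole_uncorrectable"] = False
    for pid, grp in out.groupby("plot_id", sort=False):
        valid = (grp["petiole_dry_mass"] > 0) & (grp["petiole_fresh_mass"] > 0)
        needs = (grp["petiole_dry_mass"] == 0) & (grp["petiole_fresh_mass"] > 0)
        if not needs.any():
            continue
        if not valid.any():
            warnings.warn(
                f"plot {pid}: no valid petiole fresh/dry pair; zero petiole masses left as-is"
            )
            out.loc[grp.index[needs], "petiole_uncorrectable"] = True
            continue
        r_plot = grp.loc[valid, "petiole_fresh_mass"].sum() / grp.loc[valid, "petiole_dry_mass"].sum()
        idx = grp.index[needs]
        out.loc[idx, "petiole_dry_mass"] = out.loc[idx, "petiole_fresh_mass"] / r_plot
        out.loc[idx, "petiole_corrected"] = True
    return out


def filter_outlier_leaves(
    leaf_table: pd.DataFrame, threshold: float = DEFAULT_VARIANCE_THRESHOLD
):
    """Remove at most one leaf per tree-branch whose LMA variance exceeds
    ``threshold``.

    Per (plot, tree, layer) branch with >= 2 leaves: if the sample
    variance of leaf LMA exceeds the threshold, the single leaf whose
    removal minimizes the remaining variance is dropped.  Branches still
    above the threshold after one removal are flagged, not dropped.

    Returns ``(kept, removed, flagged)``: the kept and removed leaf rows
    (with an ``lma`` column) and a DataFrame of branches flagged as still
    above threshold or as too small to assess (< 2 leaves).
    """
    table = leaf_table.copy(deep=True)
    if "lma" not in table.columns:
        table["lma"] = compute_leaf_lma(table)
    drop_idx = []
    flags = []
    for key, grp in table.groupby(_BRANCH_KEYS, sort=False):
        if len(grp) < 2:
            flags.append((*key, "fewer_than_2_leaves", np.nan))
            continue
        var0 = grp["lma"].var(ddof=1)
        if var0 <= threshold:
            continue
        vals = grp["lma"].to_numpy()
        best_i, best_var = None, np.inf
        for i in range(len(vals)):
            rest = np.delete(vals, i)
            v = rest.var(ddof=1) if len(rest) >= 2 else 0.0
            if v < best_var:
                best_i, best_var = i, v
        drop_idx.append(grp.index[best_i])
        if best_var > threshold:
            flags.append((*key, "variance_above_threshold_after_removal", best_var))
    removed = table.loc[drop_idx]
    kept = table.drop(index=drop_idx)
    flagged = pd.DataFrame(flags, columns=[*_BRANCH_KEYS, "flag", "variance"])
    if (flagged["flag"] == "fewer_than_2_leaves").any():
        warnings.warn("branches with fewer than 2 leaves were skipped by the outlier filter")
    return kept, removed, flagged


def aggregate_to_trees(leaf_table: pd.DataFrame) -> pd.DataFrame:
    """One trait record per tree x layer: mean of its leaves' LMA.

    Output columns: plot_id, species, genus, family, tree_id, layer, lma,
    log_lma (natural log of the tree-mean LMA), n_leaves.  Species-, plot-
    and region-level summaries must always be built from these tree values
    (see :func:`population_means`, :func:`plot_means`).
    """
    table = leaf_table.copy(deep=False)
    if "lma" not in table.columns:
        table = table.assign(lma=compute_leaf_lma(table))
    label_cols = [c for c in ("species", "genus", "family") if c in table.columns]
    grouped = table.groupby(["plot_id", *label_cols, "tree_id", "layer"], sort=True, as_index=False)
    traits = grouped.agg(lma=("lma", "mean"), n_leaves=("lma", "size"))
    traits["log_lma"] = np.log(traits["lma"])
    return traits


def population_means(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Species x plot (population) mean LMA from tree values, per layer."""
    grouped = trait_table.groupby(["plot_id", "species", "layer"], sort=True, as_index=False)
    pops = grouped.agg(lma=("lma", "mean"), log_lma=("log_lma", "mean"), n_trees=("lma", "size"))
    return pops


def plot_means(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted plot mean/SD of tree LMA values, per layer."""
    grouped = trait_table.groupby(["plot_id", "layer"], sort=True, as_index=False)
    return grouped.agg(
        lma_mean=("lma", "mean"), lma_sd=("lma", "std"), n_trees=("lma", "size")
    )
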