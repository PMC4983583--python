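"""CSV table contracts: strict headers, units, round-trip helpers.

Three tables travel through the pipeline (all UTF-8 CSV):

* leaf_measurements.csv — one row per leaf; masses in g, areas in m².
* census.csv — one row per (plot, species) with basal area (area units
  are arbitrary but consistent within a plot; only proportions are used).
* plots.csv — plot metadata: elevation (m), lai (m² m⁻²), vegetation_type.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["LEAF_COLUMNS", "CENSUS_COLUMNS", "META_COLUMNS", "read_tables", "write_tables"]

LEAF_COLUMNS = [
    "plot_id",
    "tree_id",
    "species",
    "genus",
    "family",
    "leaf_id",
    "layer",
    "lamina_dry_mass",
    "petiole_dry_mass",
    "petiole_fresh_mass",
    "lamina_fresh_area",
    "petiole_fresh_area",
]
CENSUS_COLUMNS = ["plot_id", "species", "basal_area"]
META_COLUMNS = ["plot_id", "elevation", "lai", "vegetation_type"]

_SCHEMA = {
    "leaf_measurements.csv": {
        "columns": LEAF_COLUMNS,
        "units": {
            "lamina_dry_mass": "g",
            "petiole_dry_mass": "g",
            "petiole_fresh_mass": "g",
            "lamina_fresh_area": "m^2",
            "petiole_fresh_area": "m^2",
            "layer": "{sun, shade}",
        },
    },
    "census.csv": {"columns": CENSUS_COLUMNS, "units": {"basal_area": "consistent area units"}},
    "plots.csv": {
        "columns": META_COLUMNS,
        "units": {"elevation": "m", "lai": "m^2 m^-2"},
    },
}


def _read_csv(path, required, label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{label} table not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{label} table is empty: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{label} table {path} is missing required columns: {missing}")
    if df.empty:
        raise ValueError(f"{label} table has no rows: {path}")
    return df


def read_tables(leaf_path, census_path, meta_path):
    """Read and validate the three pipeline inputs.

    Duplicate (plot, species) census rows are summed with a warning.
    """
    leaf = _read_csv(leaf_path, LEAF_COLUMNS, "leaf")
    census = _read_csv(census_path, CENSUS_COLUMNS, "census")
    meta = _read_csv(meta_path, ["plot_id"], "plot metadata")
    dup = census.duplicated(subset=["plot_id", "species"])
    if dup.any():
        warnings.warn(f"census: {int(dup.sum())} duplicate (plot, species) rows were summed")
        census = census.groupby(["plot_id", "species"], as_index=False)["basal_area"].sum()
    return leaf, census, meta


def write_tables(out_dir, leaf, census, meta) -> dict:
    """Write the three tables plus a sidecar schema file; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "leaf": out / "leaf_measurements.csv",
        "census": out / "census.csv",
        "plots": out / "plots.csv",
    }
    leaf.to_csv(paths["leaf"], index=False)
    census.to_csv(paths["census"], index=False)
    meta.to_csv(paths["plots"], index=False)
    with open(out / "schema.yaml", "w") as fh:
        yaml.safe_dump(_SCHEMA, fh, sort_keys=False)
    return paths
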