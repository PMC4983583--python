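"""Sorensen beta diversity, environmental distances, and Mantel tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = ["sorensen_matrix", "env_distance", "mantel_test"]


def sorensen_matrix(census: pd.DataFrame) -> DistanceMatrix:
    """Pairwise incidence-based Sorensen dissimilarity between plots.

    beta_sor(j, k) = (b + c) / (2a + b + c) with a = shared species and
    b, c = species unique to each plot; presence means basal area > 0.
    """
    pos = census[census["basal_area"] > 0]
    presence = pd.crosstab(pos["plot_id"], pos["species"]) > 0
    if presence.shape[0] < 2:
        raise ValueError("need >= 2 plots")
    empty = presence.sum(axis=1) == 0
    if empty.any():
        raise ValueError(f"plots with zero species: {presence.index[empty].tolist()}")
    # scipy's 'dice' dissimilarity is exactly (b + c) / (2a + b + c).
    dist = squareform(pdist(presence.to_numpy(), metric="dice"))
    return DistanceMatrix(dist, ids=presence.index.tolist())


def env_distance(meta: pd.DataFrame, variable: str) -> DistanceMatrix:
    """Absolute pairwise differences of a plot covariate."""
    if variable not in meta.columns:
        raise KeyError(f"variable {variable!r} not in plot metadata")
    v = meta.set_index("plot_id")[variable]
    missing = v[v.isna()].index.tolist()
    if missing:
        raise ValueError(f"missing {variable} for plots: {missing}")
    arr = v.to_numpy(dtype=float)
    return DistanceMatrix(np.abs(arr[:, None] - arr[None, :]), ids=v.index.tolist())


def mantel_test(
    d1: DistanceMatrix, d2: DistanceMatrix, nperm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """One-sided Mantel test of association between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the
    p-value is ``(1 + #{r_perm >= r_obs}) / (nperm + 1)`` under joint
    row/column permutations of ``d2``.
    """
    if list(d1.ids) != list(d2.ids):
        d2 = d2.filter(d1.ids)
    if nperm < 99:
        raise ValueError("nperm must be >= 99")
    a = d1.data
    b = d2.data
    n = a.shape[0]
    il = np.tril_indices(n, k=-1)
    x = a[il]
    if np.ptp(x) == 0 or np.ptp(b[il]) == 0:
        raise ValueError("constant lower triangle; Mantel r undefined")
    x = (x - x.mean()) / x.std()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def corr(mat):
        y = mat[il]
        sd = y.std()
        if sd == 0:
            return 0.0
        return float((x * (y - y.mean()) / sd).mean())

    r_obs = corr(b)
    count = 0
    for _ in range(nperm):
        order = rng.permutation(n)
        if corr(b[np.ix_(order, order)]) >= r_obs:
            count += 1
    p = (1 + count) / (nperm + 1)
    return r_obs, p
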