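"""Community-weighted means/variances and gradient regressions.

CWM_k = (sum_i mu_i f_i) / (sum_i f_i) over the sampled species of plot k,
where mu_i is the species mean trait (mean of tree-level LMA, raw scale)
and f_i its relative abundance (proportion of plot basal area).  Dividing
by the summed sampled abundance is the normalization that corrects for
plots whose sampled species cover different basal-area fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import population_means, plot_means

__all__ = ["CWMResult", "community_weighted_mean", "cwm_table", "gradient_regression", "RegressionResult"]


@dataclass
class CWMResult:
    plot_id: str
    layer: str
    cwm: float       # g m^-2
    cwv: float       # g^2 m^-4, abundance-weighted variance about the CWM
    coverage: float  # summed sampled relative abundance, in (0, 1]
    n_species: int


def community_weighted_mean(
    species_means, abundances, plot_id: str = "", layer: str = ""
) -> CWMResult:
    """CWM/CWV from aligned species means and abundance weights.

    ``species_means`` and ``abundances`` are mappings or Series keyed by
    species; only species present in both enter the calculation.
    ``coverage`` reports the summed abundance of those species on the
    scale given (pass basal-area *fractions* to make it interpretable).
    """
    mu = pd.Series(species_means, dtype=float)
    f = pd.Series(abundances, dtype=float)
    common = mu.index.intersection(f.index)
    mu, f = mu.loc[common], f.loc[common]
    if (f < 0).any():
        raise ValueError("abundances must be >= 0")
    total = f.sum()
    if total <= 0:
        raise ValueError(f"plot {plot_id or '?'}: summed abundance of sampled species is zero")
    w = f / total
    cwm = float((mu * w).sum())
    cwv = float((w * (mu - cwm) ** 2).sum())
    return CWMResult(plot_id, layer, cwm, cwv, float(total), int(len(common)))


def cwm_table(trait_table: pd.DataFrame, census: pd.DataFrame) -> pd.DataFrame:
    """Per plot x layer CWM/CWV plus the unweighted tree-level mean/SD.

    Abundance weights are each sampled species' share of *total* plot
    basal area (all census species), so ``coverage`` is the basal-area
    fraction the sampled dominants represent.
    """
    pops = population_means(trait_table)
    plot_total = census.groupby("plot_id")["basal_area"].sum()
    rows = []
    for (pid, layer), grp in pops.groupby(["plot_id", "layer"], sort=True):
        ba = census.loc[census["plot_id"] == pid].set_index("species")["basal_area"]
        frac = ba / plot_total[pid]
        res = community_weighted_mean(
            grp.set_index("species")["lma"], frac, plot_id=pid, layer=layer
        )
        rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    unw = plot_means(trait_table).rename(
        columns={"lma_mean": "unweighted_mean", "lma_sd": "unweighted_sd"}
    )
    return out.merge(unw, on=["plot_id", "layer"], how="left")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    excluded: tuple


def gradient_regression(values, env, exclude=None) -> RegressionResult:
    """OLS of a per-plot statistic on a per-plot covariate.

    ``values`` and ``env`` are Series indexed by plot; ``exclude`` drops
    the named plots before fitting (at least 3 plots must remain).
    """
    y = pd.Series(values, dtype=float)
    x = pd.Series(env, dtype=float)
    common = y.index.intersection(x.index)
    excluded = tuple(exclude) if exclude else ()
    common = common.difference(pd.Index(excluded))
    y, x = y.loc[common], x.loc[common]
    if len(common) < 3:
        raise ValueError("need at least 3 plots after exclusion")
    if np.isclose(x.var(ddof=0), 0.0):
        raise ValueError("covariate has zero variance")
    fit = stats.linregress(x.to_numpy(), y.to_numpy())
    rvalue = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue)  # constant y
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=rvalue**2,
        p_value=float(fit.pvalue),
        n=int(len(common)),
        excluded=excluded,
    )
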