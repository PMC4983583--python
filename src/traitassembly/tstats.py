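"""T-statistics: intraspecific/interspecific trait-variance ratios with
permutation null models and standardized effect sizes.

For trait values on the log scale, with levels of inclusiveness
i (individual tree), p (population = species x plot), c (community =
plot), r (region = all plots of one transect):

* ``T_ip.ic = sigma2_IP / sigma2_IC`` — within-population variance over
  total within-community variance.  Computed as a sum-of-squares fraction
  (the common ``n_c - 1`` denominator cancels), so it lies in [0, 1].
  Low values relative to the null indicate internal filtering (niche
  packing): conspecific individuals are more similar than a random
  partition of the community would make them.
* ``T_ic.ir = sigma2_IC / sigma2_IR`` — community variance over regional
  variance at the individual level.  Low values indicate environmental
  filtering acting on individuals.
* ``T_pc.pr = sigma2_PC / sigma2_PR`` — the same contrast using
  population means only (no intraspecific variation).

Each statistic is compared to a permutation null that destroys exactly
the structure it measures:

* ``T_ip.ic`` — shuffle individual values among individuals *within* each
  community (destroys population structure, preserves the community pool);
* ``T_ic.ir`` — rebuild each community by drawing ``n_c`` individuals
  without replacement from the regional pool of individuals;
* ``T_pc.pr`` — shuffle population means across all populations of the
  region, preserving each community's population count.

Standardized effect size: ``SES = (obs - mean(null)) / sd(null)``.  The
null confidence box is the (alpha/2, 1 - alpha/2) quantile pair of the
SES-transformed null values; an observed SES outside the box is
significant at level alpha.  The same variance estimator is used for
observed and null values, so the SES is invariant to the estimator's
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "TStatResult",
    "TransectAggregate",
    "STATISTICS",
    "variance_components",
    "t_ip_ic",
    "t_ic_ir",
    "t_pc_pr",
    "observed_statistic",
    "null_distribution",
    "ses",
    "aggregate_ses",
    "compute_tstats",
]

STATISTICS = ("t_ip_ic", "t_ic_ir", "t_pc_pr")
_SCHEMES = {
    "t_ip_ic": "shuffle_within_community",
    "t_ic_ir": "resample_from_regional_pool",
    "t_pc_pr": "shuffle_population_means",
}


@dataclass
class VarianceComponents:
    """Sums of squares and pooled-mean variances for one community."""

    plot_id: str
    ss_within_pop: float            # sum over individuals of (x_i - m_pop(i))^2
    ss_community: float             # sum of (x_i - xbar_c)^2
    n_c: int
    ss_region: float                # sum over region of (x_i - xbar_r)^2
    n_r: int
    var_pop_means_community: float  # ddof=1 variance of population means in c
    var_pop_means_region: float     # ddof=1 variance of all population means in r


@dataclass
class TStatResult:
    plot_id: str
    statistic: str
    observed: float
    null_values: np.ndarray
    ses: float
    null_ci: tuple[float, float]   # on the SES scale
    significant: bool
    scheme: str
    nperm: int
    seed: int


@dataclass
class TransectAggregate:
    """Transect-level mean/SD of per-plot SES with a pooled null box."""

    statistic: str
    mean_ses: float
    sd_ses: float
    pooled_null_ci: tuple[float, float]
    significant: bool
    n_plots: int


# ---------------------------------------------------------------------------
# internal data marshalling


class _Region:
    """Per-plot value arrays and population codes for one layer."""

    def __init__(self, traits: pd.DataFrame, value_col: str = "log_lma"):
        if traits["layer"].nunique() > 1:
            raise ValueError(
                "trait table mixes leaf layers; analyze each layer separately"
            )
        t = traits.sort_values(["plot_id", "species"], kind="mergesort")
        self.plot_ids = sorted(t["plot_id"].unique().tolist())
        self.values = {}
        self.pop_codes = {}
        self.pop_means = {}
        for pid, grp in t.groupby("plot_id", sort=True):
            x = grp[value_col].to_numpy(dtype=float)
            codes = pd.factorize(grp["species"].to_numpy(), sort=True)[0]
            self.values[pid] = x
            self.pop_codes[pid] = codes
            self.pop_means[pid] = np.bincount(codes, weights=x) / np.bincount(codes)
        self.region_values = np.concatenate([self.values[p] for p in self.plot_ids])
        self.region_pop_means = np.concatenate([self.pop_means[p] for p in self.plot_ids])


def _ss_within(x: np.ndarray, codes: np.ndarray) -> float:
    counts = np.bincount(codes)
    sums = np.bincount(codes, weights=x)
    return float((x**2).sum() - (sums**2 / counts).sum())


def variance_components(traits: pd.DataFrame, plot: str, value_col: str = "log_lma") -> VarianceComponents:
    """All variance building blocks for one community within its region.

    ``traits`` holds one trait record per individual tree for a single
    leaf layer; the region is every plot present in the table.
    Populations with a single individual contribute zero to the
    within-population sum of squares.
    """
    region = _Region(traits, value_col)
    return _components_from_region(region, plot)


def _components_from_region(region: _Region, plot: str) -> VarianceComponents:
    if plot not in region.values:
        raise KeyError(f"plot {plot!r} not present in trait table")
    x = region.values[plot]
    if len(x) < 2:
        raise ValueError(f"plot {plot}: need >= 2 individuals")
    xr = region.region_values
    if len(xr) < 2:
        raise ValueError("region: need >= 2 individuals")
    pm = region.pop_means[plot]
    pm_r = region.region_pop_means
    return VarianceComponents(
        plot_id=plot,
        ss_within_pop=_ss_within(x, region.pop_codes[plot]),
        ss_community=float(((x - x.mean()) ** 2).sum()),
        n_c=len(x),
        ss_region=float(((xr - xr.mean()) ** 2).sum()),
        n_r=len(xr),
        var_pop_means_community=float(np.var(pm, ddof=1)) if len(pm) > 1 else float("nan"),
        var_pop_means_region=float(np.var(pm_r, ddof=1)) if len(pm_r) > 1 else float("nan"),
    )


# ---------------------------------------------------------------------------
# the three ratios


def t_ip_ic(vc: VarianceComponents) -> float:
    """Within-population / within-community SS fraction, in [0, 1]."""
    if vc.ss_community <= 0:
        raise ValueError(f"plot {vc.plot_id}: community variance is zero; ratio undefined")
    return vc.ss_within_pop / vc.ss_community


def t_ic_ir(vc: VarianceComponents) -> float:
    """Community variance over regional variance (individual level)."""
    if vc.ss_region <= 0:
        raise ValueError("regional variance is zero; ratio undefined")
    return (vc.ss_community / (vc.n_c - 1)) / (vc.ss_region / (vc.n_r - 1))


def t_pc_pr(vc: VarianceComponents) -> float:
    """Community variance over regional variance of population means."""
    if not np.isfinite(vc.var_pop_means_region) or vc.var_pop_means_region <= 0:
        raise ValueError("regional population-mean variance is degenerate")
    if not np.isfinite(vc.var_pop_means_community):
        raise ValueError(f"plot {vc.plot_id}: fewer than 2 populations")
    return vc.var_pop_means_community / vc.var_pop_means_region


_RATIOS = {"t_ip_ic": t_ip_ic, "t_ic_ir": t_ic_ir, "t_pc_pr": t_pc_pr}


def observed_statistic(traits: pd.DataFrame, statistic: str, value_col: str = "log_lma") -> dict:
    """Observed value of one statistic for every community."""
    region = _Region(traits, value_col)
    fn = _RATIOS[statistic]
    return {p: fn(_components_from_region(region, p)) for p in region.plot_ids}


# ---------------------------------------------------------------------------
# permutation engines (vectorized: one matrix op per community)


def _null_t_ip_ic(region: _Region, nperm: int, rng) -> dict:
    out = {}
    for pid in region.plot_ids:
        x = region.values[pid]
        codes = region.pop_codes[pid]
        counts = np.bincount(codes)
        ss_comm = ((x - x.mean()) ** 2).sum()
        sumsq = (x**2).sum()
        perms = rng.permuted(np.tile(x, (nperm, 1)), axis=1)
        indicator = np.zeros((len(x), len(counts)))
        indicator[np.arange(len(x)), codes] = 1.0
        group_sums = perms @ indicator
        ss_within = sumsq - (group_sums**2 / counts).sum(axis=1)
        out[pid] = ss_within / ss_comm
    return out


def _null_t_ic_ir(region: _Region, nperm: int, rng) -> dict:
    xr = region.region_values
    var_r = np.var(xr, ddof=1)
    out = {}
    for pid in region.plot_ids:
        n_c = len(region.values[pid])
        if n_c > len(xr):
            raise ValueError(f"plot {pid}: community larger than regional pool")
        perms = rng.permuted(np.tile(xr, (nperm, 1)), axis=1)[:, :n_c]
        out[pid] = np.var(perms, axis=1, ddof=1) / var_r
    return out


def _null_t_pc_pr(region: _Region, nperm: int, rng) -> dict:
    m = region.region_pop_means
    var_r = np.var(m, ddof=1)
    perms = rng.permuted(np.tile(m, (nperm, 1)), axis=1)
    out = {}
    start = 0
    for pid in region.plot_ids:
        k = len(region.pop_means[pid])
        out[pid] = np.var(perms[:, start : start + k], axis=1, ddof=1) / var_r
        start += k
    return out


_NULL_ENGINES = {
    "t_ip_ic": _null_t_ip_ic,
    "t_ic_ir": _null_t_ic_ir,
    "t_pc_pr": _null_t_pc_pr,
}


def null_distribution(
    traits: pd.DataFrame,
    statistic: str,
    nperm: int = 999,
    seed: int = 0,
    value_col: str = "log_lma",
) -> dict:
    """Null values of ``statistic`` for every community.

    Returns a dict mapping plot id to an array of ``nperm`` null ratios.
    Permutation index j is drawn jointly across communities where the
    scheme is regional (``t_pc_pr``), so transect-level aggregation can
    pair null values across plots.
    """
    if statistic not in STATISTICS:
        raise KeyError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    if nperm < 99:
        raise ValueError("nperm must be >= 99")
    region = _Region(traits, value_col)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return _NULL_ENGINES[statistic](region, nperm, rng)


# ---------------------------------------------------------------------------
# standardized effect sizes


def ses(
    observed: float,
    null_values: np.ndarray,
    alpha: float = 0.05,
    plot_id: str = "",
    statistic: str = "",
    seed: int = 0,
) -> TStatResult:
    """Standardized effect size of an observed ratio against its null.

    ``SES = (observed - mean(null)) / sd(null)``; the null confidence
    interval is the central ``1 - alpha`` quantile box of the
    SES-transformed null values, and ``significant`` is True when the
    observed SES falls outside it.
    """
    null_values = np.asarray(null_values, dtype=float)
    mu = null_values.mean()
    sd = null_values.std(ddof=1)
    if sd <= 0:
        raise ValueError("degenerate null distribution (zero spread)")
    z_obs = (observed - mu) / sd
    z_null = (null_values - mu) / sd
    lo, hi = np.quantile(z_null, [alpha / 2, 1 - alpha / 2])
    return TStatResult(
        plot_id=plot_id,
        statistic=statistic,
        observed=float(observed),
        null_values=null_values,
        ses=float(z_obs),
        null_ci=(float(lo), float(hi)),
        significant=bool(z_obs < lo or z_obs > hi),
        scheme=_SCHEMES.get(statistic, ""),
        nperm=len(null_values),
        seed=seed,
    )


def aggregate_ses(results: list, alpha: float = 0.05) -> TransectAggregate:
    """Transect-level mean/SD of per-plot SES with a pooled null box.

    The pooled null is the distribution of the *mean* SES: for each
    permutation index, the SES-transform of every plot's null value is
    averaged across plots, and the box is the central ``1 - alpha``
    quantile pair of those means.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 plots to aggregate")
    stat = results[0].statistic
    if any(r.statistic != stat for r in results):
        raise ValueError("results mix statistics")
    ses_obs = np.array([r.ses for r in results])
    z_null = []
    for r in results:
        mu = r.null_values.mean()
        sd = r.null_values.std(ddof=1)
        z_null.append((r.null_values - mu) / sd)
    mean_null = np.mean(np.vstack(z_null), axis=0)
    lo, hi = np.quantile(mean_null, [alpha / 2, 1 - alpha / 2])
    mean_ses = float(ses_obs.mean())
    return TransectAggregate(
        statistic=stat,
        mean_ses=mean_ses,
        sd_ses=float(ses_obs.std(ddof=1)),
        pooled_null_ci=(float(lo), float(hi)),
        significant=bool(mean_ses < lo or mean_ses > hi),
        n_plots=len(results),
    )


def compute_tstats(
    traits: pd.DataFrame,
    statistics=STATISTICS,
    nperm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    value_col: str = "log_lma",
):
    """Observed ratios, per-plot SES and transect aggregates for a layer.

    Returns ``(results, aggregates)`` where ``results`` is a list of
    :class:`TStatResult` (one per plot x statistic) and ``aggregates``
    maps statistic name to :class:`TransectAggregate`.  Child seeds are
    spawned per statistic from the master seed.
    """
    children = np.random.SeedSequence(seed).spawn(len(statistics))
    results = []
    aggregates = {}
    for stat, child in zip(statistics, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        obs = observed_statistic(traits, stat, value_col)
        nulls = null_distribution(traits, stat, nperm=nperm, seed=child_seed, value_col=value_col)
        stat_results = [
            ses(obs[p], nulls[p], alpha=alpha, plot_id=p, statistic=stat, seed=child_seed)
            for p in sorted(obs)
        ]
        results.extend(stat_results)
        if len(stat_results) >= 2:
            aggregates[stat] = aggregate_ses(stat_results, alpha=alpha)
    return results, aggregates


def results_frame(results: list) -> pd.DataFrame:
    """Flatten TStatResults to the per-plot output table (no null arrays)."""
    rows = []
    for r in results:
        rows.append(
            {
                "plot_id": r.plot_id,
                "statistic": r.statistic,
                "observed": r.observed,
                "ses": r.ses,
                "ci_low": r.null_ci[0],
                "ci_high": r.null_ci[1],
                "significant": r.significant,
                "scheme": r.scheme,
                "nperm": r.nperm,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)
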