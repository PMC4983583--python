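"""Nested variance-component decomposition and the turnover/intraspecific
decomposition of community-weighted-mean variance.

``nested_variance_components`` fits an intercept-only random-effects model
with nested grouping (default plot / family / genus / species / tree with
leaf as residual) by REML, on log-scale trait values, and reports each
level's variance and proportion of the total.  ``moments_oracle`` solves
the same decomposition on perfectly balanced designs from the expected
mean squares of the nested ANOVA — an independent closed form used to
validate the REML path.

``leps_decomposition`` splits the across-plot variance of the specific CWM
(plot-specific species means) into a species-turnover part (CWM built from
region-wide fixed species means), an intraspecific part (variance of the
per-plot difference specific - fixed), and a covariance remainder that
makes the identity exact:

    var(specific) = var(fixed) + var(specific - fixed) + cov_term .
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import community_weighted_mean

__all__ = [
    "NestedComponents",
    "TurnoverDecomposition",
    "nested_variance_components",
    "moments_oracle",
    "leps_decomposition",
    "DEFAULT_HIERARCHY",
]

DEFAULT_HIERARCHY = ("plot_id", "family", "genus", "species", "tree_id")


@dataclass
class NestedComponents:
    levels: tuple          # nesting order, residual last
    variances: np.ndarray  # squared log-trait units, >= 0
    proportions: np.ndarray
    converged: bool = True

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level": self.levels, "variance": self.variances, "proportion": self.proportions}
        )


@dataclass
class TurnoverDecomposition:
    ss_specific: float
    ss_fixed: float
    ss_intra: float
    cov: float
    turnover_share: float
    intraspecific_share: float
    cov_share: float


def _check_nested(data: pd.DataFrame, hierarchy) -> None:
    """Labels below the top level must have a unique parent.

    The top level (site) is allowed to cross the second (a family occurs
    at many sites); below that, e.g. one genus under two families is a
    taxonomic inconsistency and is reported with the offending labels.
    """
    offenders = []
    for parent, child in zip(hierarchy[1:-1], hierarchy[2:]):
        counts = data.groupby(child, sort=False)[parent].nunique()
        bad = counts[counts > 1]
        offenders.extend(f"{child}={label} under {counts[label]} {parent} values" for label in bad.index)
    if offenders:
        raise ValueError("non-nested labels: " + "; ".join(offenders))


def _path_columns(data: pd.DataFrame, hierarchy) -> pd.DataFrame:
    """Concatenate ancestor labels so every level is nested by construction."""
    out = data.copy(deep=False)
    path = out[hierarchy[0]].astype(str)
    out["_path0"] = path
    for i, level in enumerate(hierarchy[1:], start=1):
        path = path + "/" + out[level].astype(str)
        out[f"_path{i}"] = path
    return out


def nested_variance_components(
    data: pd.DataFrame,
    hierarchy=DEFAULT_HIERARCHY,
    value_col: str = "log_lma",
    residual_label: str = "leaf",
) -> NestedComponents:
    """REML variance components of the nested random-intercept model.

    ``hierarchy`` orders the grouping columns from outermost to
    innermost; observations within the innermost group form the residual
    level.  Negative estimates are truncated at zero by the REML
    parameterization; proportions are renormalized over the total.
    Requires >= 2 units at every level.
    """
    import statsmodels.api as sm

    hierarchy = tuple(hierarchy)
    _check_nested(data, hierarchy)
    for col in hierarchy:
        if data[col].nunique() < 2:
            raise ValueError(f"level {col!r} has fewer than 2 units")
    d = _path_columns(data, hierarchy)
    d = d.rename(columns={value_col: "_y"})

    vc_formula = {
        level: f"0 + C(_path{i})" for i, level in enumerate(hierarchy[1:], start=1)
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "_y ~ 1",
            groups="_path0",
            re_formula="1",
            vc_formula=vc_formula or None,
            data=d,
        )
        # Two optimizer chains, each polished by a tight bfgs step; keep the
        # best REML likelihood.  A single lbfgs run can stall on a spurious
        # boundary point for small designs, and unpolished fits only reach
        # ~1e-4 relative accuracy.
        def restricted_ll(f):
            # f.llf can be spuriously +inf at degenerate boundary points;
            # re-evaluate and treat non-finite as unusable
            try:
                ll = float(model.loglike(f.params_object))
            except Exception:
                return -np.inf
            return ll if np.isfinite(ll) else -np.inf

        candidates = []
        for method in ("lbfgs", "bfgs"):
            try:
                fit = model.fit(reml=True, method=method, maxiter=500)
            except Exception:
                continue
            try:
                refined = model.fit(
                    start_params=fit.params_object,
                    reml=True,
                    method="bfgs",
                    maxiter=500,
                    gtol=1e-10,
                )
                if restricted_ll(refined) >= restricted_ll(fit) - 1e-10:
                    refined.converged = refined.converged or fit.converged
                    fit = refined
            except Exception:
                pass
            candidates.append(fit)
        if not candidates:
            raise RuntimeError("REML optimization failed for every optimizer")
        fit = max(candidates, key=restricted_ll)
        if not np.isfinite(restricted_ll(fit)):
            raise RuntimeError("REML optimization found no finite-likelihood solution")

    variances = [float(fit.cov_re.iloc[0, 0])]
    vc_names = list(model.exog_vc.names) if vc_formula else []
    vcomp = dict(zip(vc_names, np.atleast_1d(fit.vcomp)))
    for level in hierarchy[1:]:
        variances.append(float(vcomp[level]))
    variances.append(float(fit.scale))
    variances = np.clip(np.asarray(variances), 0.0, None)
    total = variances.sum()
    return NestedComponents(
        levels=(*hierarchy, residual_label),
        variances=variances,
        proportions=variances / total,
        converged=bool(fit.converged),
    )


def moments_oracle(
    data: pd.DataFrame,
    hierarchy=DEFAULT_HIERARCHY,
    value_col: str = "log_lma",
    residual_label: str = "leaf",
    truncate: bool = True,
) -> NestedComponents:
    """Closed-form (expected-mean-squares) components for balanced designs.

    For a balanced fully nested layout, ``E[MS_l] = sigma_e^2 +
    sum_{j >= l} N_j sigma_j^2`` with ``N_j`` the observations per
    level-j unit, which solves triangularly from the innermost level
    outward.  Raises on unbalanced input.
    """
    hierarchy = tuple(hierarchy)
    d = _path_columns(data, hierarchy)
    y = d[value_col].to_numpy(dtype=float)
    n_total = len(d)

    path_cols = [f"_path{i}" for i in range(len(hierarchy))]
    counts_per_level = []
    obs_per_unit = []
    for col in path_cols:
        sizes = d.groupby(col, sort=False).size()
        if sizes.nunique() != 1:
            raise ValueError(f"design unbalanced at level {col}: unequal group sizes")
        counts_per_level.append(len(sizes))
        obs_per_unit.append(int(sizes.iloc[0]))
    # Equal child counts per parent are implied by equal sizes at every level.

    grand = y.mean()
    ss = []
    dfs = []
    parent_means = np.full(n_total, grand)
    prev_groups = 1
    for col, n_units, n_obs in zip(path_cols, counts_per_level, obs_per_unit):
        means = d.groupby(col, sort=False)[value_col].transform("mean").to_numpy()
        ss.append(float(((means - parent_means) ** 2).sum()))
        dfs.append(n_units - prev_groups)
        parent_means = means
        prev_groups = n_units
    ss_resid = float(((y - parent_means) ** 2).sum())
    df_resid = n_total - prev_groups

    ms = [s / df for s, df in zip(ss, dfs)]
    sigma2 = np.zeros(len(hierarchy) + 1)
    sigma2[-1] = ss_resid / df_resid if df_resid > 0 else 0.0
    for l in range(len(hierarchy) - 1, -1, -1):
        inner = sum(obs_per_unit[j] * sigma2[j] for j in range(l + 1, len(hierarchy)))
        sigma2[l] = (ms[l] - sigma2[-1] - inner) / obs_per_unit[l]
    if truncate:
        sigma2 = np.clip(sigma2, 0.0, None)
    total = sigma2.sum()
    return NestedComponents(
        levels=(*hierarchy, residual_label),
        variances=sigma2,
        proportions=sigma2 / total if total > 0 else sigma2,
    )


def leps_decomposition(
    trait_table: pd.DataFrame,
    census: pd.DataFrame,
    layer: str | None = None,
) -> TurnoverDecomposition:
    """Turnover / intraspecific / covariance split of CWM variance.

    Per plot, the *specific* CWM uses plot-specific species means and the
    *fixed* CWM uses region-wide species means with the same normalized
    basal-area weights.  The three SS terms are ddof=1 variances across
    plots; the covariance term is the residual that closes the identity
    exactly.  Species present in the census but absent from the regional
    trait table are excluded from the weights with a warning.
    """
    t = trait_table
    if layer is not None:
        t = t[t["layer"] == layer]
    if t["layer"].nunique() > 1:
        raise ValueError("trait table mixes layers; pass layer=")
    spec_means = t.groupby(["plot_id", "species"])["lma"].mean()
    fixed_means = t.groupby("species")["lma"].mean()

    missing = set(census["species"]) - set(fixed_means.index)
    if missing:
        warnings.warn(
            f"{len(missing)} census species absent from the trait table were excluded from weights"
        )

    plots = sorted(t["plot_id"].unique())
    if len(plots) < 2:
        raise ValueError("need >= 2 plots to decompose across-plot CWM variance")
    cwm_specific, cwm_fixed = [], []
    for pid in plots:
        sampled = spec_means.loc[pid]
        ba = census.loc[census["plot_id"] == pid].set_index("species")["basal_area"]
        common = sampled.index.intersection(ba.index)
        w = ba.loc[common]
        cwm_specific.append(community_weighted_mean(sampled.loc[common], w, plot_id=pid).cwm)
        cwm_fixed.append(community_weighted_mean(fixed_means.loc[common], w, plot_id=pid).cwm)
    cwm_specific = np.asarray(cwm_specific)
    cwm_fixed = np.asarray(cwm_fixed)

    ss_specific = float(np.var(cwm_specific, ddof=1))
    ss_fixed = float(np.var(cwm_fixed, ddof=1))
    ss_intra = float(np.var(cwm_specific - cwm_fixed, ddof=1))
    cov = ss_specific - ss_fixed - ss_intra
    return TurnoverDecomposition(
        ss_specific=ss_specific,
        ss_fixed=ss_fixed,
        ss_intra=ss_intra,
        cov=cov,
        turnover_share=ss_fixed / ss_specific,
        intraspecific_share=ss_intra / ss_specific,
        cov_share=cov / ss_specific,
    )
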