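"""Synthetic community generator with known ground truth.

Emulates the field design the pipeline is built for: a regional species
pool distributed along an environmental gradient with strong species
turnover, basal-area-skewed abundances, sampling of dominant species up to
a basal-area coverage target with 3-5 trees per species and 3-5 leaves per
branch, and hierarchical trait variance on the natural-log scale of LMA
(site / species / population / tree / leaf).

The generative model, per plot p and species s:

    mu_s        = m + beta_env * (opt_s - env_center) + N(0, sigma_species^2)
    theta_p     = m + beta_env * (env_p - env_center)          (plot optimum)
    pop_{s,p}   = theta_p + gamma_ext,p * (mu_s - theta_p)
                  + N(0, (sigma_pop * gamma_int,p)^2)
    tree value  = site_p + pop_{s,p} + N(0, (sigma_tree * gamma_int,p)^2)
    leaf value  = tree value + N(0, sigma_leaf^2)

with site_p ~ N(0, sigma_site^2).  ``gamma_external`` < 1 shrinks admitted
species means toward the plot optimum (environmental filtering: reduces
community variance relative to the region); ``gamma_internal`` < 1 shrinks
within-population spread (internal filtering: reduces the within-population
share of community variance).  Membership weight of species s in plot p is

    w_{s,p} ∝ exp(-(env_p - opt_s)^2 / (2 niche_width^2))
              * LN(0, abundance_shape)_s * LN(0, abundance_plot_sd)_{s,p}

used as basal area.  The census lists every pool species whose relative
weight exceeds ``min_rel_weight``; the leaf table contains only the sampled
dominants that jointly reach ``basal_area_target`` of plot basal area.

Leaf records carry a back-transformed mass/area split consistent with the
target whole-leaf LMA: the petiole holds a fixed 5% of fresh area and 8% of
dry mass, with a fresh:dry petiole mass ratio of 3.0 (recorded in the
ground truth so the petiole correction is testable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig

__all__ = ["GroundTruth", "simulate_region", "inject_artifacts", "PETIOLE_FRESH_DRY_RATIO"]

# Fixed morphology constants of the mass/area split (see module docstring).
PETIOLE_AREA_FRACTION = 0.05
PETIOLE_MASS_FRACTION = 0.08
PETIOLE_FRESH_DRY_RATIO = 3.0
MEAN_LOG_LEAF_AREA = np.log(0.005)  # m^2; ~50 cm^2 typical tropical leaf
SD_LOG_LEAF_AREA = 0.3


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    config: ScenarioConfig
    species: pd.DataFrame          # species, genus, family, opt, mu (true species mean)
    plots: pd.DataFrame            # plot_id, env, site_effect, plot_optimum, gamma_internal, gamma_external
    populations: pd.DataFrame      # plot_id, species, pop_mean, basal_area, sampled
    variance_components: dict      # configured sigmas (log scale)
    petiole_fresh_dry_ratio: float = PETIOLE_FRESH_DRY_RATIO

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "species": self.species.to_dict(orient="list"),
            "plots": self.plots.to_dict(orient="list"),
            "populations": self.populations.to_dict(orient="list"),
            "variance_components": self.variance_components,
            "petiole_fresh_dry_ratio": self.petiole_fresh_dry_ratio,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            config=ScenarioConfig.from_dict(payload["config"]),
            species=pd.DataFrame(payload["species"]),
            plots=pd.DataFrame(payload["plots"]),
            populations=pd.DataFrame(payload["populations"]),
            variance_components=payload["variance_components"],
            petiole_fresh_dry_ratio=payload["petiole_fresh_dry_ratio"],
        )


def _species_pool(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    env = cfg.env_array()
    center = env.mean()
    span = env.max() - env.min()
    # Niche optima cover the gradient with a margin of one niche width so
    # edge plots are not systematically species-poor.
    opt = rng.uniform(env.min() - cfg.niche_width, env.max() + cfg.niche_width, cfg.pool_size)
    mu = (
        cfg.trait_grand_mean
        + cfg.beta_env * (opt - center)
        + rng.normal(0.0, cfg.sigma_species, cfg.pool_size)
    )
    idx = np.arange(cfg.pool_size)
    return pd.DataFrame(
        {
            "species": [f"sp{i:04d}" for i in idx],
            "genus": [f"gen{i // 3:03d}" for i in idx],
            "family": [f"fam{i // 6:03d}" for i in idx],
            "opt": opt,
            "mu": mu,
        }
    )


def _leaf_geometry(log_lma: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Invert whole-leaf LMA into lamina/petiole masses and areas."""
    lma = np.exp(log_lma)
    total_area = rng.lognormal(MEAN_LOG_LEAF_AREA, SD_LOG_LEAF_AREA, lma.size)
    total_dry = lma * total_area
    pet_dry = PETIOLE_MASS_FRACTION * total_dry
    return pd.DataFrame(
        {
            "lamina_dry_mass": total_dry - pet_dry,
            "petiole_dry_mass": pet_dry,
            "petiole_fresh_mass": PETIOLE_FRESH_DRY_RATIO * pet_dry,
            "lamina_fresh_area": (1 - PETIOLE_AREA_FRACTION) * total_area,
            "petiole_fresh_area": PETIOLE_AREA_FRACTION * total_area,
        }
    )


def simulate_region(cfg: ScenarioConfig):
    """Generate (leaf_table, census_table, plot_meta_table, ground_truth).

    All randomness flows from ``cfg.seed`` through a single seeded
    generator, so a fixed config yields byte-identical tables.

    Raises
    ------
    RuntimeError
        If a plot cannot reach ``basal_area_target`` with the species
        present in its census (names the plot).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    env = cfg.env_array()
    center = env.mean()
    gi = cfg.gamma_internal_array()
    ge = cfg.gamma_external_array()

    pool = _species_pool(cfg, rng)
    site_effects = rng.normal(0.0, cfg.sigma_site, cfg.n_plots)
    # Species-level abundance weights shared across plots (correlated ranks).
    species_weight = rng.lognormal(0.0, cfg.abundance_shape, cfg.pool_size)

    plot_ids = [f"P{i + 1:02d}" for i in range(cfg.n_plots)]
    veg_bins = np.digitize(env, np.quantile(env, [1 / 3, 2 / 3]))
    veg_names = np.array(["lowland forest", "submontane forest", "montane forest"])
    lai = 6.0 * np.exp(-((env - env.min()) / max(env.max() - env.min(), 1.0)))

    leaf_rows = []
    census_rows = []
    pop_rows = []
    plot_rows = []

    for p in range(cfg.n_plots):
        pid = plot_ids[p]
        niche = np.exp(-((env[p] - pool["opt"].to_numpy()) ** 2) / (2 * cfg.niche_width**2))
        noise = rng.lognormal(0.0, cfg.abundance_plot_sd, cfg.pool_size)
        w = niche * species_weight * noise
        total_w = w.sum()
        if total_w <= 0:
            raise RuntimeError(f"plot {pid}: no species has positive membership weight")
        rel = w / total_w
        present = rel > cfg.min_rel_weight
        if not present.any():
            raise RuntimeError(f"plot {pid}: no species exceeds the presence threshold")
        if rel[present].sum() < cfg.basal_area_target:
            raise RuntimeError(
                f"plot {pid}: basal_area_target={cfg.basal_area_target} unreachable "
                f"(present species cover {rel[present].sum():.4f})"
            )

        for s in np.flatnonzero(present):
            census_rows.append((pid, pool.at[s, "species"], w[s]))

        # Dominants first, until the coverage target is reached.
        order = np.argsort(rel)[::-1]
        order = order[present[order]]
        cum = np.cumsum(rel[order])
        n_sampled = int(np.searchsorted(cum, cfg.basal_area_target) + 1)
        sampled = order[:n_sampled]

        theta_p = cfg.trait_grand_mean + cfg.beta_env * (env[p] - center)
        plot_rows.append((pid, env[p], site_effects[p], theta_p, gi[p], ge[p]))

        for s in np.flatnonzero(present):
            is_sampled = s in set(sampled)
            mu_s = pool.at[s, "mu"]
            pop_mean = (
                theta_p
                + ge[p] * (mu_s - theta_p)
                + rng.normal(0.0, cfg.sigma_pop * gi[p])
            )
            pop_rows.append((pid, pool.at[s, "species"], pop_mean, w[s], is_sampled))
            if not is_sampled:
                continue
            n_trees = int(rng.integers(cfg.trees_per_species[0], cfg.trees_per_species[1] + 1))
            for t in range(n_trees):
                tree_id = f"{pid}-{pool.at[s, 'species']}-t{t + 1}"
                tree_val = site_effects[p] + pop_mean + rng.normal(0.0, cfg.sigma_tree * gi[p])
                n_leaves = int(rng.integers(cfg.leaves_per_tree[0], cfg.leaves_per_tree[1] + 1))
                layers = [("sun", tree_val)]
                if cfg.include_shade:
                    layers.append(("shade", tree_val + cfg.shade_offset))
                for layer, base in layers:
                    log_leaf = base + rng.normal(0.0, cfg.sigma_leaf, n_leaves)
                    geom = _leaf_geometry(log_leaf, rng)
                    for j in range(n_leaves):
                        leaf_rows.append(
                            (
                                pid,
                                tree_id,
                                pool.at[s, "species"],
                                pool.at[s, "genus"],
                                pool.at[s, "family"],
                                f"{tree_id}-{layer}-l{j + 1}",
                                layer,
                                geom.at[j, "lamina_dry_mass"],
                                geom.at[j, "petiole_dry_mass"],
                                geom.at[j, "petiole_fresh_mass"],
                                geom.at[j, "lamina_fresh_area"],
                                geom.at[j, "petiole_fresh_area"],
                            )
                        )

    leaf_table = pd.DataFrame(
        leaf_rows,
        columns=[
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
        ],
    )
    census = pd.DataFrame(census_rows, columns=["plot_id", "species", "basal_area"])
    meta = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "elevation": env,
            "lai": lai,
            "vegetation_type": veg_names[veg_bins],
        }
    )
    truth = GroundTruth(
        config=cfg,
        species=pool,
        plots=pd.DataFrame(
            plot_rows,
            columns=["plot_id", "env", "site_effect", "plot_optimum", "gamma_internal", "gamma_external"],
        ),
        populations=pd.DataFrame(
            pop_rows, columns=["plot_id", "species", "pop_mean", "basal_area", "sampled"]
        ),
        variance_components={
            "site": cfg.sigma_site**2,
            "species": cfg.sigma_species**2,
            "population": cfg.sigma_pop**2,
            "tree": cfg.sigma_tree**2,
            "leaf": cfg.sigma_leaf**2,
        },
    )
    return leaf_table, census, meta, truth


def inject_artifacts(
    leaf_table: pd.DataFrame,
    zero_petiole_rate: float = 0.0,
    outlier_rate: float = 0.0,
    outlier_scale: float = 3.0,
    seed: int = 0,
):
    """Plant measurement artifacts for exercising the ingest filters.

    ``zero_petiole_rate`` zeroes the petiole dry mass of that fraction of
    leaves (emulating a balance with limited precision); ``outlier_rate``
    picks ``round(rate * n_trees)`` tree-branches and multiplies the dry
    masses of one of their leaves by ``outlier_scale``, pushing the branch
    over the tree-variance threshold.  Returns ``(modified_copy, manifest)``
    where the manifest lists every injected artifact.
    """
    if not (0 <= zero_petiole_rate <= 1 and 0 <= outlier_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    out = leaf_table.copy(deep=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    manifest_rows = []

    if zero_petiole_rate > 0:
        hit = rng.random(len(out)) < zero_petiole_rate
        out.loc[hit, "petiole_dry_mass"] = 0.0
        for _, row in out.loc[hit].iterrows():
            manifest_rows.append(("zero_petiole", row["plot_id"], row["tree_id"], row["leaf_id"]))

    if outlier_rate > 0:
        branches = out.groupby(["tree_id", "layer"], sort=True).indices
        keys = sorted(branches)
        n_hit = int(round(outlier_rate * len(keys)))
        chosen = rng.choice(len(keys), size=n_hit, replace=False) if n_hit else []
        for k in chosen:
            idx = branches[keys[k]]
            leaf_pos = idx[rng.integers(len(idx))]
            out.loc[leaf_pos, ["lamina_dry_mass", "petiole_dry_mass"]] *= outlier_scale
            row = out.loc[leaf_pos]
            manifest_rows.append(("outlier", row["plot_id"], row["tree_id"], row["leaf_id"]))

    manifest = pd.DataFrame(manifest_rows, columns=["kind", "plot_id", "tree_id", "leaf_id"])
    return out, manifest
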