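"""Configuration objects for synthetic scenarios and pipeline runs.

``ScenarioConfig`` parameterizes the synthetic gradient generator: the
hierarchical variance structure of log-LMA (site / species / population /
tree / leaf), species niche turnover along the environmental gradient, the
basal-area abundance model, the sampling design (dominant species to a
basal-area coverage target, 3-5 trees x 3-5 leaves), and per-plot internal /
environmental filter strengths.  ``RunConfig`` parameterizes an end-to-end
pipeline run over either a simulated scenario or user-supplied tables.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ScenarioConfig", "RunConfig", "config_hash"]


def _per_plot(value, n_plots: int, name: str) -> np.ndarray:
    """Broadcast a scalar or length-n sequence to a per-plot float array."""
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n_plots, float(arr[0]))
    if arr.size != n_plots:
        raise ValueError(f"{name} must be scalar or length n_plots={n_plots}, got {arr.size}")
    return arr


@dataclass
class ScenarioConfig:
    """Full parameterization of a synthetic trait gradient.

    Trait values are Gaussian on the natural-log scale of LMA (g·m⁻²).
    The defaults describe an Andes-to-Amazon style elevation gradient:
    10 plots from 200 to 3600 m, a 150-species regional pool with strong
    turnover (niche width 400 m), grand-mean LMA of 120 g·m⁻², and a
    hierarchical variance structure in which species turnover is the
    dominant source of variation.

    Parameters
    ----------
    n_plots : number of communities along the gradient.
    env : per-plot gradient value (e.g. elevation, m); defaults to a
        uniform grid over 200-3600 m.
    pool_size : species in the regional pool.
    niche_width : sd (gradient units) of the Gaussian niche kernel that
        sets plot membership weights; small values give strong turnover.
    trait_grand_mean : grand mean of log-LMA, default ln(120).
    sigma_site, sigma_species, sigma_pop, sigma_tree, sigma_leaf :
        standard deviations of the nested random effects, log scale.
    beta_env : slope of the species trait optimum versus the gradient
        (log-LMA per gradient unit), applied to the species' niche
        position centered on the gradient midpoint.
    gamma_internal : per-plot multiplier in (0, 1] on sigma_pop and
        sigma_tree — the internal (niche-packing) filter; 1 = no filter.
    gamma_external : per-plot multiplier in (0, 1] on the spread of
        admitted species means around the plot trait optimum — the
        environmental filter; 1 = no filter.
    abundance_shape : lognormal sd of species-level basal-area weights
        (shared across plots, so abundance ranks are correlated).
    abundance_plot_sd : lognormal sd of plot-level abundance noise.
    trees_per_species, leaves_per_tree : inclusive count ranges sampled
        uniformly per species / per tree.
    basal_area_target : fraction of plot basal area the sampled dominant
        species must jointly reach (default 0.80).
    include_shade : also generate a shade branch per tree.
    shade_offset : additive log-LMA offset of shade versus sun leaves.
    min_rel_weight : minimum relative basal-area weight for a species to
        be listed as present in the census.
    seed : master seed; all randomness flows from it.
    """

    n_plots: int = 10
    env: Sequence[float] | None = None
    pool_size: int = 150
    niche_width: float = 400.0
    trait_grand_mean: float = math.log(120.0)
    sigma_site: float = 0.05
    sigma_species: float = 0.25
    sigma_pop: float = 0.10
    sigma_tree: float = 0.10
    sigma_leaf: float = 0.10
    beta_env: float = 2.8e-4
    gamma_internal: float | Sequence[float] = 1.0
    gamma_external: float | Sequence[float] = 1.0
    abundance_shape: float = 1.0
    abundance_plot_sd: float = 0.3
    trees_per_species: tuple[int, int] = (3, 5)
    leaves_per_tree: tuple[int, int] = (3, 5)
    basal_area_target: float = 0.80
    include_shade: bool = True
    shade_offset: float = -0.236
    min_rel_weight: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 2:
            raise ValueError("n_plots must be >= 2")
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        if self.env is None:
            self.env = tuple(float(e) for e in np.linspace(200.0, 3600.0, self.n_plots))
        else:
            self.env = tuple(float(e) for e in self.env)
            if len(self.env) != self.n_plots:
                raise ValueError("env must have one value per plot")
        for name in ("sigma_site", "sigma_species", "sigma_pop", "sigma_tree", "sigma_leaf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        gi = _per_plot(self.gamma_internal, self.n_plots, "gamma_internal")
        ge = _per_plot(self.gamma_external, self.n_plots, "gamma_external")
        for name, arr in (("gamma_internal", gi), ("gamma_external", ge)):
            if np.any(arr <= 0) or np.any(arr > 1):
                raise ValueError(f"{name} values must lie in (0, 1]")
        self.gamma_internal = tuple(float(g) for g in gi)
        self.gamma_external = tuple(float(g) for g in ge)
        if not (0 < self.basal_area_target <= 1):
            raise ValueError("basal_area_target must be in (0, 1]")
        if self.niche_width <= 0:
            raise ValueError("niche_width must be > 0")
        lo, hi = self.trees_per_species
        if not (1 <= lo <= hi):
            raise ValueError("trees_per_species must be an increasing positive range")
        lo, hi = self.leaves_per_tree
        if not (1 <= lo <= hi):
            raise ValueError("leaves_per_tree must be an increasing positive range")

    def gamma_internal_array(self) -> np.ndarray:
        return np.asarray(self.gamma_internal, dtype=float)

    def gamma_external_array(self) -> np.ndarray:
        return np.asarray(self.gamma_external, dtype=float)

    def env_array(self) -> np.ndarray:
        return np.asarray(self.env, dtype=float)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["env"] = list(self.env)
        d["gamma_internal"] = list(self.gamma_internal)
        d["gamma_external"] = list(self.gamma_external)
        d["trees_per_species"] = list(self.trees_per_species)
        d["leaves_per_tree"] = list(self.leaves_per_tree)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("trees_per_species", "leaves_per_tree"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RunConfig:
    """One pipeline invocation: a scenario OR a triplet of input tables.

    Exactly one of ``scenario`` and ``input_paths`` must be set.
    ``input_paths`` maps the keys ``leaf``, ``census``, ``plots`` to CSV
    paths.  ``layers`` selects which leaf layers are analyzed (each layer
    is a fully separate analysis).
    """

    scenario: ScenarioConfig | None = None
    input_paths: dict | None = None
    layers: tuple[str, ...] = ("sun", "shade")
    nperm: int = 999
    alpha: float = 0.05
    seed: int = 0
    outlier_threshold: float = 2000.0
    env_variable: str = "elevation"
    out_dir: str = "traitassembly_out"
    save_null_distributions: bool = False

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.input_paths is None):
            raise ValueError("exactly one of scenario / input_paths must be set")
        if self.nperm < 99:
            raise ValueError("nperm must be >= 99")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.scenario is not None:
            d["scenario"] = self.scenario.to_dict()
        d["layers"] = list(self.layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("scenario") is not None:
            d["scenario"] = ScenarioConfig.from_dict(d["scenario"])
        if "layers" in d and d["layers"] is not None:
            d["layers"] = tuple(d["layers"])
        return cls(**d)


def config_hash(cfg) -> str:
    """Stable short hash of a config object, stamped into every output.

    The output directory is a storage detail, not part of the analysis,
    so it is excluded: runs differing only in where they write hash alike.
    """
    d = cfg.to_dict()
    d.pop("out_dir", None)
    payload = json.dumps(d, sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
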