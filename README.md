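# traitassembly

Trait-based community assembly analysis for forest plot networks, built
around leaf mass per area (LMA, g·m⁻²) measured along environmental
gradients.  The package takes leaf-level measurements, a plot basal-area
census, and plot metadata, and answers three questions a community
ecologist asks of such data:

1. **How does the community trait composition shift along the gradient?**
   Community-weighted means, `CWM_k = Σ_i μ_i f_i / Σ_i f_i` (species mean
   trait μ_i weighted by its share of plot basal area f_i, normalized by
   the summed sampled abundance), regressed on elevation or another
   covariate.
2. **Is community assembly random, or filtered?**  The T-statistic
   variance ratios, computed on log LMA per plot and compared to
   permutation null models through standardized effect sizes
   (SES = (obs − mean(null)) / sd(null)):
   - `T_ip.ic = σ²_IP / σ²_IC` — within-population over within-community
     variance.  Below-null values indicate *internal filtering* (niche
     packing): conspecifics are more similar than a random partition of
     the community.
   - `T_ic.ir = σ²_IC / σ²_IR` — community over regional variance at the
     individual level.  Below-null values indicate *environmental
     filtering*.
   - `T_pc.pr = σ²_PC / σ²_PR` — the same contrast on population means
     only (no intraspecific variation).
3. **Where does the trait variance live?**  Nested REML variance
   components (plot / family / genus / species / tree, leaf residual) and
   the exact decomposition of across-plot CWM variance into species
   turnover, intraspecific variation, and their covariance
   (`var(specific) = var(fixed) + var(specific − fixed) + cov`), plus
   Sorensen beta diversity with a Mantel test against environmental
   distance.

Because field datasets with known filter strengths do not exist, the
package ships a first-class synthetic-gradient generator
(`traitassembly.synthetic`) with a hierarchical Gaussian trait model and
explicit internal/external filter knobs, so every statistic can be
validated against a recoverable ground truth.

## Worked example

```python
import traitassembly as ta
from traitassembly.config import RunConfig, ScenarioConfig

cfg = RunConfig(scenario=ScenarioConfig(seed=1), nperm=199,
                seed=7, out_dir="demo_run")
summary = ta.run_pipeline(cfg)

reg = summary["cwm_regressions"]["sun"]
agg = summary["tstat_aggregates"]["sun"]["t_ip_ic"]
dec = summary["turnover_decomposition"]["sun"]
print(f"CWM vs elevation: r2={reg['r2']:.2f}, slope={reg['slope']:.3f} g m-2 per m")
print(f"T_ip.ic mean SES: {agg['mean_ses']:.1f} (null box {agg['pooled_null_ci']})")
print(f"turnover share of CWM variance: {dec['turnover_share']:.1%}")
```

prints (default ten-plot, 200–3600 m gradient):

```
CWM vs elevation: r2=0.97, slope=0.034 g m-2 per m
T_ip.ic mean SES: -10.6 (null box (-0.728..., 0.595...))
turnover share of CWM variance: 98.1%
```

Read: community-mean LMA climbs ~0.034 g·m⁻² per metre of elevation and
elevation explains 97% of its variation; the internal-filter statistic
sits more than ten null standard deviations below random assembly
(conspecific trees are far more similar than a random community split);
and nearly all across-plot CWM variation comes from species turnover
rather than within-species trait shifts — as expected for a gradient
with strong species replacement.

The same stages are available from the shell
(`traitassembly run|simulate|ingest|cwm|tstats|partition|beta`); outputs
land in the run directory as CSV/JSON plus a short `report.md`, each
stamped with the config hash and seed.

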