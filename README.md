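# thermoniche

Shape analysis of species **thermal-abundance distributions**: how local
abundance varies across the temperature gradient of a species' realised
range, whether abundance peaks at the centre of the thermal niche (the
abundant-centre hypothesis) or is skewed towards one edge, and what
structures that skew across a community.

The package is aimed at macroecologists working with standardised
abundance surveys — site-level mean densities of many species along a
broad environmental gradient, such as reef-fish visual-census data — and
at anyone who needs a fully synthetic, ground-truthed testbed for this
kind of analysis.

## What it computes

For each species with adequate data (≥ 30 presence records spanning
≥ 3 °C):

1. **Absence construction and balancing** — zero-abundance records at
   surveyed sites within a 10° latitude/longitude buffer of an observed
   presence, down-sampled to the number of presences.
2. **Two-stage residual analysis** — a species-level PCA of environmental
   covariates (axes explaining > 10 % variance retained) feeds a
   zero-inflated Poisson regression together with depth, protection and
   sampling intensity; temperature is excluded by construction. The 80th
   quantile of the response residuals is then modelled as a smooth
   function of temperature (penalised pinball loss, cubic regression
   spline with k = 4, bootstrapped over 25 random absence subsets).
   T_opt is the temperature of the aggregated curve's peak.
3. **Niche geometry** — thermal edges T_min, T_max as the 2.5th/97.5th
   quantiles of occupied-site temperatures; split-Gaussian scales
   σ_Tmin = |T_opt − T_min|/1.96, σ_Tmax = |T_max − T_opt|/1.96, and the
   skew statistic **T_skew = σ_Tmax − σ_Tmin** (negative = warm-skewed).
   Guilds split at T_opt = 23 °C.
4. **Shape classification** — no-trend / abundant-centre / warm-skewed /
   cool-skewed, by whether the fitted curve drops below 75 % (and, as a
   robustness check, 50 %) of its maximum at each edge, with a chi-square
   test of the category proportions.
5. **Pooled performance model** — all species standardised onto common
   axes (temperature in units of mean σ from T_opt; abundance as a
   fraction of the species maximum), 99th percentiles within 0.1-wide
   bins, and the split-Gaussian curve

   Performance(T) = c · exp(−((T − T_opt)/σ_side)²),  σ_side = σ_Tmin below
   the peak and σ_Tmax above,

   fitted by MCMC (4 chains × 10 000 iterations, burn-in 2 500, thinning
   5, Gelman–Rubin R̂ < 1.01), per thermal guild.
6. **Skew inference** — linear mixed-effects models of T_skew on T_opt
   and coral/macroalgae habitat associations with nested taxonomic
   random intercepts (order/family/genus), AICc and likelihood-ratio
   model selection, and a Wald z-test comparing guild slopes.

A first-class synthetic-data generator (`thermoniche.synthetic_data`)
produces site tables, species ground truths and zero-inflated
split-Gaussian survey counts with known T_opt, σ's and skew, so every
stage can be validated against truth.

## Worked example

```python
import thermoniche as tn
from thermoniche import pooled_shape as ps, pipeline

sites, species, records = tn.simulate_community(
    n_sites=800, n_species=8, skew_scenario="mixed", seed=42)
results = tn.run_community(records[records["count"] > 0], sites,
                           n_boot=10, seed=42)
print(tn.profiles_frame(results)[["species_id", "topt", "tmin", "tmax",
                                  "tskew", "guild", "shape"]].round(2))
```

```
species_id  topt  tmin  tmax  tskew     guild           shape
    sp0000 25.93 19.90 29.21  -1.41  tropical abundant_centre
    sp0005  5.40  5.40 14.56   4.67 temperate     cool_skewed
    sp0007 15.93  9.98 20.12  -0.90 temperate abundant_centre
    ...
```

Each row is one species' realised niche: `topt` is the temperature of
peak modelled maximum abundance, `tmin`/`tmax` the realised thermal
edges, `tskew` the edge imbalance (sp0005 is strongly cool-skewed: its
optimum sits against the cool end of the sampled gradient), and `shape`
the categorical classification at the 75 % threshold.

Pooling the same community and fitting the split-Gaussian model:

```python
binned = pipeline.pooled_inputs(results)
post = ps.fit_split_gaussian(binned, seed=42)
print(post.summary.round(3))
```

```
                mean     sd   q2.5  q97.5   rhat
c              0.759  0.019  0.722  0.796  1.000
topt_std      -0.430  0.064 -0.554 -0.309  1.000
sigma_min_std  1.236  0.083  1.079  1.401  1.000
sigma_max_std  1.421  0.097  1.233  1.616  1.000
tskew          0.185  0.160 -0.125  0.497  1.000
```

`c` is the height of the abundance peak: even at their optimum
temperature, species reach only ~76 % of their maximum observed
abundance in this small community. All R̂ < 1.01, so the chains are
converged; the pooled `tskew` interval covers zero (no average
asymmetry here).

A thin CLI mirrors the stages: `thermoniche simulate | prep | peaks |
pooled | skew` (see `thermoniche --help`).

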