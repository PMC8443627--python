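# islandstr

Temporal turnover and community-assembly processes for island-like
microbial communities.

Small discrete habitats — water-filled tree-holes at the base of a tree,
rock pools, bromeliad tanks — behave like an archipelago of islands that
share a common immigration source. Censusing the bacterial community of
each island repeatedly over a year yields, per island, a taxon × census
presence/absence matrix. `islandstr` turns such matrices into the two
classic quantitative summaries of island community dynamics:

1. **Species–time relationships (STR).** Observed richness *S* grows with
   the observation span *T* following the power law *S = cT^w*, the
   temporal analogue of the species–area relationship *S = cA^z*. The
   scaling exponent *w* (the log–log slope) measures temporal turnover.
   Three window constructions are provided, because the choice materially
   changes *w*:
   - **MW** (moving window): walks the series pairwise and re-counts a
     taxon every time it re-appears after a local absence;
   - **CMW** (cumulative moving window): counts only first appearances
     (a running union / accumulation curve);
   - **EPW** (every possible window): accumulates richness within every
     contiguous window of every span and averages within span.
2. **Raup–Crick similarity (s_rc) and assembly processes.** For every
   within-island census pair, the observed shared-taxon count is ranked
   against a Monte-Carlo null that redraws both communities at fixed
   richness from the regional pool (occupancy-weighted by default). The
   index is rescaled to [−1, 1] as a similarity:
   `s_rc = 2·(P(null < obs) + ½·P(null = obs)) − 1`. Pairs with
   s_rc ≥ 0.95 indicate homogenizing dispersal, ≤ −0.95 dispersal
   limitation (selection), and values in between ecological drift.

Power laws are fitted by OLS on log10–log10 scale; exponents are compared
across methods by one-way ANOVA and regressed on island size (volume,
area), series duration, and other covariates. A neutral
immigration–extinction simulator generates synthetic archipelagos with a
species–volume law and volume-dependent turnover, so the whole pipeline is
testable without any sequencing data.

## Worked example

Run the full pipeline on the default synthetic archipelago (10 islands,
500-taxon shared pool, 20 censuses each, volumes 50–5000 mL) and print the
summary:

```sh
islandstr run-all --seed 42 --out-dir demo_run
islandstr report --bundle-dir demo_run
```

which prints (abridged):

```
## Temporal scaling exponents (w)

- MW: mean w = 0.531 ± 0.102 (range 0.391–0.684, n = 10 islands)
- CMW: mean w = 0.269 ± 0.102 (range 0.115–0.417, n = 10 islands)
- EPW: mean w = 0.271 ± 0.104 (range 0.117–0.423, n = 10 islands)

## Assembly processes (% of census pairs per island)
...
- mean homogenizing dispersal = 69.1 ± 9.3%
- mean drift = 30.9 ± 9.3%
- mean dispersal limitation = 0.0 ± 0.0%

## Island-size relationships

- richness ~ volume: slope = 0.2495, R² = 1.00, F(1,8) = 3.935e+04, p = 4.67e-16
- w [CMW] ~ volume: slope = -0.1512, R² = 1.00, F(1,8) = 1666, p = 1.43e-10
...
```

Reading the numbers: MW yields systematically higher *w* than CMW/EPW
because it re-counts recurrent taxa — the generator allows local
extinction followed by re-immigration, so gross turnover (MW) exceeds net
accumulation (CMW/EPW). The species–volume slope recovers the generating
exponent z_v = 0.25, and *w* declines significantly with log10 volume:
larger islands turn over more slowly. Most census pairs are more similar
than the regional-pool null expects (homogenizing dispersal), as expected
for a metacommunity with a single shared immigration source; dispersal
limitation is essentially absent.

The same stages are available piecewise (`islandstr simulate`, `str`,
`fit`, `rc`, `classify`) on TSV files — a taxon table (first column
`taxon_id`, one integer column per sample) plus a sample metadata table
(`sample_id`, `island_id`, `day`, `area_cm2`, `volume_ml`) — and as a
library (`islandstr.run_all`, `islandstr.build_str`,
`islandstr.raup_crick_island`, ...). See `docs/methods.md` for the model
and every numerical convention.

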