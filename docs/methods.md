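# Methods

## Data model

An archipelago dataset is a set of island community time series plus size
metadata. Each island carries a taxon × census boolean presence matrix,
integer census days re-based so the island's first census is day 0 (only
elapsed time enters any computation), and optional counts. Presence is
scored as count ≥ `presence_threshold` (default 1 read; tables are assumed
to have been denoised upstream, e.g. singleton removal during OTU
clustering). Taxon labels are opaque strings; taxonomy plays no role.
Samples with zero observed taxa are rejected at load, because log-richness
and fixed-richness null draws are undefined for empty communities. The
regional pool is the exact union of taxa observed anywhere in the dataset,
and each pool member's occurrence frequency is the number of samples
(dataset-wide) in which it occurs.

Island size supports either a single measurement per island or a
per-census series (aquatic habitats refill and drain between visits); with
a series, the summary size is the mean over censuses and its sample SD is
retained for error bars. The sample SD (n−1 denominator) is used for every
"mean ± SD" in the package.

## STR construction

All three constructions share one definition of a *new* taxon: a taxon
counts as new in the last census of a window only if it is absent from the
window's earlier census (MW) or cumulative earlier censuses (CMW/EPW).

- **MW**: point 1 is the first census's richness; point t adds the taxa
  present at census t but absent at census t−1. Recurrent taxa are counted
  at every re-appearance, so MW measures gross immigration.
- **CMW**: point t is the union richness of censuses 1..t; the final point
  is the island's total observed richness.
- **EPW**: for each span k there are n−k+1 contiguous windows; each
  window's value is the union richness of its censuses (chaining first
  appearances within a window reduces to the union on presence/absence
  data), and point k is the mean over windows. EPW(1) equals the mean
  per-census richness and EPW(n) equals the CMW endpoint exactly.

Useful orderings hold by construction: MW ≥ CMW pointwise, with equality
iff no taxon re-appears after a local absence.

**Span unit.** Spans are counted in censuses (T = 1..n), the only
convention under which log T is defined for single-census windows, and the
mean day extent of each point's windows is emitted alongside
(`span_days_mean`). An optional "days" unit for fitting offsets day
extents by the median inter-census gap to keep the span-1 point in the
positive domain. EPW groups windows by census-count span even when day
extents differ between windows under irregular sampling. The span-1 point
is included in fits by default and can be dropped (`include_span1=False`).

## Power-law fits and regressions

STR, species–area and species–volume laws are fitted by OLS of log10(S) on
log10(T or A or V): the exponent is the slope and c = 10^intercept. This
is the convention under which R², F(1, n−2) and p summaries are reported
in the SAR/STR literature; a nonlinear least-squares refinement on the
original scale is available as an option, never the default. A flat
response is reported as exponent 0 with R² = 0, F = 0, p = 1 (the
statistic carries no signal rather than being undefined). Fits on fewer
than 3 points are flagged degenerate (F/p NaN, no residual df). p-values
are two-sided from the F distribution; no multiple-testing correction is
applied anywhere.

Per-method exponent sets are compared by one-way ANOVA with df (1, N−2);
the reported R² for a comparison is eta-squared (between-group over total
sum of squares), labelled as such. For two groups, F equals the squared
pooled-variance t statistic, which the tests cross-check.

## Raup–Crick null model

For a census pair with observed shared-taxon count `obs`, each of
`n_rand` randomizations (default 1000) draws one null community matching
each member's richness from the regional pool, without replacement, with
inclusion probability proportional to occurrence frequency (default) or
equiprobable. The rescaled similarity is

    s_rc = 2·( #{null < obs} + ½·#{null = obs} ) / n_rand − 1

Ties get half weight, which makes the forced-sharing degenerate case (both
communities equal to the pool) land exactly at 0, and orients the index as
a similarity: +1 means far more shared taxa than chance. Under the
equiprobable option the null shared count is exactly hypergeometric, and
the closed form `exact_src_unweighted` serves as an independent oracle for
the Monte-Carlo path in the tests.

Weighted sampling without replacement uses exponential sort keys
(Efraimidis–Spirakis): taxon i receives key Exp(1)/w_i and the smallest
keys win, equivalent to sequential draws proportional to remaining
weights. Within an island, one null ensemble is drawn per census at that
census's richness and every pair is ranked against the shared counts
between the two censuses' ensembles; this is statistically equivalent to
independent per-pair draws, makes the result symmetric in pair order by
construction, and costs O(n·n_rand·pool) instead of O(n²·n_rand·pool).
Each island gets its own seeded stream, recorded in the run summary.

The regional pool and its weights are global (all islands, all censuses)
and applied identically to every island. Classification uses inclusive
thresholds: s_rc ≥ 0.95 homogenizing dispersal, ≤ −0.95 dispersal
limitation (selection), otherwise drift; per-island percentages sum
to 100. Between-island pairs are not compared, and speciation is not
modeled (negligible on within-year timescales for 97%-identity taxa).

## Synthetic archipelago generator

The generator emulates a year-long survey of ~10 tree-hole-like islands
sharing one immigration source: 20 censuses per island at irregular
7–35-day gaps (≈400-day span), volumes log-spaced 50–5000 mL (two orders
of magnitude), areas tied to volume by A = 3·V^(2/3) (isometric
surface–volume scaling), and a 500-taxon shared pool with lognormal
(σ = 1) abundance weights.

Per island j:

- equilibrium richness S_j = round(c_v·V_j^z_v) with defaults c_v = 40,
  z_v = 0.25 — a species–volume exponent in the range reported for
  aquatic microbial islands, giving richness ≈ 106–337 across the volume
  range;
- each census, every resident goes locally extinct with probability
  e_j = min(1, e0·(V_ref/V_j)^α), defaults e0 = 0.10 at the largest
  volume and α = 0.25, so per-census turnover runs from ≈ 10% (largest)
  to ≈ 32% (smallest island) — chosen as a realistic contrast that spans
  the slow-to-fast turnover regime;
- immigration redraws taxa (weighted, without replacement) from the taxa
  absent at the previous census until richness returns to S_j. A taxon
  lost in a step cannot re-immigrate within that same step, so the
  realized per-census replacement fraction is binomially distributed
  around e_j (asserted in the tests); re-immigration in later steps is
  allowed, which is what separates MW from CMW/EPW.

Richness is pinned at S_j (immigration balances extinction) so STR
curvature reflects turnover, not richness drift. α = 0 makes turnover
size-independent; e0 = 0 freezes every community (all exponents exactly
0). A null variant redraws every census independently at fixed richness —
no temporal persistence — as a maximal-turnover, drift-dominated negative
control. Everything is deterministic given the seed: the master seed
spawns one stream for global structure and one per island.

**What the generator does and does not emulate.** It reproduces the
structural features the analysis relies on — shared pool, high
between-island overlap, richness increasing and turnover decreasing with
volume, recurrence of locally extinct taxa, irregular sampling — and under
the defaults the pipeline recovers the inverse size–turnover relationship
and the MW ≥ CMW exponent ordering. It does not model read-count noise,
abundance dynamics, seasonality, or density-dependent drift, so passing
tests demonstrate correctness of the statistical machinery, not fidelity
to any particular sequencing dataset. One emergent caveat: at the default
configuration the largest islands hold a large fraction of the pool
(≈ 340/500), and under the occupancy-weighted null such saturated
communities produce narrow null distributions; temporally decorrelated
census pairs there can score as drift or even anti-similarity, so the
drift-versus-volume regression on synthetic data need not be negative even
though turnover-versus-volume always is. Conclusions about how drift
frequency scales with island size should come from data, not from this
generator.

## Pipeline and reproducibility

`run_all` executes load/simulate → STR curves → per-island power-law fits
→ cross-method ANOVA and regressions → size summaries and species–area /
species–volume fits → w-versus-volume and w-versus-duration regressions →
Raup–Crick → classification → process-versus-volume regressions, and
writes each result family as a TSV (floats at fixed `%.6g` precision)
plus `run_summary.json` holding parameters, the master seed, the derived
per-island null-model seeds and the package version. Reruns with the same
configuration are byte-identical. The report renders only numbers
recomputable from the emitted tables.

Default problem sizes (10 islands × 20 censuses, 1000 randomizations per
census pair) run the whole pipeline in a few seconds on one core; the test
suite's Monte-Carlo consistency grid uses 10 000 randomizations on pools
of ≤ 12 taxa where the hypergeometric closed form is exact.
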