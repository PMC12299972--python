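# Methods

This note records the models, conventions and numerical choices behind the
pipeline, and what its synthetic data can and cannot show about real plates.

## Plate model and blank correction

The structural model is the commercial EcoPlate: 96 wells, three replicate
blocks occupying column ranges 1–4, 5–8 and 9–12, each block holding the
same 31 substrates plus one water control (A1, A5, A9). The well map is
config-overridable (`layout.csv`), and validation rejects any plate that is
not exactly this shape: every substrate present once per block, one control
per block, a consistent guild per substrate. Guild membership follows the
usual six-category grouping of the 31 EcoPlate substrates (10 carbohydrates,
6 amino acids, 7 organic acids, 4 polymers, 2 phenolic acids, 2 amines);
since classifications of a few substrates vary between labs (e.g.
pyruvic acid methyl ester, D-glucosaminic acid), the layout file is the
single source of truth and can be edited.

Blank correction happens within blocks — each block's own control reading
R_b is subtracted from that block's substrate wells — and the three
corrected replicates are then averaged. This ordering matters when control
wells drift differently across the plate. A time point whose control well is
missing in any block is skipped with a warning rather than imputed; a
substrate missing in all three blocks is an error.

Negative C_i − R_i differences are floored at zero before any index is
computed. This is standard CLPP practice and is required for the logarithm
in H; the unfloored block-mean differences are preserved on every profile,
and AWCD can be computed from them via a flag. Whether published analyses
floor is typically unstated; the default here is the floored form.

## Indices

With n_i the floored utilization values and p_i = n_i/Σn_i:

* AWCD = Σn_i/31. Dimensionless OD difference.
* H = −Σ p_i ln p_i, natural log, with 0·ln 0 := 0. Range [0, ln 31].
* D = 1 − Σ p_i². Range [0, 30/31].
* U = Σ n_i² by default, with `form="sqrt"` giving the conventional
  McIntosh √Σ n_i². The squared form is kept as the default because it is
  what many CLPP papers print; the chosen form is recorded in every output
  row (`mcintosh_form`), so downstream consumers never have to guess.

A profile with Σn_i = 0 yields missing H and D (with a warning), never 0:
"no detectable activity" must stay distinguishable from "one dominant
substrate", which legitimately has H = 0. p_i is defined on the corrected
substrate utilizations, not on raw or control-well absorbances — the only
definition under which H and D behave as evenness measures.

## Group comparisons

The routing reproduces the common soil-science workflow. For each variable:

1. Shapiro–Wilk on the pooled one-way residuals (observations minus group
   means) and Levene across groups, both at α = 0.05. Residual testing,
   rather than per-group testing, matches the downstream ANOVA model and is
   stable at the small group sizes typical of pot experiments (n = 3);
   per-group Shapiro at n = 3 has essentially no power.
2. Both pass → one-way ANOVA + Tukey HSD (statsmodels; studentized-range
   adjusted p-values, no further correction).
3. Either fails and all values are positive → re-test after a natural-log
   transform; pass → ANOVA on ln(x), recorded as `transform="log"`.
4. Otherwise → Kruskal–Wallis (tie-corrected) + Dunn's multiple-comparison
   z tests with the tie-corrected pooled-rank variance, Benjamini–Hochberg
   adjusted within the k(k−1)/2 family. Dunn's test is implemented here
   directly (tie term T = Σ(t³−t) subtracted from the rank variance).

Constant data route nonparametrically with a warning, since Shapiro–Wilk is
undefined. The compact letter display uses insert-and-absorb: start from one
column holding all groups, split columns on each significant pair, absorb
contained columns, then assign letters with columns sorted by their
alphabetically smallest member — deterministic, and the letter sets encode
exactly the thresholded significance graph (round-tripped in tests).

Correlation matrices are available as Spearman (average ranks on ties; the
method usually quoted for nutrient–index tables) and Pearson (often used for
display heatmaps); both are exported, neither is privileged.

## Ordination

PCA operates on the correlation matrix by default: nutrients (g/kg, mg/kg)
and diversity indices (nats, unitless) are incommensurate, so covariance
PCA would be dominated by whichever variable has the largest numeric range.
A `scale="covariance"` flag exists for homogeneous tables. Loadings are
eigenvectors scaled by √eigenvalue (variable–component correlations under
the correlation scaling); the sign convention makes the largest-|loading|
entry of each component positive, so repeated runs and platforms agree.
Explained fractions are eigenvalues over their total and sum to 1.

RDA is the eigenanalysis of the fitted values of the multivariate
least-squares regression of the standardized response table on the
standardized predictor table. Significance uses unrestricted row permutation
of the response (no strata are modeled):

pseudo-F = (SS_constrained/q) / (SS_residual/(n − q − 1)),

with q the predictor rank after collinear columns are dropped by pivoted QR.
The permutation p-value uses the add-one convention (1 + b)/(1 + m), so the
smallest attainable p with 999 permutations is 0.001 and p is never 0. The
permutation RNG is seeded and the seed recorded in the output. The pseudo-F
and constrained-axis fractions were cross-checked against vegan's
`rda`/`anova.cca` on a frozen fixture (agreement to 6 decimal places; see
`tests/test_ordination.py`).

The ordination variable list is explicit configuration rather than a
hard-coded count, since studies differ in how many of the measured
physicochemical parameters enter the integrated matrix.

Radar normalization min–max scales each variable's treatment means onto
[0, 1]; a variable with identical means everywhere maps to 0.5 with a
warning (drawing at the midline rather than collapsing the polygon).

## Synthetic experiments

The generator exists so the full pipeline — file I/O included — is testable
with no instrument data. Substrate wells follow

OD(t) = blank(t) + capacity · K_g · logistic(r_g (t − t0_g)) · m(t) + ε,

truncated at 0, with blank(t) = 0.05 + 0.0002·t (OD units), per-reading
Gaussian noise ε (sd 0.02 OD, a typical reader/plate repeatability figure),
and a per-plate lognormal capacity (σ = 0.08) standing in for pot-to-pot
variation in inoculum density and community state. m(t) encodes the
archetype: 1 (stable/inactive), a Gaussian mid-course dip 1 − a·exp(−(t −
t_dip)²/2w²) (biphasic), or exp(−d·max(0, t − t_peak)) (transient). All
wells of a guild share kinetics; the three replicate blocks share parameters
and differ only in noise.

The packaged preset has five archetypes × 3 replicate pots on the 0–168 h
24-hour grid: a weak, carbohydrate-skewed control (`ck`), a strong and even
stable treatment (`s75`), a strong but less even biphasic one (`s4`), and
two intermediate transient ones (`s32`, `s59`). Guild asymptotes were chosen
once, from the closed-form guild H and plateau-AWCD formulas, so that the
preset's plateau AWCD and mean H order as s75 > s4 > {s32, s59} > ck with
margins of several replicate-level standard deviations; the ordering is a
designed property of the configuration at its packaged seed, not an
empirical finding. Nutrient marginals (e.g. AK 110 ± 12 mg/kg, TC 15 ± 1.5
g/kg) are round placeholder values in realistic ranges for acid forest
soils, not measurements.

Nutrient–function coupling uses a Gaussian copula on the normal scores of
the ranks of each plate's realized final-time AWCD (computed through the
actual pipeline, noise included), with the Spearman target converted to the
latent Pearson scale by ρ_P = 2 sin(πρ_S/6). This meets Spearman targets
regardless of marginal shapes. Treatment-level nutrient shifts are added
after coupling, so the preset's realized nutrient–AWCD correlations exceed
the per-sample targets — as in real experiments, where treatment structure
and within-treatment coupling both contribute.

What the generator does **not** emulate: substrate-level kinetic
heterogeneity within guilds, non-Gaussian reader noise, spatial plate
effects (edge evaporation), inoculum-density dilution effects, or any
mechanistic soil chemistry. Passing tests therefore demonstrate that the
analysis is correct for sigmoidal, guild-structured color development with
independent well noise — not that any biological conclusion from a real
plate is right.

## Numerical and design choices

* Fixed CSV dialect (comma, UTF-8, header, "." decimals), floats written in
  shortest round-trip repr and parsed with pandas'
  `float_precision="round_trip"`: write → read is bit-exact, which the
  suite asserts on every product.
* Times are decimal hours; the 24 h grid is a convention of the assay
  protocol, not a requirement — arbitrary strictly increasing grids work.
* Missing readings stay NaN end to end; each operation states its policy
  (skip the time point, average available blocks, error) instead of
  imputing.
* Calibration simulations (test suite and acceptance script) use 5 groups
  of 20 with 2,000 replicates: at 20 per group the Kruskal–Wallis
  chi-square approximation's true level is ≈ 0.047 (measured at 40,000
  replicates), close enough to nominal for a [0.035, 0.065] band at this
  replicate count; at very small group sizes (n = 3–10) the approximation
  is visibly conservative (level ≈ 0.02–0.045).
* Permutation-RDA checks use 199 permutations across many seeds for
  uniformity checks and 999 for single calls; problem sizes throughout
  (n = 15–60 samples, 100–500 seeds) are chosen to give stable Monte-Carlo
  estimates in seconds on one core.
* α = 0.05 everywhere by default; every α, seed, permutation count and
  McIntosh form is recorded in outputs or the run manifest.

## Known limitations

* The normality gate's pass rate depends on α in both directions (a larger
  α is a *stricter* normality requirement), so routes — and therefore
  letters — can change non-monotonically with α.
* Dunn + BH at n = 3 per group has limited power; only large effects (a few
  pooled SDs) are reliably lettered, which matches the pot-experiment
  design it mirrors.
* RDA assumes exchangeable rows under the null (unrestricted permutation);
  repeated-measures or blocked designs would need restricted permutation,
  which is not implemented.
* The McIntosh `paper` default (Σn_i²) is not the conventional U; users
  comparing against older CLPP literature should pass `form="sqrt"`.
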