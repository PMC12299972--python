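# ecoplate

Community-level physiological profiling (CLPP) of soil microbial communities
from Biolog EcoPlate™ OD590 time series — a tested, reusable pipeline from
raw microplate-reader exports and a soil-nutrient table to metabolic-activity
and functional-diversity trajectories, substrate-guild profiles, routed group
statistics, ordination, and nutrient–function correlation.

It is written for soil/rhizosphere microbiologists who run EcoPlate assays
(e.g. to compare inoculation or amendment treatments across potted or field
soils) and want the whole analysis — blank correction, diversity indices,
normality-gated tests, compact letter displays, PCA/RDA — reproducible from
the command line or from Python, instead of spread across spreadsheets.

## The measurements and statistics

An EcoPlate carries 31 sole-carbon substrates plus a water control, each in
three replicate blocks; respiration reduces a tetrazolium dye, so well
absorbance at 590 nm tracks substrate utilization. With C_i the absorbance of
a substrate well and R_i its block's control well, the pipeline computes, per
plate and time point, n_i = mean over blocks of (C_i − R_i) (floored at zero
by default) and:

* **AWCD** = Σ(C_i − R_i)/n with n = 31 — average well color development,
  the standard proxy for overall metabolic activity;
* **Shannon H** = −Σ p_i ln p_i with p_i = n_i/Σn_i (nats, ≤ ln 31);
* **Simpson D** = 1 − Σ p_i² (functional evenness, ≤ 30/31);
* **McIntosh U** = Σ n_i² (with a `sqrt` option for the conventional
  Euclidean-norm form √Σ n_i²).

Substrates aggregate into six guilds (carbohydrates, amino acids, organic
acids, polymers, phenolic acids, amines). Treatment comparisons follow a
normality gate: Shapiro–Wilk on one-way residuals and Levene across groups
route each variable to ANOVA + Tukey HSD, via a natural-log re-test, or to
Kruskal–Wallis + Dunn's test with Benjamini–Hochberg adjustment; results
carry compact letter displays. Nutrient–function structure comes from
correlation-matrix PCA with biplot loadings, Spearman/Pearson correlation
matrices, and redundancy analysis (RDA) with a pseudo-F permutation test
(p = (1 + #{F* ≥ F})/(1 + 999) by default).

A synthetic-data module generates full experiments (logistic color
development with guild- and treatment-level kinetics, Gaussian-copula
coupling between nutrients and realized metabolic capacity) so every stage
is testable without any instrument export.

## Worked example

Simulate the packaged five-treatment study (an untreated control `ck`, a
stable high performer `s75`, a biphasic `s4`, two transient treatments
`s32`/`s59`, 3 replicate pots each, readings every 24 h over 168 h), then run
the full pipeline:

```sh
ecoplate simulate --seed 2025 --outdir inputs
ecoplate run --plates inputs/plates.csv --layout inputs/layout.csv \
             --nutrients inputs/nutrients.csv --n-perm 999 --seed 1 \
             --outdir results
```

`results/trajectories.csv` holds the four indices per plate and time point:

```
sample_id treatment  time_h     awcd  shannon  simpson  mcintosh mcintosh_form
    ck_r1        ck    72.0 0.087379 3.113590 0.946730  0.390854         paper
    ck_r1        ck   168.0 0.118609 2.704798 0.924659  1.018577         paper
   s75_r1       s75    72.0 1.035386 3.428168 0.967376 33.610031         paper
   s75_r1       s75   168.0 1.528139 3.427783 0.967351 73.268245         paper
```

The control plate barely develops color (AWCD ≈ 0.12 at 168 h) and its
evenness erodes as a few carbohydrate wells dominate (H falls to 2.70);
the `s75` plate is an order of magnitude more active (AWCD ≈ 1.53) with
near-maximal evenness (H ≈ 3.43 ≈ ln 31). `results/comparisons.csv` gives
the routed tests with letters — e.g. for available potassium (AK), `ck`
differs from every treated group, and `s75` from all others:

```
group_a group_b   p_adjusted letters_a letters_b
     ck     s32 1.399359e-02         a         b
     ck      s4 2.211585e-04         a         b
     ck     s59 6.801879e-03         a         b
     ck     s75 2.428452e-07         a         c
```

`results/ordination_summary.csv` reports that PC1 of the joint
nutrient + index table carries 80.9% of the variance (nutrient availability
and metabolic activity move together in this preset), and the RDA of the
four indices on the seven nutrients is significant at the permutation floor:

```
component  explained_fraction  pseudo_f  permutation_p
     RDA1            0.857542 10.035675          0.001
```

Every output, including `manifest.json` (inputs, seed, per-variable gate
decisions, surfaced warnings), is byte-reproducible from the same config and
seed. The same operations are available as library functions
(`ecoplate.diversity_trajectory`, `ecoplate.compare_groups`,
`ecoplate.rda_permutation_test`, …).

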