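# Methods

`tmtdyn` implements the post-search quantitative analysis of a multi-plex
TMT10 proteome dynamics experiment: two *Saccharomyces cerevisiae* strains (a
control and a minimal-glycolysis mutant, "CTRL" and "MG") sampled across
growth phases under aerobic (ME, LE, ED, MD, MS) and anaerobic (ME, LE, ES,
MS) conditions, in biological triplicate with two technical replicates each,
quantified as reporter-ion intensities in fourteen TMT10 plexes that each
carry two bridge channels filled with a common reference pool.

## Bridging-channel normalization

Reporter intensities are only comparable within a plex. The pipeline
therefore expresses every protein in every sample channel as a fold change
relative to the plex's bridge reference,

    FC_ip = I_ip / mean(I_i,bridge1, I_i,bridge2),

where the arithmetic mean of the two bridge channels is the default combiner
(a geometric-mean option exists; the choice is immaterial at the bridge
channels' small technical spread and the arithmetic form matches how the
physical pool is mixed). Any multiplicative plex-wide batch factor cancels
exactly in this ratio, which is the design's entire purpose; the package
verifies cancellation to 1e-10 under injected four-fold batch factors.
Proteins missing in both bridge channels of a plex are emitted missing and
flagged. Cross-plex assembly takes the union of proteins with per-sample
missingness preserved.

Technical replicates are averaged arithmetically on the linear fold-change
scale after bridge normalization (normalize-then-average; the order is
configurable and makes no difference for noise-free data). Biological
replicates are summarized per strain × condition × phase as mean, sample SD
(n−1 denominator), n, and RSD = 100·SD/mean.

### Channel scaling

`scale_channels` offers two within-plex loading corrections: equal-total
scaling (all channel totals over complete rows set to the plex mean total)
and median-of-ratios size factors (DESeq-style, robust to moderate
composition shifts). **Neither runs by default in `process_plexes`.** Search
engines export channel-normalized reporter tables already, and on data whose
composition genuinely shifts between growth phases — stationary-phase
channels really do carry more storage/stress protein mass — rescaling to
equal totals biases every fold change by the composition ratio. On the
synthetic design this bias measures +0.29 mean log2 units for equal-total
scaling and +0.04 for median-of-ratios, versus ≤0.013 with scaling off.
Scaling remains available for genuinely unnormalized exports.

## Differential abundance

Per contrast (two phases within a strain×condition, or two conditions at a
phase), FC is the ratio of linear-scale replicate means and significance
comes from a two-sided two-sample t-test on the summary statistics. Two test
forms are provided:

* **pooled** (default): the equal-variance Student form — the exact
  computation of `scipy.stats.ttest_ind_from_stats` at its default
  arguments. At triplicate scale it is correctly sized: under a null
  simulation (10,000 proteins, lognormal noise at 15% RSD, n = 3) it rejects
  4.8–5.2% at p < 0.05.
* **welch**: the unequal-variance statistic with Welch–Satterthwaite degrees
  of freedom. At n = 3 this form is markedly conservative (true size ≈
  0.035, measured by 200,000-draw simulation under both normal and
  lognormal noise) because the degrees of freedom are estimated from two
  sample variances. It is the better choice when group variances can
  genuinely differ and n ≥ 5.

The volcano rule classifies each protein as *significant* (p < 0.05 and
linear FC beyond 1.25-fold, i.e. |log2 FC| > log2 1.25 ≈ 0.32, symmetric for
down-regulation), *statistical_only* (p threshold alone) or *insignificant*.
No multiple-testing correction is applied to per-protein tests — the raw
dual-threshold rule is the convention this pipeline reproduces — and
BH-adjusted q-values are an opt-in column. Proteins quantified in fewer than
two biological replicates of either group are left unclassified with a
reason code; transition-count tables count classified proteins
(`n_quantified`) and split the significant class by direction. Proteins with
zero variance in both groups (the noise-free limit) are classified by exact
separation: equal means → p = 1, different means → p = 0.

## emPAI absolute abundance

In-silico digestion uses the trypsin rule (cleave C-terminally of K/R, not
before P; the proline block can be disabled) with configurable missed
cleavages (default 0 for observable counting, per the original index
definition). A peptide is *observable* when at least one charge state z ∈
{2, 3} puts its monoisotopic m/z inside the instrument acquisition window,
385–1250 m/z by default; both window and charges are configurable and are
logged with every run. N_observed counts distinct peptide sequences. Then

    PAI = N_observed / N_observable,   emPAI = 10^PAI − 1,

with molar fraction emPAI/ΣemPAI and mass fraction emPAI·MW/Σ(emPAI·MW)
(average MW from the FASTA sequence; peptide masses are monoisotopic).
Proteome mass coverage assigns every database protein absent from the
identified set the lowest observed emPAI as a floor and reports the
identified share of Σ emPAI·MW; mass weighting is the headline statistic
(the quantity of interest is protein mass), molar weighting is an option.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
P[X ≥ k] per gene set, after intersecting each set with the explicitly
supplied background — the genes detected across the experiments, never
defaulted to the whole genome — and Benjamini–Hochberg adjustment across
tested sets (FDR threshold 0.05). Sets with fewer than two background
members are skipped and logged. This is the standard local ORA statistic; a
web-service enrichment score is not reproducible offline, and the
hypergeometric/BH combination respects the custom-background semantics. A
small GMT of yeast central-carbon-metabolism pathways ships with the package
for convenience.

## Replicate power planning

Effect size follows d = (FC − 1)/(RSD/100): the reference group mean is 1 on
the fold-change scale and both groups share SD = RSD/100 (a log-scale
alternative d = ln FC / ln(1 + RSD/100) is available). Power is that of the
two-sided equal-variance two-sample t-test from the noncentral t
distribution (statsmodels `TTestIndPower`, with a direct scipy noncentral-t
fallback where statsmodels' evaluation overflows at large noncentrality).
`required_n` finds the smallest integer n ≥ 2 reaching the target power by
doubling/bisection on the monotone power curve, so achieved power at n meets
the target while n−1 does not (when n > 2; n = 1 has zero degrees of
freedom). The default planning grid crosses FC ∈ {1.25, 1.5, 2, 2.5, 3}
with RSD ∈ {5, 10, 15, 20, 30}% at alpha 0.05 and power 0.8; at 15% RSD,
three replicates suffice for 1.5-fold changes while 1.25-fold changes need
seven.

## Clustering and reports

Sample-profile distances are Euclidean on log2 bridge-relative values
(log2 makes the metric symmetric in fold direction; a linear option exists),
computed over proteins present in every sample (`complete_only`), without
row standardization. Agglomeration is average linkage (UPGMA). Replicate
clustermaps are computed per strain and condition, with the four
strain×condition subsets treated separately. Heatmap matrices re-reference
phase means to the mid-exponential phase within each strain×condition, so
the reference column is identically zero. All figure outputs are data
tables (volcano: log2FC, −log10 p, class; circle graphs: area proportional
to emPAI, radius √(emPAI/π)); rendering is a thin optional layer so tests
assert numbers.

## Synthetic data generator

The generator is first-class, tested code that defines the study conditions
end to end. Defaults (units in parentheses):

| parameter | default | rationale |
|---|---|---|
| n_proteins | 1000 | desk-scale stand-in for the ~1100–1200 proteins quantified per condition |
| baseline abundance | log-normal, log10 N(2, 0.8) | ~3 decades of dynamic range typical of one-dimensional shotgun TMT |
| biological RSD | 15% | upper end of controlled-bioreactor replicate variation |
| technical RSD | 5% | reporter-ion repeatability of technical injections |
| plex batch RSD | 40% | between-run global intensity drift the bridge must remove |
| channel loading RSD | 2% | residual mixing error in *exported* (already channel-normalized) tables |
| missingness | logistic in log10 latent abundance, midpoint 0.5, scale 0.35, per protein × plex | detection happens at precursor level, so whole plexes drop out for a protein, preferentially at low abundance (MNAR); MCAR and none are options |
| layout | 14 TMT10 plexes, bridges in channels 126/131 | 6 anaerobic plexes of exactly one strain × replicate (8 samples), 8 aerobic plexes packing 60 sample-channels |

All noise is multiplicative log-normal (reporter intensities are positive
and heteroscedastic on the linear scale); RSD r converts to ln-scale sigma
via σ = √ln(1+r²). The bridge pool is the arithmetic mean of the three MG
aerobic mid-stationary biological replicates, mirroring the reference-pool
recipe of such designs. Default regulons give each phase a distinct
signature: respiration (up through the aerobic diauxic shift, flat
anaerobically), ribosome (down toward stationary phase in both conditions),
storage carbohydrate and stress (up on glucose exhaustion), cell periphery
(up anaerobically in stationary phase), plus an MG deletion set (−5 log2,
effectively absent) and a small MG compensation set. In the noise-free
limit (`SimConfig.noise_free()`) peptide counts are also deterministic so
identification filters cannot drop proteins stochastically.

What the generator does **not** emulate: spectrum-level effects
(cofragmentation ratio compression, isotope impurities), correlated
co-regulation beyond the declared regulons, peptide-level quantification
variance, and retention-time/charge biases in detectability. Passing tests
therefore demonstrate the correctness of the numerical pipeline under the
declared generative model, not instrument-level fidelity; in particular real
TMT fold changes are compressed toward 1 by cofragmentation, which no
amount of bridge normalization repairs.

## Numerical choices and degenerate inputs

Zero or blank reporter intensities are missing values, never zeros, since a
zero reporter intensity is censoring. SDs use the n−1 denominator and are
absent at n = 1. BH adjustment enforces monotonicity and preserves input
order. Hypergeometric ties and volcano thresholds are strict inequalities
(p < 0.05, FC > 1.25). `welch_test` raises on n < 2 and on doubly-zero
variance rather than guessing. Evaluation runs in this repository use 250 to
10,000 synthetic proteins per check, sizes at which every statistical
property under test is already stable.

## Known limitations

* The per-plex identification filter can only evaluate replicate presence
  within one plex; the ≥2-biological-replicate quantification rule binds at
  the cross-plex contrast stage.
* Equal-total channel scaling is composition-sensitive by construction; it
  exists for raw exports and should stay off for autonormalized input.
* The pooled default test assumes equal group variances; switch to
  `test="welch"` for designs with heteroscedastic groups and n ≥ 5.
* emPAI is a coarse absolute-abundance estimate (roughly within 2–3-fold of
  true molar amounts in published benchmarks); mass-coverage figures inherit
  that coarseness.
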