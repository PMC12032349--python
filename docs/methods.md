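# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `seacycle`.

## Anomaly decomposition

Each feature series (z-scored proportion, environmental variable, trait
proportion, AGS) is fitted by OLS to

    y_t = mu + alpha_{month(t)} + beta_{year(t)} + e_t

with 12 monthly and one-per-observed-year categorical effects, no
interaction, under sum-to-zero (effects) coding — so an "anomaly" is a
deviation from the grand mean attributable to a calendar level, and the
effect vectors each sum to zero. Calendar levels come straight from the
sample dates (`month`, `year`); the simulator uses the same convention, so
generator and model share one calendar.

Variance is partitioned by sequential (Type-I) sums of squares with month
entered first: the seasonal signal dominates these series, and Type-I
attributes month/year-shared variance to the factor entered first. The
order is configurable (`ss_order`). Sequential SS telescope, so
SS_month + SS_year + SS_residual = SS_total holds exactly for balanced and
unbalanced designs alike; unbalanced sampling is handled by OLS on the
observed design with no imputation. A month or year with zero observations
is dropped from the design with a warning and its effect reported as NaN
(not estimable); the remaining effects still sum to zero.

Peak month/year is the argmax of the effect vector. When ordering many
features by peak, integer ties are broken by the circular phase of a
single-harmonic cosine fitted to the monthly effects. For presentation,
effect vectors are scaled by their maximum absolute value into [-1, 1]
(all-zero vectors pass through unscaled).

`env_variance_explained` is a redundancy-style statistic: each feature's
yearly-effect vector is regressed (OLS with intercept) on the
environmental yearly effects, and the pooled explained-SS fraction is
reported. This is one defensible reading of "interannual variation tied to
a linear combination of environmental drivers"; with k covariates and m
years the statistic inherits an expected overfit share of roughly k/(m-1)
on pure noise, which the acceptance construction removes by injecting
noise orthogonal to the covariate span.

## Normalization

Coverage is normalized to each sample's summed total (compositional
observation model: only relative abundance is informative). Features with
*mean* proportion below 5e-5 are excluded; the mean-across-samples
criterion (rather than per-sample) keeps one fixed feature set across the
series, which PCA/MCOA require. The comparison is inclusive: exactly 5e-5
is retained, below is excluded. Z-scores use the n-1 standard deviation;
zero-variance features are dropped with a warning.

`robust_loess` is a from-scratch implementation of Cleveland's robust
locally weighted regression: local linear fits over the span·n nearest
points with tri-cube distance weights, iterated (default 3 times) with
bisquare robustness weights delta = (1 - (r/6s)^2)^2 clipped to [0, 1],
s = median |r|. When the median residual collapses toward zero (a majority
of points fitted exactly — e.g. a constant series with one gross outlier)
the scale falls back to the mean absolute residual so the reweighting
stays defined and the outlier is still rejected; without the guard the
bisquare weights degenerate and the outlier passes through unsmoothed.
On non-degenerate inputs the implementation agrees with
statsmodels' lowess to ~1e-15 (asserted in tests). Default span 0.3.

## Consensus taxonomy

A contig's taxonomy is the lineage at the lowest rank to which at least
50 % of its ORFs is assigned, evaluated domain → species, stopping at the
first rank without a passing taxon. ORFs unclassified at a rank still
count in the denominator, so unclassified ORFs dilute support. "At least"
is read as >= 0.5; when two taxa both reach the threshold at a rank
(possible only at exactly 50 %), the taxon whose supporters agree with the
consensus at the parent rank wins, then higher support, then lexicographic
order — deterministic, and parent-consistency preserves the prefix
property (once unclassified, all lower ranks unclassified). Aggregation to
family tables weights by contig coverage, not ORF count; contigs resolved
only to a shallower rank accumulate under `<rank>:<name>_unresolved`, so
column sums conserve total coverage. Phylum attribution of a gene family
sums the coverage of carrier contigs into their consensus phyla and
normalizes to the across-phylum total.

## Ordination

PCA and MCOA share uniform row weights 1/n, i.e. eigenvalues are variances
with divisor n; variance fractions are divisor-invariant. MCOA finds per
axis one synthetic score vector v (normalized v'Dv = 1, D = I/n,
orthogonal across axes) maximizing sum_k w_k cov^2(X_k u_k, v) over
unit-norm per-table loadings u_k; this reduces to the symmetric
eigen-decomposition of sum_k w_k X_k X_k' / n, with u_k proportional to
X_k' D v. By default each table is first rescaled to total inertia 1
("equal-inertia" weighting) so the largest classification system (KO)
cannot dominate the compromise; `table_scaling="none"` uses the tables as
given, under which K=1 reduces exactly to PCA and duplicating a table
doubles every pseudo-eigenvalue (both asserted at 1e-8).

PERMANOVA Gower-centers the squared distance matrix, G = -1/2 J D^2 J, and
partitions trace(G) by nested projection (hat) matrices for the sequential
terms month → year → month×year, mirroring the anomaly convention.
Pseudo-F per term is (SS_t/df_t)/(SS_res/df_res); p-values permute raw
sample identities (rows/columns of G), the same permutation applied to all
factors, with p = (1 + #{F* >= F}) / (1 + n_perm). Permutation statistics
exactly tied with the observed F are counted as exceeding, with a 1e-10
relative tolerance absorbing round-off in the trace computations — without
it, exact ties drift below F under floating point and the test becomes
anti-conservative on discrete permutation distributions. If any
month×year cell is empty (an unbalanced multi-year series cannot fill all
cells) the interaction term is dropped with a warning. Euclidean distance
on z-scored tables is the intended input; the total SS then equals
(n-1) × n_features.

## Traits, keywords, genome size

A trait's per-sample value is the summed coverage of its member genes
divided by the *total annotated coverage* of the table (an all-annotated
denominator), so traits are proportions in [0, 1] and aggregation is
linear over disjoint gene sets and invariant to splitting a gene's
coverage across rows. The shipped Fe/N/P-stress (KO) and
carbon-degradation (Pfam) sets are a small default curation sufficient for
simulation and testing — editable YAML, not a claim of equivalence to any
published list. Spearman correlations use average ranks for ties; nitrate
enters interannual correlations negated (nitrate stress).

Keywords are lowercased alphabetic tokens of length >= 3 with a versioned
stop-word list removed, counted at most once per gene; a part-of-speech
filter (nouns/verbs) can be plugged in via the `pos_filter` hook, keeping
the deterministic path as the default so results do not depend on a tagger
model. Keyword series are sums of member-gene proportions (linear in the
table) and inherit the anomaly machinery; rankings sort by seasonal and by
annual variance fraction.

AGS = total assembled bases / N_genomes, with N_genomes the arithmetic
mean of the 139 single-copy marker counts (mean rather than median is a
configurable choice; tests pin the mean). Markers absent from an assembly
count as zero, inflating the coefficient of variation; CV >= 0.5 flags the
sample unreliable and no AGS is reported for it. The marker IDs shipped
are synthetic Pfam-style placeholders (PF9xxxx); the estimator consumes
whatever coverage-weighted marker counts it is given.

## Synthetic community generator

The generator defines the regime the analysis assumes, with known truth:

- **Calendar**: fortnightly sampling 2011–2021 by default (~287 samples;
  near-weekly is a config change), months/years as in the anomaly model.
- **Latent abundance**: log-linear,
  l_it = b_i + A_i cos(2π(month−φ_i)/12) + s_i·ENSO(year) + e_it, with
  AR(1) noise (default sd 0.5, ρ 0.9, reflecting the strong
  sample-to-sample autocorrelation of real series). Cosine seasonality is
  the simplest model with "peak month" semantics.
- **ENSO forcing**: an annual-mean ONI-like series for 2011–2021 (La Niña
  at both ends, a strong El Niño mid-series).
- **Guild structure** (`SimulationConfig.default`): half the taxa are
  winter/spring-peaking copiotrophs (genomes 3–6 Mbp, ENSO-negative,
  carrying Fe-stress and carbon-degradation genes), half summer/fall
  oligotrophs (1.2–2 Mbp, ENSO-positive, N/P-stress genes); every taxon
  carries the 139 markers once plus a shared housekeeping pool.
- **Observation model**: per-sample softmax to relative abundances;
  multinomial reads (10⁶ per sample), Dirichlet-multinomial when
  overdispersion > 0. Gene-family coverage is the sum of carrier-taxon
  coverage.
- **Environment**: temperature sinusoid (August peak) + ENSO + noise;
  nitrate/phosphate anti-phased with temperature; spring-bloom chlorophyll
  and POC; stoichiometric ratios around Redfield.

What the generator does **not** emulate: assembly artefacts and chimeric
contigs, annotation error beyond uniform ORF misassignment, taxon gain/
loss events, depth variation between samples, within-family genome-size
variance, or trait genes shared across guilds. Passing recovery tests
therefore demonstrates correctness of the analysis chain under the assumed
statistical regime, not robustness to those real-data failure modes. The
softmax coupling does produce one realistic distortion the tests account
for: a taxon's *proportion* peak can shift by about a month relative to
its latent peak when the community-wide denominator is itself seasonal.

## Problem sizes and determinism

Recovery checks run at 200 features × ~260 samples (anomaly), 500
simulations × 199 permutations at n=60, p=20 (PERMANOVA calibration),
1,000 contigs × 3 misassignment rates (taxonomy) and 10,000 random
directions (MCOA maximality) — sizes at which each property is sharply
testable on a single CPU in seconds. Every stochastic component takes an
explicit seed (`numpy.random.default_rng`); fixing the configuration seed
fixes all emitted tables bit-for-bit, and the pipeline is idempotent under
a fixed seed.

## Known limitations

- The sequential-SS convention makes the month/year partition
  order-dependent in unbalanced designs; the order is explicit and
  configurable, not hidden.
- MCOA table weighting (equal-inertia) is one of several defensible
  schemes; results for strongly heterogeneous table sets depend on it.
- `env_variance_explained` is a pooled OLS redundancy statistic with the
  overfit bias noted above; with ~11 years it should be read
  qualitatively.
- The consensus rule tallies taxon *names* per rank; homonymous taxa under
  different parents would be pooled at that rank (not an issue for
  GTDB-style unique names).
- Trait and marker gene sets are synthetic defaults; analyses of real
  tables should supply curated YAML definitions.
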