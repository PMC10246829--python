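# Methods

`evoparallel` quantifies how parallel the evolutionary response of
replicate populations is at two molecular levels — gene expression and
metabolite abundance — and tests whether the metabolome responds more
consistently than the transcriptome, as expected if molecular phenotypes
are organized hierarchically and gene-level responses are functionally
redundant.

## Study design

The assumed design is an experimental-evolution common-garden study:

* one ancestral population assayed with **5** replicate samples;
* **10** independently evolved populations with **3** replicate samples
  each for RNA-seq;
* a subset of **6** evolved populations (3 replicates each) assayed for
  metabolites.

Every per-population contrast is therefore 3 evolved vs 5 ancestral
replicates (8 samples).

## The generative model (synthetic data)

The generator embodies a hierarchical redundancy model. Each of the
`n_metabolites` metabolites owns a disjoint *module* of
`genes_per_module` (default 5) genes. For module *m* a shared log2
effect `s_m ~ N(0, shared_effect_sd^2)` is drawn once. In population
*p* each module gene *g* is independently *active* with probability
`redundancy_fraction`; an active gene's effect is
`delta_gp = s_m + u_gp` with `u_gp ~ N(0, specific_effect_sd^2)`, an
inactive gene's effect is 0. The metabolite's per-population effect is
the arithmetic mean of its module genes' effects (`sum` and `max` are
available as alternative aggregations; nothing in the analysis depends
on this choice qualitatively, and any quantitative gene-to-metabolite
map is a modeling choice — real pathway kinetics are nonlinear).

Averaging over partially overlapping active gene subsets is exactly the
redundancy mechanism: with `redundancy_fraction < 1` and
`specific_effect_sd > 0` different gene sets respond in each population
while the aggregated metabolite response stays similar, so the true
cross-population correlation of metabolite effects strictly exceeds that
of gene effects. This is verified by Monte-Carlo in the test suite.

Counts are negative binomial around library-scaled means
(`Var = mu + phi mu^2`, common `nb_dispersion` default 0.05, a typical
bulk RNA-seq biological dispersion for replicate pools); per-gene
baselines are log-uniform in log2-CPM on [-5, 9] so the 0.1-CPM
expression filter removes a nontrivial tail by construction. Library
sizes are lognormal around 1e6 with 10% CV. Metabolite values are
Gaussian on the natural-log scale: baseline uniform on [10.5, 14] (just
above the detection floor of 10), plus `ln(2) * effect` in evolved
samples, plus `N(0, met_noise_sd^2)` noise with `met_noise_sd = 0.1`
(~10% CV replicate noise, plausible for pooled fly samples after QC
normalization). The noise level matters: the exact 56-split permutation
test reports a floored minimum p of 1/57, so BH can only reject when a
substantial fraction of metabolites fully separate between groups;
at 0.1 noise roughly half do, giving significant sets comparable in
relative size to real untargeted metabolomics studies of this design.

**What the generator does not emulate:** batch effects, count
overdispersion heterogeneity across genes (a single common dispersion is
simulated), correlated noise between features, missing metabolite
values, annotation errors, or nonlinear pathway kinetics. Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under a clean hierarchical model, not robustness to every
artifact of real data.

## Differential expression (RNA)

Counts are CPM-normalized by total library size; genes with mean CPM
across all samples >= `cpm_filter` (default 0.1) are kept (`min`-mode
filtering is available; the low-threshold mean filter is the common
idiom). Each evolved population is contrasted against the ancestral
replicates with a log-link negative-binomial GLM with log-library-size
offset, `log mu = beta0 + beta1 * evolved`. With a fixed dispersion the
MLE decouples into one rate per group, solved by vectorized Fisher
scoring (step tolerance 1e-8, max 50 iterations; all-zero groups are
pinned at a log-rate floor). A common dispersion per contrast is
estimated by maximizing the Cox–Reid adjusted profile likelihood over a
log-spaced grid (16 coarse + 9 refined points on [1e-4, 10]); the CR
adjustment counters the downward bias of plain profile ML at 8 samples.
The evolution effect is tested by the likelihood ratio against the
intercept-only model (chi-square, 1 df), with BH adjustment per
population. Non-converged genes get missing p and are excluded from
adjustment. The engine agrees with `statsmodels` NB GLM at fixed
dispersion to ~1e-5 relative (test-pinned) and its type-I error on null
simulations is calibrated (fraction of raw p < 0.05 within [0.03, 0.07]
at 2,000 genes).

log2 fold change is `log2((mean_evo + c) / (mean_anc + c))` on the CPM
scale with pseudocount `c = 0.5` CPM (c = 0 recovers the plain ratio of
means and can be undefined at zero means).

## Differential abundance (metabolites)

Metabolite matrices are log-scale (raw areas are natural-log
transformed first; non-positive areas cannot be transformed and are
excluded). A metabolite is *detected* when its log value strictly
exceeds the floor (default 10) in every sample. Per metabolite and
population the test statistic is the difference in group means; the
p-value is the proportion of group reassignments (5 ancestral / 3
evolved) whose absolute difference strictly exceeds the observed one.
Only C(8,3) = 56 distinct reassignments exist, so exhaustive enumeration
(an exact test) is the default; a random-sampling mode with configurable
`n_permutations_met_test` reproduces the sampled variant and converges
to the exact p (test-pinned at n = 10^4). Strict exceedance can yield
p = 0 for the extreme split; reported p is floored at
1/(n_assignments + 1) = 1/57 (1/(B+1) in random mode) so BH never
receives an exact zero. Zero-variance rows get p = 1 by convention.
For metabolites the log2FC is the difference of group means on the log2
scale, i.e. the log2 ratio of geometric means.

## Parallelism statistics

For every unordered pair of evolved populations:

* **Jaccard index** `|A ∩ B| / |A ∪ B|` of the two significant-feature
  sets (0 for two empty sets, with a warning);
* **Pearson correlation** of the full log2FC vectors over the shared
  tested universe (missing values dropped pairwise; constant vectors
  yield a missing correlation).

10 populations give 45 pairs, 6 give 15.

## Heterogeneity permutation null

The null of *no population-specific effects* is built by permuting, for
each feature independently, the evolved-sample values across all evolved
sample slots (30 RNA samples, 18 metabolite samples), leaving ancestral
columns fixed; per-population calls and the pairwise statistics are then
rebuilt from scratch, and the mean over pairs recorded. 100 permutations
by default. The test is one-sided: p is the proportion of permuted means
*strictly below* the observed mean (ties count as not smaller); an
add-one variant (k+1)/(B+1) is reported alongside.

Two numerical points. First, for the correlation statistic the shuffle
operates on normalized values (CPM, or log areas): library size is a
property of the sample, and shuffling raw counts across samples of
different depths would add spurious noise to the null. With this choice
the null is exchangeable and the p-value is calibrated (40-simulation
check in the acceptance tests). For the Jaccard statistic the DE refit
needs integer counts with sample-attached offsets, so counts are
shuffled there; at 10% library-size CV the residual mismatch is mild and
conservative. Second, per-feature shuffling destroys within-sample
correlation between features — a deliberately liberal null; a
whole-column (`mode="columns"`) variant that preserves it is provided.

## Cross-level comparison

Only populations assayed at both levels enter (6 by design, 15 pairs).
Feature numbers are equalized by downsampling: the expressed-gene log2FC
universe is subsampled without replacement to the detected-metabolite
count for the correlation statistic, and each population's significant
gene set to its significant-metabolite count for the Jaccard statistic
(targets are clamped with a warning if a population has fewer
significant genes). Each statistic is averaged per pair over 100
downsampling repetitions, and the two 15-pair distributions are compared
with Welch's t-test (Student's pooled test optional; the sign of t
follows metabolite − gene). The 15 pairs from 6 populations are not
truly independent observations; the t-test treats them as such, which is
the conventional reading, and the per-pair tables are emitted so users
can apply any alternative. An exhaustive-enumeration mode of the
downsampled Jaccard expectation exists for small sets and anchors the
Monte-Carlo estimator in tests.

## Joint pathway analysis

Per population, pathway, and omic, association between the pathway's
member features and the ancestral/evolved grouping is scored with the
global-test quadratic form `Q = y_c' X X' y_c / (m y_c' y_c)` (centered
group indicator `y_c`, column-standardized member matrix `X`, constant
columns dropped). Significance comes from permuting the group labels
(default 1,000 relabelings, add-one p, so the floor is 1/1001); one
relabeling block is drawn per population and omic and shared across
pathways, which keeps the scan fast and the pathway comparison
consistent. Pathways need >= 2 present gene members; single-metabolite
pathways are tested as the univariate limit of the same score (the
synthetic annotation maps each pathway to exactly one metabolite).
The omic p-values are integrated with Fisher's method,
`S = -2 Σ ln p ~ chi-square(2k)`; with one omic present this is the
identity on p. BH adjustment runs across pathways within each
population; the shared-pathways summary lists pathways significant in
every population with their mean adjusted p.

## Reproducibility and problem sizes

A single master seed drives everything: per-stage generators are derived
through `SeedSequence` spawn keys, so identical config + seed yields
byte-identical output files (TSV numbers at 6 significant digits, JSON
at full precision) and stages can be re-run in isolation. Default
problem sizes (2,000 genes, 200 metabolites, 100 permutations
throughout) run the full pipeline in about three minutes on one CPU;
tests use smaller draws of the same design.

## Known limitations

* The common-dispersion NB model is a deliberate simplification of
  empirical-Bayes tagwise dispersion estimation; genes with atypical
  dispersion are respectively over/under-called.
* The exact metabolite test's p floor (1/57) makes BH rejection
  impossible unless a large fraction of metabolites is extreme; this is
  an honest property of exact tests at n = 8 combined with FDR control.
* The per-feature permutation null ignores inter-feature correlation.
* Pathway membership is taken at face value; overlapping pathways are
  tested marginally, not jointly.
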