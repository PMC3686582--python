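# Methods

This note records the modeling and numerical choices behind `snpselect`, in
the order the pipelines run.

## Data model and conventions

Genotypes are coded additively as the count of alternate alleles (0/1/2).
Labels are +1 for cases and −1 for controls, which fixes the sign convention
of the SVM weight vector: a positive wⱼ means more alternate alleles push the
decision toward "case". Missing genotypes are imputed per SNP with the column
mean before SVM or projection steps (which need numeric completeness) and
with the column mode for MDR (which needs categories); no other imputation is
attempted. The stratified split draws ⌊fraction·class_count⌋ subjects of each
class into training, uniformly at random from a seeded generator; with a 0.5
fraction and even class sizes this is an exact half/half split, and odd
classes put the extra subject in the test set.

## Synthetic cohorts

The generator emulates a candidate-gene panel: a few hundred to a thousand
subjects typed at ~10²–10³ biallelic SNPs. Each SNP draws a minor allele
frequency uniformly from `maf_range` (default 0.05–0.5) and genotypes from
Hardy–Weinberg proportions ((1−q)², 2q(1−q), q²), independently across SNPs.
Disease risk follows a logistic liability:

  logit P(case) = logit(π₀) + Σⱼ log(ORⱼ)·gⱼ + Σ_pairs [logit(pen[g_a][g_b]) − logit(π₀)]

with baseline prevalence π₀ = 0.5 by default (a balanced case/control design,
not a population prevalence). Writing the epistatic term as a deviation from
baseline makes pure-epistasis configurations (all OR = 1) reduce exactly to
the penetrance table, so a planted XOR pattern — elevated risk iff exactly
one of two loci is heterozygous — has no marginal signal when the pair's MAF
is 0.5. Case/control quotas are filled by rejection sampling, capped at
1000× the cohort size so impossible configurations fail fast rather than
hang. An optional block-LD knob (adjacent SNPs copy their neighbour, re-drawn
with a flip probability) exists solely to exercise the correlation filter;
the generator otherwise has no linkage disequilibrium, population structure,
genotyping error, or missingness, so passing tests demonstrate method
correctness under idealized sampling, not robustness to real-cohort
artifacts.

Simulation-study settings used by the statistical tests and the acceptance
script, chosen once as representative of the regime the methods target:
main-effect studies use 5 causal SNPs with OR = 3 and causal-range MAF
0.2–0.5 (common variants, where a per-allele OR of 3 is a strong but
realistic candidate-gene effect), n = 600 subjects, d = 200 SNPs; epistasis
studies use an XOR penetrance of 0.8/0.2 at MAF 0.5 with n = 800, d = 20,
which makes the interaction strong in the joint table and absent marginally;
null calibration uses 1000 subjects × 2000 SNPs. Rates are estimated over 25
simulation seeds (JL unbiasedness over 2000 projection seeds).

## SVM and the GCI selection pass

The margin problem is solved in its soft-margin form with C = 1.0 by
default: genotype classes always overlap, and the hard-margin program is
infeasible on overlapping data. The solver is scikit-learn's libsvm backend;
this package owns the kernel parametrization — polynomial (xₐ·x_b + 1)ᵖ maps
to gamma = 1, coef0 = 1; RBF σ maps to gamma = 1/(2σ²) — and everything
downstream of the fit.

Feature weight for ranking is |wⱼ| under the linear kernel. Non-linear
kernels have no explicit w, so the linearized pre-image weight
|Σᵢ αᵢyᵢxᵢⱼ| (the weight the same dual coefficients would give a linear
kernel) is used; this is one defensible reading among several, and feature
ranks under RBF/sigmoid should be interpreted accordingly. The weight sort is
stable with original column order breaking ties.

The greedy correlation pass compares each candidate only to the most
recently picked feature (threshold on |Pearson r|, default 0.8; absolute
value because negative correlation is still redundancy). Comparing against
all picked features is available via `compare_all_picked=True`; the default
follows the sequential description of the scan. Constant columns are defined
to correlate 0 with everything, with a warning, rather than propagate NaNs.
After GCI reordering, the pipeline retrains the SVM on the selected top-m
columns before reporting test accuracy, so the reported number reflects the
model actually deployed on the subset.

## Projection stage

`jl_min_dimension` returns the smallest integer strictly above
k₀ = (4 + 2β)·ln n / (ε²/2 − ε³/3). The success probability of the distance
band is 1 − n^(−β); β > 0 shrinks the failure mass polynomially. Both
projection laws have mean 0 and variance 1 per entry, making
E‖f(u) − f(v)‖² = ‖u − v‖² exactly; the sparse law touches only a third of
the entries, which is what makes it database-friendly.

PCA components fix their sign by making each component's largest-magnitude
loading positive, so repeated fits are bit-identical. Scores are computed on
column-centered data with the training-set means.

In the projection pipeline, min-max normalization (default target [0, 1])
and equal-width discretization (default 3 bins, mimicking the 3-level
genotype coding the downstream selection pass was designed for) are applied
to both the RP and PCA branches by default (`normalize_discretize=False`
disables). Column statistics are always computed on the training portion and
re-applied to test data; test values outside the training range extrapolate
under normalization and clip to the extreme bins under discretization.
Binning is half-open [lo, hi) with a closed last interval; ties at an
interior edge go to the upper bin; a constant column maps to the target
minimum / bin 0 with a warning.

## MDR

Cells are labeled high-risk when cases/controls ≥ threshold (default 1.0,
appropriate for balanced designs; a cell with cases and no controls has
infinite ratio and is high-risk). Genotype combinations never seen in
training predict control — deterministic and conservative. Within each of
the 10 stratified folds, the candidate with the fewest misclassified
training subjects wins, ties broken by lexicographic locus order; the
overall winner is the candidate chosen in the most folds, ties broken by
higher mean testing accuracy. Both the mean accuracy over the winning folds
and over all folds are reported, since either convention appears in
practice. Random search is budgeted by a count of distinct evaluated
combinations rather than wall-clock time, which is the reproducible analogue
of a timed search; exhaustive search refuses above 10⁶ combinations and
points to the random method. If a fold partition leaves a training part with
one class, the partition is re-drawn once before erroring.

## Association module

The chi-square test uses the 2 × g contingency table of label × observed
genotype classes, df = g − 1, no continuity correction. Genotype classes
with expected count < 1 are merged into their neighbour first (disable with
`merge_small=False`). The logistic alternative enters genotype as
categorical dummies so its likelihood-ratio test has the same df and is
asymptotically equivalent to the chi-square; it exists because a
regression-based test generalizes to covariates (out of scope here). SNPs
with a single observed genotype class record p = 1 with a warning. Raw
p-values are reported (a Bonferroni column is included for information
only). The random-pick baseline uses the independent-draws form
1 − (1 − t/N)^m by default; the exact hypergeometric variant
1 − C(N−t, m)/C(N, m) is available with `exact=True` (at the
N=1212, m=32, t=3 scale they differ only at the second decimal: 7.6% vs
7.7%).

## Determinism and leakage

Every stochastic step takes an explicit seed; there is no global RNG state.
Pipeline reports embed the seed and a hash of the config, and identical
configs produce identical tables. Each pipeline stage appends an audit
record stating whether it touched test labels; `assert_no_leakage` verifies
only evaluation (and MDR's internal cross-validation) ever does.

## Known limitations

- No LD-aware simulation, covariates, or population stratification control;
  results on real cohorts with structure will be optimistic.
- The non-linear feature weight is a linearization; RBF/sigmoid rankings are
  heuristic.
- MDR significance is reported via CV consistency and testing accuracy only;
  permutation-based significance testing is not implemented.
- The chi-square small-cell guard (merge at expected < 1) is a coarse rule;
  exact tests are not provided.
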