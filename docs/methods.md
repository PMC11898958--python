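# Methods

## Scope and data model

The package analyses small-molecule datasets characterised on three
biomimetic chromatographic systems. Each compound carries four
endpoints: CHI_C18 (lipophilicity index on a C18 phase, roughly
0–110), CHI_IAM (phospholipid-affinity index on an immobilised
artificial membrane), LogK_HSA (log albumin affinity) and %HSA
(percent bound to human serum albumin, in (0, 100)). A packaged
18-compound organophosphate table provides the reference dataset;
molecular descriptors enter as plain numeric compound × descriptor
tables computed by external software and are never computed here.

## Index transforms

Calibration maps gradient retention time to an index scale by ordinary
least squares over reference standards (≥ 2 standards with distinct
times required; the fit's r² is reported so a poor calibration is
visible). The two albumin-binding scales are linked by

    LogK_HSA = log10( %HSA / (101 − %HSA) ),

with inverse `%HSA = 101·10^k / (1 + 10^k)`. The 101 denominator is
reverse-engineered: it is the only affine-log candidate that reproduces
every LogK_HSA/%HSA pair of the packaged table at its printed
two-decimal precision, and the test suite asserts exactly that for all
18 compounds. Displayed values are rounded half-up to two decimals,
matching the table convention.

## Descriptor pruning and scaling

Pruning removes, in order: constant columns; nearly constant columns
(most frequent value occupying > 95% of entries, or sample sd below
1e−8 of the value magnitude — descriptor software emits both
pathologies); then one member of every pair with |Pearson r| ≥ 0.95,
scanning pairs in column order and keeping the earlier column
(configurable to keep the higher-variance member). The absolute value
is used so strong negative correlation also triggers. The report
accounts for every removal, and pruning is deterministic given column
order. Auto-scaling standardises each column to mean 0 and unit sample
sd (ddof = 1) and refuses constant columns rather than silently
dividing by zero.

## GA-MLR subset selection

Candidate models are binary inclusion masks over the descriptor
columns. The default configuration fixes the subset size at two
descriptors (the size of all reference models); a repair step after
crossover and mutation randomly adds/removes genes to restore the
size. Operators: tournament selection of size 2, uniform crossover,
independent per-gene mutation at rate 0.20, elitism of 1, population
10, 500 generations. All randomness flows through a single seeded
`numpy` generator; the seed and a configuration hash are recorded on
the fitted model, and two runs with the same seed are bit-identical.

Fitness defaults to Q²_LOO of the candidate OLS model rather than
training R²: on n ≈ 12–18 compounds every 2-descriptor model fits
respectably, and leave-one-out scoring is what separates robust
subsets from overfit ones. Training-R² fitness is available via
configuration. Fitness values are memoised by mask — a pure-function
cache that changes nothing but run time. Singular candidate designs
score −∞ and are never selected.

OLS itself is solved by `numpy.linalg.lstsq` on the
intercept-augmented design after an explicit rank check; fits with
n ≤ p + 1 are refused. The test suite verifies coefficients against an
independent normal-equations oracle and against `statsmodels`.

## Validation

The systematic ("ranked") split sorts compounds by the endpoint and
assigns every third compound (2nd, 5th, 8th, … in sorted order) to the
validation set, leaving the endpoint extremes in training — with 18
compounds this gives the 12/6 split used throughout. A seeded random
split is available.

Metrics: R² and RMSE on the training fit; Q²_LOO and RMSE_LOO by
leave-one-out cross-validation; R²_EXT, RMSE_P and Lin's concordance
CCC_EXT on the external set. R² uses the observed values' own mean in
the denominator; for the external statistic this means the external-set
mean by default, with the training-mean variant available (the
Q²_F1/F2-style choice). LOO predictions use the exact OLS identity
e_loo = e/(1 − h) from the hat-matrix diagonal rather than n refits;
tests compare against a brute-force refit oracle. CCC is implemented
in Lin's standard form, bounded in [−1, 1], penalising both scatter
and location shift.

Acceptability follows the Tropsha thresholds R² > 0.6 and
R²_EXT > 0.5 (strict inequalities).

## Applicability domain

Leverage is h = x'(X'X)⁻¹x on the intercept-augmented training design;
training self-leverages are the hat diagonal and sum to p + 1. The
critical leverage is h\* = 3p/(n − 1) with p the number of model
descriptors (intercept not counted) and n the training size — for a
two-descriptor model trained on 12 compounds, h\* = 6/11. Standardized
residuals divide each residual by the RMSE of the compound's own set
(training or external), the common Williams-plot convention since no
single definition is universal. A compound is in-domain when h ≤ h\*
and |standardized residual| ≤ 3, both boundaries inclusive.

## Exploration

Correlation matrices are Pearson over chosen endpoint columns.
Clustering defaults to Ward linkage on Euclidean distances over the
auto-scaled CHI_C18, CHI_IAM and LogK_HSA columns; %HSA is excluded by
default because it is a deterministic transform of LogK_HSA and would
double-weight albumin binding. Flat groups come from either a fixed-k
cut or a "gap" cut at the largest jump between successive merge
heights. A three-group cut is named low/medium/high bioaccumulation
potential by ranking cluster means of CHI_C18. The exact linkage and
column set behind any particular published dendrogram are rarely
stated, so group recovery on measured data is treated as a qualitative
check; on synthetic blob data with ≥ 5× between/within separation the
gap rule recovers the planted group count in ≥ 95% of seeds.

## Synthetic data

`generate_descriptors` draws base columns i.i.d. standard normal;
optional correlated blocks of 5 columns share a latent factor
(X = √ρ·F + √(1−ρ)·E), the simplest structure with a controllable
within-block correlation ρ; near-duplicate columns are a base column
plus N(0, 0.01) noise, guaranteeing r > 0.99 so the pruner must catch
them. `generate_response` plants a linear signal on a random subset of
non-duplicate columns with coefficient magnitudes ~uniform(0.8, 1.2) ×
effect scale and random signs, plus Gaussian noise of stated absolute
sd; the convention used throughout the tests is noise sd = 10% of the
noise-free signal sd. `generate_endpoint_table` draws correlated
Gaussian latents, squashes them through a logistic to realistic index
ranges (CHI_C18 ∈ [20, 110], CHI_IAM ∈ [15, 45], LogK_HSA ∈
[−0.5, 1.3]) and computes %HSA exactly from LogK_HSA via the package
transform, mirroring the structure of the measured table.

What the generators do *not* emulate: heavy-tailed or discrete
descriptor distributions, measurement error on the endpoints,
retention-time drift, or any chemistry — a passing pipeline test shows
the statistics behave as designed, not that a particular real compound
set will yield a good model.

## Problem sizes and test design

The headline pipeline checks run at the study's natural scale — 18
compounds, 20–50 descriptors, 12/6 splits, 10 seeds — which keeps every
test below a minute on one CPU. The GA-versus-exhaustive comparison
uses C(20,2) = 190 candidate pairs so the global optimum is enumerable.
The ±3σ residual-coverage check uses 10⁴ simulated points with a
four-standard-error binomial tolerance.

## Known limitations

- Reference CHI values for calibration standards are user-supplied;
  the package deliberately does not embed literature calibration
  tables.
- The reference models' own descriptor values are not distributed, so
  their training statistics cannot be recomputed here; they are stored
  as printed metadata and used only for threshold and prediction
  arithmetic.
- The GA is single-objective and the regression strictly linear OLS;
  no regularisation, nonlinear terms or multi-objective search.
- The %HSA link function is inferred from data consistency, not from a
  stated instrument formula; values outside the packaged table's range
  rely on its extrapolation.
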