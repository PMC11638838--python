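# Methods

This note documents the statistical models, the numerical choices behind the
REML engine, the combining-ability procedures, and what the synthetic trial
generator does and does not emulate.

## Trial structure and trait derivation

A plot table holds one row per field plot with design identifiers
(environment, management regime, replicate, incomplete block, entry) and
trait values.  Testcross entries carry a line and a tester id; commercial
check hybrids carry neither.  Grain yield converts harvested field weight
(kg of dehusked ears per plot) to t/ha:

    GY = FW x shelling x (100 - MOI) / (100 - MOI_std) x 10 / area

with defaults shelling = 0.80, MOI_std = 12.5%, and area = rows x length x
row spacing = 2 x 5 m x 0.75 m = 7.5 m2.  The formula is assembled from the
stated ingredients (shelling percentage, standard moisture, plot geometry);
it is the only composition consistent with those inputs and the t/ha unit.
Field weight is taken to be measured on the full two-row plot (no border
removal is modelled).  ASI = SD − AD may be negative.  Missing cells are
preserved and handled listwise per analysis; nothing is imputed.

## Crossing plan and estimability

Lines and testers belong to two heterotic groups and every cross pairs
opposite groups, so the line–tester graph splits into at most two
sub-designs (A-lines x B-testers, B-lines x A-testers) that share no
parents.  GCA contrasts are jointly estimable only within a connected
sub-design, so internal connectivity of each sub-design is a hard validity
requirement of a plan.  When more opposite-group testers are available than
each line uses, assignment is deterministic by sorted tester label so a plan
is reproducible from the line/tester list alone.

## REML engine

All models have the form y = Xb + sum_k Z_k u_k + e with u_k ~ N(0, s2_k I)
and e ~ N(0, s2_e I).  Estimation maximises the restricted likelihood via
the mixed model equations (MME), using the identity
log|V| + log|X'V^-1 X| = log|R| + log|G| + log|C| so the likelihood,
effects, and all trace terms come from one factorisation of the MME
coefficient matrix C.

* **Updates.** Two EM steps from a deterministic start (the phenotypic
  variance split equally over all components), then average-information
  (Newton) steps with step-halving and an EM fallback whenever a step would
  decrease the likelihood.  Components on the zero boundary with negative
  score are held out of the Newton system that iteration (an active-set /
  projected step, the KKT condition for a boundary optimum).
* **Boundary.** Negative updates are projected to a floor of 1e-8 x var(y);
  floored components are reported as exactly 0.  Likelihoods remain finite
  and comparable across nested models at the boundary because the log|G|
  and log|C| contributions of a vanishing component cancel.
* **Convergence.** Relative log-likelihood change < 1e-8 and component
  changes < 1e-6 (relative to the phenotypic variance); maximum 500
  iterations, failure raises with the iteration trace.  Everything is
  deterministic for fixed input; estimates are invariant to row order and
  level relabelling because factors are sorted categoricals.
* **Factorisation strategy.** Dense Cholesky below 700 equations.  Above
  that, the largest random factor is absorbed by a Schur complement — its
  Z'Z block is diagonal since each plot carries exactly one level of every
  factor — leaving a dense system over the remaining equations; the
  absorbed block's inverse diagonal (needed for scores and EM traces) is
  recovered from sparse quadratic forms against the Schur inverse.  A
  sparse-LU path remains as fallback for very large remainders.  At the
  reference scale (795 testcrosses x 3 environments x 2 replicates; MME
  dimension ~4,400) a seven-component fit takes a few seconds on one core.
* **Fixed effects.** Design columns are full indicators per term plus an
  intercept, pruned to a full-rank set by pivoted Cholesky of X'X, which
  resolves the intentional aliasing of nested terms (rep within env) and
  makes estimable functions explicit.

Model wrappers: the combined genotype model (env and rep-within-env fixed;
block, genotype, genotype x env random), the within-environment
line-by-tester model, and the across-environment line-by-tester model with
all three environment interactions.  Single-environment inputs degrade
gracefully: environment terms are dropped with a warning.

Variance components are tested by likelihood-ratio against the model
without the term, referred to the 50:50 mixture of a point mass at zero and
chi-square(1) — the boundary correction for a variance under the null.
Calibration was checked by simulation (empirical size ~0.05-0.06 at nominal
0.05 over 1000 one-way nulls with 100 genotypes x 3 replicates).

## Entry means and two-stage combining ability

Entry BLUEs come from refitting the genotype model with entries fixed; each
entry's BLUE is the average of its fitted fixed-effect values, so all means
share one environmental baseline.  The reported SED is the average standard
error of a difference between two entry means from the full covariance of
the fixed effects.

GCA/SCA estimation is two-stage, operating on testcross BLUEs (checks
excluded): means are decomposed as

    m(i, j) = mu_c + g_i + g_j + s_ij

by least squares with explicit constraint rows.  Because the two heterotic
sub-designs share no parents, the system carries one intercept per
connected component and sum-to-zero constraints on line and tester effects
within each component; for a single connected design this reduces to the
textbook one-mean system.  SCA effects are the fit residuals and therefore
sum to zero over every line's and every tester's realized crosses.
Standard errors come from the constrained-solution covariance scaled by the
stage-1 sampling variance of an entry mean; t tests use the stage-1
residual degrees of freedom.  A cross whose line (or tester) has only one
realized cross is flagged non-estimable for SCA.  Significance stars are
*/**/*** at 0.05/0.01/0.001 throughout.

Baker's ratio is 2(s2_GCA_line + s2_GCA_tester) / (2(sum) + s2_SCA): the
line + tester composition is adopted because it reproduces the printed
reference ratios (e.g. silking date 0.99 from 6.18 + 0.06 vs 0.09), where a
single-parent composition does not.  Proportional contributions divide the
three genetic components by their sum (x100).

Broad-sense heritability takes e and r as explicit user inputs rather than
deriving them from the data, because the effective environment count of a
combined analysis need not equal the number of locations listed (unbalanced
coverage, discarded site-trait combinations); the reference drought values
are reproduced with e = 3, r = 2.

## Leave-one-hybrid-out prediction

Each hybrid is predicted as mu_c + g_line + g_tester (no SCA term — the
point is to measure what GCA alone achieves).  For each fold the
decomposition is re-estimated without that hybrid via a rank-one
Sherman–Morrison downdate of the constrained normal equations, which is
algebraically identical to a full refit (verified against a brute-force
refit oracle to 1e-8) and makes 795 folds essentially free.  Hybrids whose
edge is a bridge of the line–tester graph are skipped with a warning: their
removal disconnects a parent, leaving its GCA inestimable.  Variance
components are not re-estimated per fold; only effects are.

A useful planning identity: with entry means averaged over e environments
and r replicates, the achievable r(GCA, TCP) is bounded by roughly
sqrt(s2_GCA / (s2_GCA + s2_noise)) with s2_noise = s2_GxE-terms/e +
(s2_block + s2_e)/(e r).  Under the drought preset this bound is ~0.95 for
anthesis date (GCA 5.31 vs residual 1.99) but only ~0.81 for grain yield
(GCA 0.36 vs residual 1.01) — simulated LOO values are ~0.95 and ~0.73.
Real-data prediction correlations for yield above this bound imply an
effective error smaller than the printed plot-level components, so the
simulation checks assert the property on the flowering traits where the
regime is unambiguously GCA-dominant.

## Trait correlations

Pearson r on entry means (one value per hybrid per trait per regime), with
pairwise-complete missing handling, two-sided t-test p values, and the same
star convention.  Across-regime mode suffixes traits `_DS`/`_OPT` and joins
on entry.  Constant traits yield undefined (missing) correlations.

## Synthetic trial generator

The generator draws every random effect independently from a zero-mean
normal at the configured variance and sums them exactly as the analysis
models assume — it is the generative counterpart of the across-environment
line-by-tester model, which makes parameter-recovery tests meaningful and
sharp.  Defaults reproduce the reference study conditions: 93 + 172 lines,
3 + 3 single-cross testers, 3 testers per line (795 testcrosses), 6 checks,
3 drought or 4 optimum environments, 2 replicates, resolvable incomplete
blocks of 25 plots re-randomised per replicate.  The `drought` and
`optimum` presets store the printed per-trait variance components of both
the combined genotype analysis and the line-by-tester partition, plus the
trial grand means (e.g. drought GY 2.15 t/ha, optimum 7.39 t/ha).

Choices where the reference conditions are silent:

* **Block structure.** No block variance or block size is published; blocks
  default to 25 plots with variance 5% of the trait residual.  Both are
  config fields.
* **Environment and replicate shifts** are drawn at 1.0x and 0.05x the
  residual variance respectively; they are fixed effects in every model, so
  their magnitude does not affect component recovery.
* **Flowering identity.** AD and ASI are simulated from their own variance
  regimes and SD is derived as AD + ASI, so the anthesis–silking identity
  holds in every plot and ASI keeps its printed components exactly; SD's
  own preset is used only when SD is simulated directly.  One member of the
  triple must be derived in any generator that respects the identity.
* **Stress syndrome.** Line-level GY and ASI effects share a latent
  standard normal with mixing weight -0.5 under drought (-0.3 optimum), so
  drought data show the expected negative GY–ASI dependence with a positive
  mean ASI (2.78 d).  The weight is configurable; it induces a line-level
  correlation equal to the coefficient, without changing either trait's
  marginal variances.
* **Checks** receive an own genotypic effect with variance equal to the
  total testcross genetic variance, so including them in the genotype model
  is harmless and realistic.

What passing recovery tests do **not** show about real data: the generator
has homoscedastic, normal, independent effects; no spatial trend beyond the
block effect, no heterogeneous error across environments, no
genotype-specific stress-response curves, and its missing-data pattern is
complete.  Agreement on synthetic data validates the estimators under the
models' own assumptions, not those assumptions themselves.

## Reported tables and reproducibility

The report module chains the stages (checks retained in genotype-model
fits, excluded from line-by-tester stages), computes CV% = 100 x
sqrt(s2_e)/grand mean, and serialises rounded tables only at output;
internally everything is full precision.  Identical inputs give
byte-identical reports; all simulation randomness descends from a single
integer seed through named substreams.

Problem sizes used by the verification suite: worked-example statistics are
exact recomputations from printed components; estimator oracles run on
small balanced layouts (15-20 genotypes); parameter-recovery runs use the
full 795-testcross drought design with 20-30 seeds (medians of REML
components are compared at ±15%, where the tiny line x env component,
0.02 against a residual of 1.01, sits near its boundary-truncation limit);
LRT calibration uses 1000 one-way nulls.
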