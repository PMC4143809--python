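# Methods

## Hypertension states

Each examination is mapped to one of three states from systolic/diastolic
blood pressure (mm Hg) and the antihypertensive-medication flag:

| state | definition |
|---|---|
| 1 (normotensive) | SBP < 120 and DBP < 80 |
| 2 (prehypertensive) | not state 1, SBP < 140 and DBP < 90 |
| 3 (hypertensive) | everything else, or medication use |

Thresholds are strict inequalities: a reading of exactly 120/80 or 140/90
falls in the higher state. Medication forces state 3 regardless of the
recorded pressures because treated readings do not reflect the untreated
phenotype; each exam is classified independently (medication at one exam
does not propagate to later exams). An exam missing any clinical variable
(SBP, DBP, medication flag, sex, smoking, age) is excluded — including a
missing medication flag, which we treat as missing data rather than as "no
medication". Subjects keep their remaining exams; a subject with a single
retained exam contributes no transitions but still receives a response
(only the conditioning state and covariates are needed).

## Transition model and response

Transitions between consecutive retained exams are modelled per previous
state *l* with a baseline-category multinomial (generalized logit),
log(y_lj/y_ll) = z'γ_lj for j ≠ l, where z holds an intercept, sex, smoking
status and age **at the earlier exam of the pair**. Examination time can
enter as a categorical factor (treatment coding, first observed exam as
reference) either as a main effect or as an age-by-time interaction. By
default the package selects, per previous state, among {no time term,
+time, +age×time} by likelihood-ratio test at α = 0.05 against the base
model, keeping the candidate with the smaller p-value when both reject.
With selection disabled the shapes default to: age×time out of state 1,
time main effect out of state 2, no time term out of state 3.

Fitting is maximum likelihood: L-BFGS-B with analytic gradient followed by
Newton polishing (analytic Hessian) to a projected-gradient norm below
1e-8. Coefficients are capped at |γ| ≤ 30 so that a transition category
with zero observed counts yields a finite fit whose corresponding
probability underflows smoothly instead of diverging; the cap keeps every
TPM entry strictly inside (0, 1). Coefficient covariances are the inverse
observed information.

The per-subject 3×3 transition probability matrix evaluates all three
fitted models at one covariate vector. The response is the TPM row indexed
by the subject's **last observed state**, with covariates from the last
retained exam. Because the time factor is fitted on the earlier exam of
each transition pair, a subject's final exam index usually exceeds the
largest fitted level; the response evaluation therefore clamps the exam
index into the fitted range (the last fitted level). Direct TPM evaluation
at an unseen time level raises an error naming the level.

## Dirichlet regression and the Wald scan

Responses y_i live on the open 3-simplex and are modelled as Dirichlet with
all three concentrations free (the "common" parametrization, no reference
component) and a log link: log λ_ij = s_i'β_j. Model M1 uses intercept +
minor-allele dosage; M2 adds pedigree as a fixed categorical via treatment
contrasts with the largest family as reference. Families smaller than a
configurable minimum (default 2) are pooled into the reference level to
avoid rank deficiency. With a single (effective) family the contrast matrix
has zero columns and M2 reproduces M1 exactly.

The log-likelihood, analytic gradient (digamma terms) and analytic Hessian
(trigamma terms) are coded directly; fitting is Newton with Armijo line
search, warm-started in the scan from the no-dosage null fit, with an
L-BFGS-B fallback if a Newton direction fails. The coefficient covariance
is the inverse observed information at the optimum. The SNP test is the
joint 3-df Wald statistic W = β̂'V̂⁻¹β̂ over the three per-component dosage
coefficients. The scan drops subjects with missing dosage marker-by-marker,
flags non-converged fits (p set to NaN) rather than imputing, and marks
markers below a configurable genome-wide threshold (default 5 × 10⁻⁸).

Responses produced by the transition stage are strictly interior to the
simplex. User-supplied responses touching the boundary (within 1e-10 of 0
or 1) are compressed toward the barycenter by y′ = (y(n−1) + 1/3)/n, the
standard transformation for Dirichlet-distributed outcomes whose support
is the open simplex.

## Penalized gene-level selection

For the p SNPs of a gene the penalized objective is

ℓ(η) − cκ Σ_l ‖η_·l‖₂² − (1−c)κ Σ_l ‖η_·l‖₁,

where η_·l is predictor l's coefficient triple across components, c ∈ [0,1]
mixes ridge (c = 1) and lasso (c = 0), and κ ≥ 0 sets the overall strength.
Since the squared group-L2 norm is an elementwise sum of squares, the
penalty is a separable elastic net and the proximal map has the closed form
soft(x, t(1−c)κ)/(1 + 2tcκ). The solver is proximal-gradient ascent with
backtracking (the objective never decreases; this is asserted at run time),
stopping at a relative objective change below 1e-8 or 5000 iterations,
after which the fit is returned flagged with its iteration count. Exact
zeros occur whenever c < 1; at c = 0 the solution satisfies the lasso KKT
inequality |score| ≤ κ at zero coefficients.

Dosage columns are centered and scaled to unit variance before
penalization (penalties are scale-sensitive) and coefficients are reported
on both the standardized and the raw scale. The intercept row and, under
M2, the family-contrast rows are never penalized: family is adjustment, not
a selection target. Selection counts use a tolerance of 1e-6 on the
standardized scale, counted both as coefficients and as SNP groups (a SNP
with any nonzero component). No default κ is imposed; a κ grid is exposed
and a c grid of {0, 0.3, 0.5, 0.7, 1} is the default report. Optional
cross-validation for κ was considered and deliberately left out of scope;
users can sweep the grid and inspect the path.

## Genotype QC

Filters run in a fixed order: sample call rate (individuals with < 95%
non-missing markers removed), then per marker: call rate ≥ 95%, exact
Hardy-Weinberg test (p < 1e-6 removed), minor-allele frequency ≥ 5%. The
report partitions markers across stages, so a marker failing several
filters is counted at the first one.

The marker "call rate" criterion is deliberately read as *missingness ≤ 5%*
(call rate ≥ 95%); a literal 95%-missingness cutoff would remove almost
nothing from any realistic panel.

The HWE test is the exact conditional test: the probability of each
feasible heterozygote count given the allele counts is computed in log
space (gammaln), and the p-value sums the probabilities no larger than the
observed count's. It applies to hard calls only; dosage-imputed data skip
the HWE stage with a logged notice, since genotype counts are undefined for
fractional dosages. MAF is computed from non-missing dosages as
min(m, 1−m) with m = mean(dosage)/2, and is invariant to allele relabeling.

## Synthetic cohorts

The simulator emulates a family-based cohort: by default 142 nuclear
families of 4–8 members (≈ 850 subjects, matching a typical pedigree-GWAS
cohort), four examinations four years apart, marker MAFs uniform on
[0.05, 0.5], 1% clinical missingness per exam, 0.2% genotype missingness.
Founders are drawn from Hardy-Weinberg proportions; children receive one
allele from each of the two founders (gene-dropping), which induces the
expected sibling dosage correlation of about one half.

Longitudinal states are generated by the same multinomial transition
mechanism the pipeline estimates, with diagonal-dominant default
coefficients on (1, sex, smoke, centered age) and an initial-state
distribution of (0.55, 0.30, 0.15). Causal SNPs add β·dosage to the linear
predictor of the hypertensive destination. Blood pressures are then drawn
uniformly inside the assigned state's (SBP, DBP) rectangle — state 1:
[90,120)×[50,80); state 2: the complement within [90,140)×[50,90); state
3: [140,180]×[90,110] — so state assignment round-trips exactly for
non-medication exams; 30% of hypertensive exams are flagged as medicated
with pressures drawn over the full range. This is a synthetic convention:
the generator reproduces the state-assignment geometry, not blood-pressure
autocorrelation, measurement error, medication dynamics, linkage
disequilibrium, or extended pedigrees. Passing tests therefore validate
the estimation machinery and test calibration, not predictive performance
on real cohorts.

Because causal effects enter on the transition (generative) scale while
the pipeline estimates effects on the Dirichlet scale, recovery studies
assert sign, ranking and test calibration rather than equality of
generative and fitted effect sizes.

## Numerical choices and problem sizes

- Multinomial and Dirichlet fits: analytic gradients and Hessians,
  observed-information covariances; gradient tolerances 1e-8 (multinomial)
  and 1e-6 (Dirichlet); the Dirichlet Newton iteration is warm-started from
  the null fit during scans.
- All simulation randomness flows through a single `numpy.random.default_rng`
  stream per run, so every artifact is a pure function of (inputs, config,
  seed); the pipeline rerun with the same config is byte-identical.
- Test and acceptance problem sizes were chosen to make the Monte-Carlo
  bands tight while keeping a full run on one CPU in a few minutes:
  calibration uses 2000 null replicates at n = 300 subjects, power uses 200
  replicates per effect size, parameter recovery uses n = 5000 transitions
  and n = 2000 subjects, the exact-HWE comparison is exhaustive over all
  genotype configurations with n ≤ 200, and the end-to-end cohort studies
  use ≈ 200–880 subjects and 200–300 markers.

## Known limitations

- The Dirichlet models include only SNP and family; no further covariate
  adjustment, and no random-effect (kinship) extension — a latent
  multivariate-normal family effect is a natural but nontrivial follow-up.
- Family is a fixed categorical; very many small families inflate the M2
  parameter count and the observed-information inversion cost.
- The penalized stage treats markers as exchangeable; no adaptive or
  hierarchical weighting, and κ must be supplied or swept.
- The exact HWE stage requires hard calls; heavily imputed panels are
  filtered only by call rate and MAF.
- Selection counts at c = 1 (pure ridge) depend entirely on the reporting
  tolerance since ridge never produces exact zeros.
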