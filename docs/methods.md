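# Methods

## Model

Samples are heterogeneous tissue: each observed beta value is assumed to
be a fraction-weighted mixture of pure-compartment methylation states,

    beta_ij = ec_j * epi_i(age_j) + fib_j * fib_i + ic_j * imm_i(age_j) + e_ij

where `ec`, `fib`, `ic` are the sample's epithelial, fibroblast and
immune fractions (summing to one) and each pure compartment follows a
linear methylation-age trajectory. Under this model, regressing beta on
`[1, ic, ec, age, ic·age, ec·age]` per CpG identifies the
compartment-specific aging rates: the coefficient on `ec·age` is the
epithelial aging slope and the coefficient on `ic·age` the immune slope
(beta units per year). Identification requires a third compartment with
non-zero variance: if `ec = 1 − ic` exactly, the two interaction columns
are collinear with `age` and the fit refuses with an explanatory error.

### aDMP classification

CpGs are classified by coefficient magnitude with two thresholds,
`thr_hi = 1e−3` and `thr_lo = 1e−5` beta/year by default, all
comparisons strict:

* epithelial-specific: `|b_ec·age| > thr_hi` and `|b_ic·age| < thr_lo`;
* immune-specific: symmetric;
* shared: both interaction magnitudes `> thr_hi`, or (for bulk aging
  signal not resolved into compartments) `|b_age| > thr_hi` with both
  interaction magnitudes `< thr_lo`;
* other: the remainder.

The shared rule is this package's definition. Under the mixture model a
CpG aging identically in the epithelial and immune compartments has its
signal decompose *exactly* onto the two interaction columns
(`b0 + s·ec·age + s·ic·age`), leaving `b_age = 0`; shared aging therefore
appears as both interaction coefficients exceeding `thr_hi`, and a rule
keyed on `b_age` alone would never fire. The `b_age` clause is retained
so that data in which aging is expressed at the bulk level (fractions
uncorrelated with the signal) still classify as shared. Both thresholds
are parameters.

Note the statistical caveat: the two interaction-coefficient estimates
are strongly negatively correlated (because `ec ≈ 1 − ic`, identification
rides on the small fibroblast fraction), and at realistic noise their
sampling error is of order 10⁻³ beta/year for cohorts of ~10³ samples.
The "specific" calls, which require the off-target coefficient to be
*below* `thr_lo`, are therefore conservative on noisy data: planted
specific CpGs are mostly detected (`|on-target| > thr_hi`) but often
land in "other" because the off-target estimate does not fall below
`thr_lo`. Exact category recovery should only be expected in the
noise-free regime; see Limitations.

## Clocks

* **General clock**: lasso (L1) regression of chronological age on all
  CpG betas. Features are standardised internally and coefficients
  returned on the beta scale; the penalty is chosen on a geometric path
  (100 values, ratio 10⁻³) by 10-fold CV minimising mean squared error
  (the minimum-CV rule, not the 1-SE rule). Only CpGs with non-zero
  weight are retained. An all-constant feature matrix yields an
  intercept-only model predicting the mean training age.
* **Cell-type clocks**: ridge (L2) regression on one aDMP category with
  paired interaction features `beta·ic`, so the read-out can depend on
  immune content. The penalty grid is log-spaced (50 values, 10⁻⁶–10²,
  scaled by sample count so the per-observation penalty is
  size-stable) with the same CV rule. If `ic ≡ 0` the interaction
  columns are constant and their coefficients are exactly zero.
* Fold assignment is a seeded shuffle; training is bit-reproducible
  given (data, seed, folds).
* Applying a clock to a matrix missing model CpGs is an error listing
  the missing probes; `allow_missing="mean"` is an explicit escape hatch
  substituting a neutral beta of 0.5.

Accuracy metric: median absolute difference between predicted and
chronological age, plus the Pearson correlation (reported as NaN when
either vector is constant).

## Relative age and adjustment

`age_accel = general − chronological`, `rea = epithelial − general`,
`ria = immune − general` (years). Because these depend on age and on
cell composition, group comparisons use residuals from an OLS fit of the
raw statistic on covariates — `{age, ic}` by default, `{age}` for
tissues with little compositional variance — estimated on a caller-
supplied reference mask (e.g. all controls, or controls never on
hormone therapy) and applied to every sample. The reference choice is a
mask parameter, not hard-coded phenotype logic. Adjustment is linear
only; over the reference set the residuals are exactly orthogonal to
each covariate.

## Quartile odds ratio

Quartile boundaries are the 25/50/75th percentiles of the *reference*
samples (numpy's linear-interpolation/type-7 quantiles); a value exactly
on a boundary goes to the lower quartile. Exposure is membership in the
designated quartile (default lowest). The OR is `ad/bc` with a Wald 95%
CI `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`; zero cells trigger a flagged
Haldane correction (+0.5 on every cell). Wald is the default because it
is closed-form and testable; a median-unbiased mid-p estimator (root of
the conditional non-central-hypergeometric mid-p at 0.5) is available,
since epidemiology toolkits differ in their default and the choice can
matter for small tables.

## QC

Filter order: (1) drop samples with median methylated or unmethylated
log2 intensity `< 9.5`; (2) drop samples with `> 10%` failed probes
(detection p `> 0.01`, strict); (3) drop probes failing in `> 10%` of the
*remaining* samples. The intensity-before-detection order is a package
decision (the chain's result can depend on it); all thresholds are
parameters. The intensity filter takes precomputed per-sample medians so
the module stays platform-agnostic. Remaining failed entries are imputed
as the mean of the `k = 10` nearest probe rows by Euclidean distance
over shared observed samples (rescaled to the full sample count),
neighbours being required to be observed at the imputed sample —
probe-space nearest-neighbour imputation with mean aggregation.
Exclusion lists (non-CpG probes, SNP-related probes, chrY, trimodal
probes, …) are user-supplied CpG sets; none are bundled.

## Deconvolution stand-in

Cell fractions are estimated per sample by non-negative least squares
against pure-compartment reference profiles with a sum-to-one
constraint, implemented as a heavily weighted constraint row in the NNLS
system followed by exact renormalisation. On mixtures of the reference
profiles the solution is exact; under noise it is the NNLS solution
re-projected onto the simplex. This is a deliberate simplification of
robust-partial-correlation reference-based deconvolution: the pipeline
consumes only the fractions, and externally computed fractions can be
supplied in the sample table instead. When a reference distinguishes
immune subtypes, `ic` is their summed fraction.

## Synthetic cohorts

The generator emulates cervical-like mixtures: immune fraction uniform
on [0, 0.95] (heterogeneous, roughly uniform immune content), a small
fibroblast compartment (uniform on [0, 0.1] of the non-immune
remainder — enough variance to keep the interaction design full-rank),
ages uniform on 20–75 years, per-CpG baselines on [0.1, 0.9], aging
slopes of magnitude 0.001–0.005 beta/year with random sign, and additive
Gaussian noise clipped to [0, 1] (sigma interpreted pre-clipping).
Planted categories: shared CpGs age identically in the epithelial and
immune compartments, specific CpGs in one, null CpGs in neither;
fibroblasts do not age, which keeps the two interaction coefficients
interpretable as pure-compartment rates. A `case_effect < 1`
multiplicatively slows the epithelial compartment's aging in case
samples — the minimal mechanism producing a reduced relative epithelial
age in cases.

Baselines of aging CpGs are drawn from the sub-interval of the baseline
range that keeps the noiseless trajectory inside [0, 1] over the whole
age range, so the planted signal is exactly linear and noise-free
recovery is exact; clipping remains as a safeguard and clipped entries
are counted in the truth object (zero at sigma = 0; < 1% of entries at
the default ranges with sigma up to 0.05).

What the generator does **not** emulate: array chemistry (probe-type
effects, batch/chip structure), beta-distributed heteroscedastic noise,
non-linear trajectories, correlated CpGs, realistic covariate biology
(menopause, HRT) beyond the planted case effect. Passing tests on these
cohorts demonstrate correctness of the estimators under the stated
mixture model, not performance on real arrays.

## Standard study design and problem sizes

Tests and the acceptance script use a reference design of 2,000 CpGs
(300 shared / 100 epithelial / 100 immune / 1,500 null) by 800 samples
with a 600/200 train/test split, and a 300-sample case/control cohort
(case fraction 0.5, case effect 0.9, sigma 0.02) for the planted-effect
comparison; module tests use smaller cohorts of the same shape. These
sizes keep the full suite and the acceptance script in the tens of
seconds while leaving the statistical conclusions stable.

## Known limitations

* On noisy cohorts the specific-aDMP *category* sensitivity is low even
  when detection of the on-target coefficient is high (see the
  classification caveat above): with sigma = 0.02 and 800 samples the
  off-target coefficient's sampling error (~2.5×10⁻³) dwarfs `thr_lo`,
  so few CpGs satisfy the off-target condition. Category recovery is a
  noise-free/very-low-noise property.
* Cell-type clock accuracy is intrinsically capped by composition
  heterogeneity: with epithelial-only signal, the features `[β, β·ic]`
  carry age only through `ec·age` terms, so chronological age is outside
  their linear span and held-out correlation plateaus around 0.9 on
  noiseless synthetic data (and much lower on real tissue, where
  cell-type clocks are known to track age more weakly than general
  clocks). The cell-type clocks' value is in the *relative* statistics,
  not in absolute age prediction.
* The deconvolution stand-in is not a substitute for curated-reference
  deconvolution on real arrays.
* The per-CpG screen provides no standard errors or p-values;
  classification is by coefficient magnitude only.
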