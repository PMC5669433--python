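# Methods

## Scientific setting

Fibrinogen is an acute-phase protein whose hepatic expression is
up-regulated by interleukin-6. Promoter and UTR variants in the
fibrinogen genes are hypothesised to change the magnitude of that
IL-6 response, so the quantity of interest is not the marginal
genotype effect on fibrinogen but the genotype-specific slope of the
fibrinogen–IL-6 relationship, and its downstream reflection in fibrin
clot phenotypes (formation lag, lateral aggregation rate, fibre
diameter via maximum turbidity, and clot lysis time). In a low-LD
population the 14 genotyped cluster SNPs can be analysed individually,
and carrying several minor alleles at once may act additively — the
motivation for the cumulative risk score.

## Models and procedures

### Turbidity features

Input curves are A405 absorbance vs time (seconds). The signal is
smoothed with a centered moving average (odd window, default 5
samples). The baseline is the median of the five smallest smoothed
values — for a complete rise-and-fall record this is the clear level
the curve starts from and returns to after lysis, and it degrades
gracefully to the pre-rise level for censored records. The plateau is
the smoothed maximum. Features:

- formation midpoint: first upward crossing of baseline + amplitude/2,
  linearly interpolated between samples; lysis midpoint: last downward
  crossing of the same level; CLT is their difference in minutes;
- lag time: first crossing of baseline + 5% of amplitude that stays
  above the level for 3 consecutive samples (the 5% fraction and the
  sustain count are options — the lag is only conceptually defined in
  the source assay, so the operationalisation is ours and documented);
- slope: maximum first difference of the smoothed rising limb (au/s,
  reported ×10³ in output tables);
- maximum absorbance: plateau − baseline (au). Turbidity plate
  readers report absorbance in arbitrary units at 405 nm; tables that
  label this quantity "nm" are quoting the wavelength, and this
  package reports au throughout.

QC: amplitude below 0.02 au (configurable) raises/flags NoClot; a
record that never falls back through the midpoint is flagged
CensoredLysis with CLT undefined; more than one upward midpoint
crossing flags MultiPhase. Extraction is deterministic; features are
invariant to time translation and equivariant under affine absorbance
maps (offset moves only baseline/plateau; scale multiplies slope and
amplitude).

### Population genetics

MAF folds the counted allele to [0, 0.5] and excludes missing calls
from the denominator. Hardy–Weinberg is tested with the exact
conditional test (probabilities of all heterozygote counts compatible
with the observed allele counts, summed over configurations no more
probable than the observed one); the chi-square approximation is
deliberately avoided because minor-homozygote counts at these MAFs are
single digits to low tens.

Two-locus haplotype frequencies come from EM over unphased genotype
pairs; only the double-heterozygote class is phase-ambiguous, so the
M step redistributes that class between the cis and trans phases by
their current relative likelihood. The log-likelihood is monotone and
the estimate is checked in the tests against a brute-force scan over
the single free phase parameter. LD coefficients: D = f_mm − p_m q_m,
D' = |D|/D_max with D_max the marginal bound on the observed sign,
r² = D²/(p q (1−p)(1−q)).

Confidence bounds on D' use a profile likelihood: allele frequencies
fixed at their sample estimates, likelihood evaluated on a 1000-point
|D'| grid, normalised, and the 5th/95th percentiles of the cumulative
mass taken as one-sided 95% bounds. This mirrors the construction
behind Gabriel-style block calling; the exact CI algorithm is an
implementation choice since block methods are conventionally named,
not specified. Blocks: a pair is *strong LD* if its lower bound
exceeds 0.70 and its upper bound reaches 0.98; it shows *strong
recombination* if the upper bound is below 0.90; other pairs are
uninformative. A contiguous run of ≥2 SNPs is a block when ≥95% of
its informative pairs are strong (with at least one informative
pair); maximal non-overlapping runs are kept longest-first. No
outermost-pair requirement is imposed, so a run whose outer pair is
merely uninformative can still be called — the choice that lets a
three-SNP block survive the noisy CI of its weakest pair.

The minimum-group-size rule treats the reference group as effectively
unlimited: a one-sample noncentral-t formulation with noncentrality
d√n, searched for the smallest n whose power reaches the target. The
sidedness of the underlying calculation is not conventionally
reported; the package default (one-sided) is recorded in the run
manifest. At d = 0.3, power 0.80, α = 0.05 the rule returns 71, and
genotype groups smaller than that threshold trigger carrier
collapsing (heterozygotes pooled with minor homozygotes).

### Association

All fits are ordinary least squares on explicitly constructed design
matrices (treatment-coded group indicators; covariates untransformed),
complete-case per model, so the analyzable n differs between outcomes.
Group effects and interactions are partial F tests against the nested
model. Adjusted means are evaluated at the covariate means of the
analyzed cases. Rank-deficient designs raise an aliasing error naming
the collinear columns rather than silently dropping them.

IL-6 quartiles use the inclusive empirical 25/50/75 percentiles with
boundary ties assigned to the lower quartile; ties that empty a
quartile are an error naming the degenerate cut. Tukey HSD p-values
come from the studentized-range distribution on the (covariate-
adjusted) model residual variance with Tukey–Kramer unequal-n scaling;
with no covariates this reproduces the classical procedure exactly
(verified against an independent implementation). Whether post-hoc
contrasts should use raw or covariate-adjusted variance is left as a
mode because both are defensible; the adjusted mode is the default.

Interaction models add group × IL-6 product terms; the reported
per-genotype slopes are simple within-stratum regressions of outcome
on IL-6 with 95% CIs — the form stratified interaction effects are
conventionally reported in, and the form whose CI coverage the
acceptance suite verifies. IL-6 enters untransformed (slopes are in
g/L per pg/mL); a log-IL-6 option exists but is off by default.
Mediator adjustment refits the identical model with total (and γ')
fibrinogen added as covariates, keeping raw and adjusted p side by
side; a mediator equal to the outcome is refused, and a refit that
loses analyzability (fewer than two groups after mediator missingness)
yields NaN rather than aborting a multi-SNP run. Benjamini–Hochberg
adjustment is applied per outcome across SNPs — the most conservative
family consistent with per-outcome reporting; the family definition is
a knob recorded in the manifest. The sensitivity filter drops samples
with IL-6 above 100 pg/mL and reports the count.

### Risk score

Per-SNP coding is derived from the same 71-count rule (carrier coding
when the minor-homozygote group is underpowered, three-level
otherwise) rather than hard-coding a published SNP list, because which
SNPs enter the score is data-driven (those with BH-significant
positive interactions). The score × IL-6 model treats the score as a
categorical factor; score levels under the group-size threshold are
excluded and reported. Pairwise slope equality is tested by Wald
contrasts on the interaction coefficients (the published analysis
reports that regression coefficients "differed significantly" without
naming a test; Wald contrasts on the factorial model are the natural
choice and are exact under OLS normality).

## Synthetic cohort generator

The generator is the package's study-conditions module: its defaults
encode the cohort the analysis assumes.

- **Genotypes.** 14 SNPs; MAFs use the printed values where available
  (e.g. 6.95%, 6.78%, 3.32%, 11.4% for the four upstream *FGB*
  variants) and are otherwise back-derived from collapsed group
  counts; the novel promoter SNP rs2227385 is assigned 6.86%
  (between its tightly linked neighbours) and rs2227388 10%. Linked
  groups are sampled as two-state haplotype Markov chains hitting the
  adjacent pairwise D' targets exactly in expectation; unlinked SNPs
  are HWE binomial draws.
- **LD calibration.** The *FGB* promoter trio is chained at adjacent
  D' = 0.985, implying D' ≈ 0.97 / r² ≈ 0.92 for its outer pair —
  adjacent coupling near (but below) the complete-LD pattern most
  within-block pairs show, strong enough for CI-based block calling to
  be stable. The *FGG* 3'UTR pair is set to D' = 0.99; its unequal
  MAFs keep r² ≈ 0.49, i.e. no complete LD anywhere. The closed-form
  pool operation reproduces the printed outer-pair value exactly when
  asked (D' = 0.95 at MAFs 6.95/6.78% implies r² = 0.879).
- **IL-6** is log-normal with parameters moment-matched to mean 6.50
  and SD 21.0 pg/mL (μ = 0.6536, σ = 1.5610) — heavy-tailed, so a
  2010-sample cohort carries a handful of values above 100 pg/mL,
  which is what the sensitivity filter exercises.
- **Fibrinogen.** total = c₀ + Σ c_g + (m₀ + Σ m_g)·IL6 + covariate
  effects + N(0, σ), with per-SNP per-genotype (c_g, m_g)
  contributions; for a single-SNP effect map the within-stratum
  population slope equals m(genotype) exactly, which is what the
  zero-noise recovery tests assert. Default σ = 2.0 g/L reproduces the
  observed fibrinogen dispersion. γ' is a Uniform(8%, 15%) fraction of
  total plus its own noise; covariates (age, gender, BMI, HIV, HbA1c,
  HDL-c, PAI-1 activity) are drawn independently with configurable
  additive effects, since no joint covariate structure is reported —
  the independence is a stand-in, not an inference.
- **Clot features** derive from total fibrinogen (and PAI-1 activity
  for CLT) through a monotone linear forward model (maximum absorbance
  and slope rising with fibrinogen; CLT rising with fibrinogen and
  PAI-1). The source analysis reports associations, not a forward
  model, so the coefficients are config with defaults that land the
  feature means/SDs near the observed descriptives; curves are
  double-logistic A(t) = A₀ + ΔA·σ((t−t_f)/s_f)·(1−σ((t−t_l)/s_l))
  with s_f chosen so the analytic maximum rate ΔA/(4 s_f) matches the
  requested slope, and the default external-control parameters give a
  CLT inside the 60–100 min assay window.
- **Missingness** is injectable per variable; the study-default rates
  (20–28%) reproduce the differing analyzable n per outcome.

Scenario constructors freeze the recovery experiments: the
single-SNP interaction cohort (n = 1346, carrier slopes 0.014/0.110);
the full-mediation cohort in which maximum absorbance depends on
genotype and IL-6 only through fibrinogen (coupling 0.05 au per g/L,
residual SDs 1.5 g/L and 0.06 au — sized so the unadjusted
interaction carries the decisive significance of the mediated
signature while its stratified maxabs slopes stay near the printed
ones); and the seven-SNP score cohorts (carrier probability 0.25 per
SNP, so scores span 0–6 with the top two levels too small to analyse,
n ≈ 21 and ≈ 2 at n = 1800; slope base 0.01, increment 0.04 per
risk-allele group, flat beyond three in the threshold pattern, noise
1.5 g/L — increments sized so adjacent Wald contrasts are decisively
powered rather than marginal). Problem sizes in the acceptance suite
(300 interaction seeds, 100 seeds elsewhere) are the package's chosen
simulation scale: large enough for the proportion checks to be stable,
small enough to keep the suite fast.

What the generator does **not** emulate: the real covariate joint
distribution, HIV biology, any >2-locus joint LD beyond the chained
pairwise targets, skewness of real fibrinogen (noise is Gaussian, so
extreme draws can be unphysiologically low), or assay artefacts in
turbidity curves beyond additive Gaussian noise. Passing recovery
tests therefore demonstrates correctness of the statistical machinery
under the assumed data-generating process, not robustness to real
plate-reader pathology or confounding.

## Numerical choices

- EM tolerance 1e-10 on the log-likelihood, max 2000 iterations;
  degenerate classes handled by 0·log 0 := 0.
- Profile-CI grid: 1000 midpoints on [0, 1]; sign of D fixed at the
  EM estimate.
- Perfect-fit interaction models (zero residual) report p = 0 rather
  than a 0/0 F statistic.
- Quartile boundary ties go to the lower quartile by construction
  (left-sided search of the cut points).
- Smoothing windows must be odd; edge bins are averaged over the
  available support.
- A single pipeline seed is expanded into per-stage child seeds via
  SeedSequence spawning, so any stage can be re-run in isolation and
  a fixed seed reproduces every output byte-for-byte.

## Limitations

- The exact HWE test is conservative at small minor-allele counts; its
  type-I rate sits below nominal, which is the intended behaviour.
- Carrier collapsing discards dominance information by design; no
  dominant/recessive model scans are provided.
- Mediation handling is covariate adjustment only — no formal causal
  mediation estimands.
- Block calling follows the CI-threshold recipe exactly and is
  sensitive, as all such recipes are, to the CI construction at low
  minor-allele counts.
- Printed MAFs and collapsed group counts in the source tables are
  mutually inconsistent under any single n (different analysis
  subsets); the generator takes the MAFs as primary and does not try
  to reconcile them.
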