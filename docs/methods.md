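# Methods notes

## Generating model

Twin pairs are simulated under a bivariate ACE model. Each latent trait —
parenting received (x) and child antisocial behavior (y) — is
`T = a·A + c·C + e·E` with independent standard-normal factors and unit total
variance. Additive-genetic factors correlate 1.0 between MZ co-twins and 0.5
between DZ co-twins (implemented by splitting A into a pair-shared and a
twin-specific part with variance weights 0.5/0.5); shared-environmental
factors are common to the pair; nonshared factors are twin-specific. The two
traits are linked only through correlations between like factors
(`r_A, r_C, r_E`), which yields the closed forms quoted in the README and in
`BiometricParams`. The three scenario presets place the entire cross-trait
association on one route (nonshared environment; genes; genes plus shared
environment, split evenly between the two routes) by inverting the
individual-level closed form for the required factor correlation.

Default variance shares are literature-anchored rather than free knobs:
parenting received uses a² = .26, c² = .39, e² = .35 (meta-analytic estimates
of child-driven genetic and shared-environmental variance in parental
warmth from child-based twin designs), and childhood ASB uses a² = .50,
c² = .20, e² = .30. The default cross-trait effect size is an
individual-level correlation of −0.10, the magnitude typical of
nurturance–ASB associations, and the default sample is 426 MZ and 604 DZ
pairs (the pooled two-arm study the pipeline emulates).

## Measurement layer

Each (measure, informant) report is `sqrt(ρ)·latent + sqrt(1−ρ)·noise`, so an
observed cross-trait correlation is the latent one attenuated by
`sqrt(ρ_x ρ_y)`. The default reliability is ρ = 0.7 for every report; this is
deliberately a round middle value — real inter-informant correlations
(≈ 0.2–0.6) would imply informant-specific valid variance that a single
latent-plus-noise layer cannot represent, so ρ is exposed per report for
sensitivity analyses. Raw ASB scores are right-skewed; the simulator induces
skew with a monotone exponential transform (`exp(λs)`, default λ = 0.6, giving
sample skewness ≈ 1–4, as in raw behavior-checklist data) followed by a fixed
affine map of ±4 latent SD onto the instrument range (clipping beyond). The
map is deliberately sample-independent so that rendering is rank-preserving
and bit-reproducible. Reports are deleted completely at random at
informant-specific rates chosen to match the emulated study's coverage
(mother ≈ 99%, father and teacher ≈ 83%, twin reports ≈ 94–99%); real
missingness is unlikely to be MCAR, so coverage — not informativeness — is
the only aspect emulated. Item-level structure, rater bias and
sibling-contrast effects are not modeled; passing tests therefore speak to
the design's statistical behavior under clean measurement, not to the
robustness of any real-data conclusion.

## Analysis variables

Composites are means of available member reports (a single available report
stands in; all-missing propagates). Members are standardized before averaging
only when a composite mixes instruments (checklist + teacher form +
interview), since raw scores on different instruments are incommensurable;
within-instrument composites average raw scores. The twin's perception of
nurturance is the mean of their available mother- and father-reports. Log
normalization is `log(1+x)`. Standardization is z-scoring over the pooled
sample (both zygosities, sample-SD convention, ddof = 1) before any
difference scoring, and every analysis column is standardized after
composite formation; the alternative ordering (standardize, then composite)
only reweights members and is available by composing the public primitives.
Zero-variance columns raise immediately, naming the column.

## Estimators

**Difference correlations.** Twin A/B labels are drawn once per dataset from
the labeling seed. Difference scores use complete pairs only (exclusions are
counted on the table). Correlations of difference scores are computed from
moments about the origin rather than about sample means: difference scores
have population mean zero by construction under random labeling, the origin
form loses nothing, and it makes every estimate *exactly* invariant to the
labeling seed (relabeling flips Δx and Δy together). CIs are Fisher-transform
intervals, `tanh(atanh(r) ± 1.96/√(n−3))`, with the two-sided p from the
normal reference of `atanh(r)·√(n−3)`. |r| = 1 returns a degenerate CI and
p = 0.

**Phenotypic model.** A linear mixed model with one normal random intercept
per family, fitted by maximum likelihood on available cases (twins with both
variables); Wald 95% CIs and normal p-values. No robust/sandwich errors and
no full-information ML over missing data: available-case estimation trades a
little efficiency under missingness for a simpler, testable implementation.
Note a structural point: when within-family and between-family slopes differ
— as they do under the ACE presets, where the within-MZ slope can be far from
the marginal correlation — the random-intercept GLS estimand is a
precision-weighted blend of the two, not the marginal correlation. Slope
*recovery* is therefore validated on data generated from the model the
estimator assumes (known slope, family intercepts, bias < 0.01 at 50,000
twins); under the ACE presets the model is validated for sign and
significance, which is all the decision rule consumes.

**p→z and aggregation.** Two-sided p-values convert to |z| via the normal
quantile at p/2 with the estimate's sign attached; p is floored at 1e−15 to
keep aggregates finite. Curve summaries use unweighted medians and
sample-size-weighted means (the study weights "averages" only; a median is
not an average), with per-cell weights equal to analyzed twins (phenotypic)
or complete pairs (differences). `pct_p_lt_05` uses strict inequality. The
four-indicator decision takes |avg_z| so that positive and negative effects
are treated symmetrically; disagreement among indicators is conservatively
nonsignificant, which makes the rule monotone under sharpening of evidence.

**Steiger contrast.** Two dependent correlations sharing the outcome are
compared with Steiger's Z1* using the pooled mean correlation (the variant
implemented by the standard online calculator); it is validated against a
Monte-Carlo trivariate-normal oracle (type-I error 0.052 at α = 0.05,
n = 200, 10,000 replicates) rather than trusted on faith. The correlation
between the two parenting variables (r23) and the per-cell n are explicit
inputs, as no general rule recovers them from curve output; the summary-level
contrast uses the unweighted median per-cell n.

## Scenario classification and recovery

The classifier maps the (phenotypic, MZ, DZ) significance pattern to
environmental / genetic / genetic-plus-shared-environmental, with
no-association when the phenotypic curve is nonsignificant and inconsistent
for the MZ-only pattern (which no etiologic scenario produces). The recovery
harness simulates full observed studies at the default scale and runs a
compact one-cell grid (all-informant composites, log-normalized ASB) at both
levels: composites maximize effective reliability (ρ_composite ≈ 0.9 for four
informants at ρ = 0.7) and the log transform approximately linearizes the
exponential skew, so one cell carries the design's power without 130
mixed-model fits per replicate. At these settings the environmental scenario
is recovered in ≳ 90% of replicates and the genetic scenarios are essentially
never mislabeled environmental (the MZ difference correlation has expectation
zero there).

## Problem sizes and numerical choices

Closed-form checks use 50,000 pairs per zygosity (MC error ≈ 0.005 on a
correlation, comfortably inside the ±0.02 test band). Recovery suites use 100
replicates per scenario at study scale. All randomness flows from
`numpy.random.SeedSequence` master seeds spawning per-stage substreams
(latents, measurement noise, missingness, A/B labeling), so every artifact is
bit-reproducible given its seed. Degenerate inputs fail loudly rather than
silently: zero discordance, zero-variance predictors, non-PSD correlation
triples, families without exactly two twins, and p-values outside (0, 1] all
raise typed errors.

## Known limitations

MCAR missingness and a single shared latent per trait are simplifications;
the simulator cannot represent informant-specific perspectives or
non-random attrition. The pipeline carries two traits, so three-variable
analyses (e.g. a joint nurturance/harshness/ASB dataset) must be composed at
the difference-score level. The mixed model fits one random intercept; random
slopes and robust errors are out of scope.
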