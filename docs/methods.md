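# Methods

## The problem

Hospital pay-for-performance schemes tie payment to measured quality for a
set of targeted conditions. Because physicians, wards, and budgets are
shared, such schemes can spill over onto patients admitted for conditions
the scheme does not target — through effort or resource diversion,
learning by doing, knowledge transfer between colleagues, or reallocation
of patients across physicians (patient sorting). `spilldid` implements an
analysis pipeline that quantifies these spillovers on 30-day mortality for
non-targeted emergency patients, using a regional scheme design: hospitals
in one treated region face the incentives, the rest of the country is the
control group, and the scheme switches on at a known quarter.

Because the real linked admission/death extracts such analyses run on are
access-restricted, the package ships a first-class synthetic-data
generator whose draws exercise every stage of the pipeline with known,
recoverable effects.

## Cohort construction

From admission-level records the analysis sample keeps adults (19+)
admitted for one of a catalogue of non-targeted conditions, excludes
patients carrying a targeted primary or secondary diagnosis, and — to
avoid attributing one death to several stays — drops every admission that
occurs after the first *emergency* admission inside the patient's final 30
days of life (the first such admission keeps the death). Finally the
sample is restricted to a balanced physician panel: physician-hospital
pairs with at least one retained admission in every quarter of the study
window. Filters are applied in that fixed order and the exclusion log
reports sequential counts; the counts are order-dependent by construction.
The 30-day window is inclusive of day 30. The outcome is a binary 30-day
death indicator from linked death registrations.

## Exposure measures

Direct exposure `x_direct` is a physician's mean number of targeted
patients per quarter over the post-policy period (quarters with none count
as zeros; a patient admitted twice counts twice, since admissions are the
observable unit). Indirect exposure `z_indirect` is the specialty-weighted
average of peers' direct exposure,

    z_p = sum_s (n_ps / N_p) * sum_{q != p} [ n_qs / (N_s − n_ps) ] * x_q ,

with all counts taken over post-policy admissions (targeted included) so
that exposure is a fixed physician attribute. A specialty in which the
physician works alone contributes zero. One consequence worth noting: the
outer weights are not renormalized over non-solo specialties, so a
physician with a solo specialty can have `z_p` below the minimum of their
peers' exposures; the bound that always holds is `0 <= z_p <= max_q x_q`,
with full convexity whenever every specialty has at least one peer.

Robustness variants: indirect exposure restricted to peers treating at
least one shared condition (weights renormalized over the restricted
set), share-based measures (targeted share of a physician's caseload, and
its peer-weighted average), and specialty exposure `x_specialty` (mean
targeted patients per quarter in the specialty of treatment).

## Two-stage difference-in-differences

Directly adjusting for time-varying covariates inside one DiD regression
contaminates the adjustment with post-treatment responses. The pipeline
instead uses a two-stage imputation design:

1. **Stage 1 (controls only).** A two-way fixed-effects linear probability
   model of the outcome on patient covariates, time-varying hospital
   covariates, hospital attributes interacted with quarter dummies, and
   hospital (or physician-hospital) plus quarter intercepts.
2. **Gap.** The fitted covariate and time coefficients predict each
   treated-region patient's expected mortality; `ytilde = Y − Yhat`.
   Control-hospital intercepts have no treated counterpart and are
   excluded from the prediction — the second stage absorbs all levels, so
   any constant offset cancels.
3. **Stage 2 (treated region only).** The gap is regressed on the
   post-policy indicator with hospital fixed effects (average spillover
   `delta`), or — after adding physician/specialty covariates and
   physician-hospital fixed effects in both stages (the patient-sorting
   adjustment) — on the exposure decomposition

       ytilde = theta*D + mu*X*D + phi*Z*D + pi_ph + e .

   Exposures are deliberately not demeaned: `theta` is the effect on
   patients of zero-exposure physicians, `mu` and `phi` the marginal
   effects per additional targeted patient per quarter of direct and
   indirect exposure. In decomposition mode stage 1 additionally adjusts
   for exposure-by-quarter terms so untreated potential outcomes may vary
   with exposure.

Everything is ordinary least squares on the probability scale; reported
coefficients are multiplied by 100 (percentage points). Fixed effects are
absorbed by within-group demeaning (exact for these one-way structures);
absorbed fits agree with explicit dummy-variable regression to machine
precision, which the tests assert at 1e-10. Collinear design columns are
dropped greedily, first-come kept, via an incremental Cholesky
rank check; categorical levels present in the panel but absent from the
control sample yield all-zero columns that the same filter removes, so
prediction treats them as reference levels rather than failing. Levels
never seen at fit time still raise (no silent extrapolation). Predicted
probabilities are not clipped.

## Inference

Standard errors are CR1 cluster-robust at the hospital level:
`V = c (X'X)^{-1} [sum_g X_g'e_g e_g'X_g] (X'X)^{-1}` with
`c = G/(G−1) · (N−1)/(N−K)`, where K counts slope regressors plus absorbed
fixed-effect levels (so absorbed and dummy-variable fits report identical
SEs). p-values use t(G−1). With one observation per cluster the estimator
reduces exactly to the HC1 heteroskedasticity-robust matrix.

Stage-1 sampling uncertainty is *not* propagated into the reported
spillover standard errors — they are the plain clustered second-stage SEs,
a documented limitation of the design. The pre-trend tests are the
exception: the stage-1 prediction error is a shock common to every treated
observation in a quarter, invisible to hospital clustering, and ignoring
it makes the joint pre-trend test reject several times its nominal level.
Because the second stage is linear in the stage-1 coefficients, that
component is `B V1 B'` with `B = (X2'X2)^{-1} X2'P` (P the treated rows'
stage-1 design, demeaned like the stage-2 design) and `V1` the stage-1
clustered coefficient variance; the two samples are disjoint, so the
pieces add. With this correction the joint Wald test — referred to an
F(q, G−1) distribution, the standard few-cluster choice — holds close to
nominal size; the 500-replicate null study in the test suite checks the
5% rejection rate against its exact binomial band. The linear pre-trend
slope test uses the same correction.
The event-study reference period is the last pre-policy quarter observed
in the sample.

Degenerate cases: fixed-effect groups with no pre/post variation are
dropped with a warning; requesting the decomposition with zero-variance
exposures raises a collinearity error pointing to the average model (an
`allow_degenerate` switch instead drops the collinear terms, which
reproduces the average model exactly — the two specifications nest).

## Robustness suite and subgroups

Nine variants re-run the full two-stage pipeline: the main decomposition;
added specialty-exposure, direct-x-indirect interaction, and squared
exposure terms; the condition-restricted and share-based exposure
measures; and three sample restrictions (dropping the final pre-policy
quarter against anticipation, dropping control regions adjacent to the
treated region, dropping control regions with similar later incentives).
Restrictions change sample membership only — never the estimator — and
exposure variables are never recomputed on restricted samples, keeping the
zero-exposure interpretation of `theta` constant across variants. The
turning point of the squared specification is `−linear/(2·quadratic)`,
in targeted patients per quarter.

Subgroup analyses stratify by whether the admission condition shares a
diagnosis area with the targeted conditions, and by whether the hospital's
post-policy share of targeted admissions is above or below the median
share among treated-region hospitals (ties to "below"; the threshold is
defined on treated-region hospitals and applied globally). Stage 1 is
re-fit within each subgroup's control rows, a choice the design leaves
open.

## The synthetic-data generator

One draw generates hospitals (region tag, trust type, foundation status,
a Gaussian mortality shift), physicians per hospital (Gaussian ability
that *lowers* mortality, a primary specialty, and a gamma-distributed mean
targeted caseload — shape 0.6, scale 20, so most physicians have little
exposure and a few have a lot), and Poisson patient counts per
physician-quarter for targeted and non-targeted streams. Patient
covariates: age ~ N(72, 15) truncated to 19–99 (1% minors to exercise the
age filter), sex, a Poisson(2) comorbidity count thinned into 31 distinct
flags, standard-normal deprivation, and admission-route flags. 30-day
death is the Bernoulli primitive with probability

    p = baseline + hospital effect − ability + trend·t + covariate terms
        + treated·post·(theta + mu·X + mu2·X² + phi·Z)/100
        + treated·1[last pre quarter]·anticipation/100 ,

clipped to [0.001, 0.999]; covariate contributions are centred at their
generating-law means so the overall rate stays near the 6.5% baseline.
Decedents get a death date uniform on days 0–30; survivors occasionally
(2%) die after day 30 to exercise the outcome boundary. The spillover
terms use the exposures computed by the exposure module on the generated
admission table itself, so the simulator truth and the estimand are the
same object. A share of decedents (5%) receive an extra emergency
admission inside their final 30 days, which the attribution filter must
remove; these extra rows slightly perturb the peer weights of `z_indirect`
relative to the exposures the effects were applied with — a negligible
(<1%) attenuation that only matters in knowledge-transfer scenarios.
Patient sorting reassigns a configurable share of treated-hospital
post-policy non-targeted patients from above- to below-median-ability
physicians, reproducing the qualitative attenuation of the average
estimate when physician-hospital fixed effects are added.

Scenario presets encode the mechanism taxonomy: `null` (all effects off),
`resource_diversion` (theta = 0.321), `learning` (mu = −0.008),
`knowledge_transfer` (phi = −0.004), `sorting` (strength 0.35, ability sd
0.02), and `combined` (theta = 0.321, mu = −0.008, phi = 0), the last
calibrated to the headline decomposition estimates so recovery studies
target realistic magnitudes.

What the generator does **not** emulate: real ICD-10/CCS coding,
seasonality beyond a linear trend, hospital entry/exit, patient transfers,
confounded treatment assignment (treated status is independent of all
latent outcome terms by construction), or serially correlated
within-hospital shocks. Passing recovery tests therefore demonstrate that
the estimator is consistent and correctly scaled under the maintained
design assumptions — not that those assumptions hold in any real data.

## Default scales and runtimes

The reference simulation scale is 60 hospitals (20 treated), 8 physicians
per hospital, 3 specialties, 4 pre + 4 post quarters, ~40 non-targeted
patients per physician-quarter (~190k admissions per draw). Parameter
recovery runs 100 replicates at this scale. The pre-trend size study keeps
the full hospital split — cluster count is what drives test size — but
shrinks within-cluster load to 3 physicians and ~8 patients per
physician-quarter for 500 replicates. Simulation studies use a lean
stage-1 covariate specification (age-band x sex, deprivation, route flags,
comorbidity count); since treatment is unconfounded by construction,
covariate choice affects efficiency only, not bias.

## Known limitations

* Reported second-stage SEs ignore stage-1 sampling noise (see above);
  only the pre-trend tests correct for it.
* Exposure is admission-count based; true patient-level counting would
  require spell reconstruction, which is out of scope.
* CR1 with ~20 treated clusters is approximate; t(G−1) reference degrees
  of freedom are a convention, not exact.
* The linear probability model can predict outside [0, 1]; predictions are
  intentionally left unclipped to keep the estimand linear.
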