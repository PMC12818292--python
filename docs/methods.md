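# Methods

This note documents the models implemented in `olfdyad`, the defaults of the
synthetic-data generator and how they were calibrated, the numerical choices
in the fitting stage, and the limitations of what the synthetic pipeline can
and cannot show.

## 1. Individual observer model

Each m-alternative forced-choice trial is modeled with Gaussian signal
detection. The target alternative draws evidence from `Normal(a, 1)` and
each of the `m − 1` distractors independently from `Normal(0, 1)`; the
observer chooses the argmax. The parameter `a` ("ability") is the mean
evidence advantage of the target in noise-SD units: `a = 0` gives exactly
chance performance (1/m), and accuracy is
`P(correct) = ∫ φ(e − a) Φ(e)^{m−1} de`, the quantity used as the
independent quadrature oracle in the tests.

Confidence is produced by a noisy readout of decision quality: the margin
between the top and runner-up evidence, plus `Normal(0, meta_noise)`
metacognitive noise, binned into (by default) 4 ordinal levels at the
quartiles of the null-margin distribution. `meta_noise = 0` gives maximal
confidence–accuracy coupling; `meta_noise → ∞` makes confidence
uninformative, and confidence-based dyadic aggregation then degrades to the
voting benchmark (a property test).

Distractor evidences are i.i.d.; no inter-odor similarity structure is
modeled, so systematic confusability between particular odors (and
complementary error profiles within a dyad) is outside this model's scope.

## 2. Dyadic aggregation rules

Three rules are implemented as benchmarks (none is a claim about what human
pairs actually do):

- `coin_flip_voting`: agreement stands; disagreement is settled by a fair
  coin. Expected dyad accuracy is exactly the members' mean accuracy, for
  any answer correlation.
- `defer_to_higher_confidence`: disagreement is settled by the more
  confident member (confidence ties by fair coin, logged). With informative
  confidence this beats the better member when abilities are similar.
- `evidence_sum`: argmax of the summed evidence vectors; the ideal-pooling
  upper benchmark. In 2AFC it realizes the weighted-confidence-sharing
  closed form `s_dyad = (s_low + s_high)/√2`, with collective benefit
  crossing 1.00 exactly at sensitivity ratio `√2 − 1`.

## 3. Threshold staircase

The threshold procedure is a two-phase single staircase over 16 dilution
levels (1 = strongest). Initial phase: levels 16, 14, …, 2, 1 are presented,
each repeated after a first correct; two successive corrects record the
first turning point; failing through level 1 terminates with an anosmia
exclusion. Main phase: 2-down/1-up on concentration — two successive
corrects move one level weaker, any incorrect one level stronger — with a
turning point recorded at each direction reversal. The run ends at seven
turning points; `T` is the mean of the last four.

Decisions where the clinical description is ambiguous:

- The direction convention is the standard 2-down/1-up on concentration.
- The initial descent steps by 2 down to level 2, then level 1.
- Boundary rule: two successive corrects at level 16 (or an incorrect at
  level 1) record a turning point at the boundary and hold the level, so
  perfect and never-correct observers terminate with T = 16 or T = 1.
- A main-phase presentation cap (default 60) guards non-termination for
  pathological responders; hitting it yields an `incomplete` flag, never a
  fabricated T.
- The ~30 s inter-trial interval has no computational consequence and is
  not modeled; likewise no solvent-only catch presentations are modeled.

## 4. Synthetic study generator

`generate_study_dataset` produces a full two-day study: 53 day-1
participants, quartile-based matching on day-1 D+I (middle two quartiles
randomly paired as high-similarity dyads; top-quartile members paired with
bottom-quartile members as low-similarity dyads; boundaries at `ceil(n/4)`
and `floor(3n/4)`, ties broken by subject id, odd leftovers dropped with a
warning), 40 returning participants in 20 dyads, and 16 trials per task per
dyad on day 2 with private answers, confidences, joint answers from a
configurable rule (default: confidence deferral), conflict flags, and
conversation counts.

**Abilities.** Latent abilities are Gaussian, truncated at 0 (stated in the
run manifest). Defaults: discrimination `N(1.75, 0.55²)`, identification
`N(2.0, 0.6²)`. These were calibrated once, by quadrature, to put mean
individual accuracy near 0.80 in both tasks, because under independent
observers the conflict probability is
`1 − p₁p₂ − (1−p₁)(1−p₂)/(m−1)`, and accuracy ≈ 0.80 puts the expected
conflict rate at the one-third of trials characteristic of this paradigm
(the generated mean conflict counts are ≈ 5.5 of 16 per task;
`EXPECTED_CONFLICT_BAND = (0.25, 0.45)` is asserted by a test). Day-2
abilities correlate with day 1 at `rho_d = 0.8 > rho_i = 0.6`
(discrimination is the more reliable subtest). A small linear age effect on
identification ability (0.053 ability units/year ≈ 0.16 score points/year)
is on by default; gender has no generative effect. The threshold latent is
drawn correlated 0.5 with discrimination ability and scored by actually
running the staircase. The inter-session gap (mean 40.6 d, SD 23.3) is
manifest metadata only.

**Conversation counts.** Per-trial dyad word totals follow
`λ = (base + b_conflict·conflict + b_task·identification) × dyad-lognormal
× trial-lognormal`, with member counts Poisson at λ/2. Defaults:
base 25 words, conflict effect +47.9, identification effect −11.47,
between-dyad sigma 0.3, within-dyad sigma 0.25. Any overdispersed positive
count model with a within/between decomposition would do; this one was
chosen for simplicity. Confidence-lexicon counts are Poisson with log-link
effects (+1.26 for conflict, −0.35 for identification) on a base rate of
0.6 with a lognormal dyad intercept (sigma 0.15).

**Talkative-wins coupling.** On conflict trials the joint answer is decided
by the aggregation rule; the generator then assigns the two members' word
counts so that the winner is the *more* talkative member with probability
`expit(talkative_wins_logodds)` (default −0.59 → 35.7%), swapping the
member counts when needed. This preserves the confidence-defer joint
decisions (and hence the similarity→benefit structure) while making the
intercept-only clustered logistic model identifiable for the coupling
parameter. Word-count ties are left in place and excluded downstream.

**What the generator does not emulate:** utterance text (only counts),
inter-odor confusion structure, learning or feedback across trials,
discussion duration, non-verbal cues, and any dependence of resolution
success on lexicon content (the lexicon model is generatively null with
respect to accuracy). Passing tests therefore validate the pipeline's
statistical machinery and the qualitative mechanism claims, not any
empirical claim about human conversation content.

## 5. Inference stage

- OLS (statsmodels) with two-sided t tests and 95% CIs; rank-deficient
  designs are rejected.
- Paired baselines by paired t tests; zero-variance difference vectors are
  handled as a degenerate case (t = 0 when the mean difference is 0).
- Random-intercept logistic and Poisson models are fitted by marginal
  maximum likelihood with fixed-node Gauss–Hermite quadrature (151 nodes;
  BFGS with a Nelder–Mead polish; fixed-effect SEs from the observed
  information in β at the estimated random-effect SD, the lme4 convention).
  Setting the random-intercept SD to 0 reproduces the ordinary GLM to
  ≤ 1e-6 (tested), and the fitter agrees with `lme4::glmer` at `nAGQ = 25`
  to ~1e-3 on a reference dataset (tested via Rscript). Suspected complete
  separation (|β| > 15) triggers a weak-ridge refit flagged `penalized`.
- The Gaussian word-count model uses statsmodels `MixedLM` with an explicit
  REML→ML→Powell fallback chain, since REML retries can hit singular
  covariance on some simulated datasets.
- Task-split follow-up models are Holm-corrected and their p-values labeled
  `[corrected]`.
- Bayes factors use the BIC approximation `BF01 = exp((BIC_c − BIC_s)/2)`.
  Note that with ~100–640 rows the BIC penalty makes BF01 for a truly
  absent interaction much larger than values near 1.7 seen at other sample
  sizes; the test suite asserts only `BF01 > 1` under an interaction-free
  generator.
- Metacognition models cluster by subject (individual, isolated decisions);
  all dyad-level models cluster by dyad; random intercepts only, as no
  slope structure is identified at 20 clusters.
- Confidence is treated as a numeric predictor on any ordinal scale.

## 6. Problem sizes and tolerances

Monte-Carlo checks use 3 standard errors at their stated n (10,000 trials
for chance-level accuracy; 100,000+ for the voting and pooling identities).
The parameter-recovery suite generates 100 replicate studies at the default
configuration and requires each sign/coverage check to hold in ≥ 90% of
replicates; the similarity→benefit slope is additionally checked by a sign
test across seeds on 40-dyad sweeps spanning ability ratios in (0, 1].
These sizes keep the full suite within a few minutes on one CPU while
leaving all checks comfortably powered.

## 7. Known limitations

- The Wald CIs of the clustered logistic model run slightly below nominal
  coverage at ~100 observations (the usual small-sample behavior), which
  is why the recovery criterion is set at 90% rather than 95%.
- The non-adaptive quadrature rule loses accuracy for random-effect SDs
  far above ~2 on the link scale; the 151-node default covers the regimes
  that arise here with margin.
- Quartile matching drops unpaired leftovers rather than re-balancing, so
  cohorts with heavily unbalanced quartiles lose a few participants (as a
  53 → 40 cohort does by design).
- The similarity→benefit effect produced by confidence deferral at
  16-trial scores and 20 dyads is real but noisy; at that scale its sign is
  only reliably recovered in aggregate (sign test across seeds), matching
  what a single 20-dyad study can and cannot show.
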