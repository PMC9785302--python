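# Methods

This note records the models, numerical choices and known limitations of
`enosekit`, in the order data flows through the pipeline.

## Synthetic cohort model

The generator emulates a two-region olive-oil study: `n_coa = 36` and
`n_douro = 31` samples, eight volatile chemical classes per sample
(alcohols, aldehydes, alkanes, alkenes, esters, ethers, ketones, terpenes;
mg of internal-standard equivalents per kg of oil), and nine MOS sensors
sampled every `dt = 4 s` for 2.5 min. The time grid is `t = 0, 4, …, 148 s`
(38 points); whether the acquisition window's endpoint is included is an
open convention and 38 points is our committed choice.

**Volatile contents.** Each class content is drawn from
`N(μ_rc, σ_rc)` truncated to a per-class range (intersected with `[0, ∞)`),
where `μ_rc, σ_rc` are the published per-region summaries of the reference
cohort. The truncation ranges bracket the published concentration ranges
for alcohols and aldehydes and default to `[0, μ_max + 4σ_max]` for the
classes with no published range. Truncation keeps contents physical but
shifts the realized moments away from `(μ, σ)` — for Douro aldehydes
(μ = 27.7, σ = 18.0, lower bound 0.41 mg/kg) the realized mean is ≈ 30.1
mg/kg. Tests therefore compare empirical moments against truncated-normal
moments computed by an independent numeric-integration oracle, not against
the nominal parameters. A truncated normal was preferred over a lognormal
because the published summaries are means/SDs, which parameterize it
directly. The per-sample total is the exact class sum (the published Côa
class means reproduce their printed total; the Douro means differ from
their printed total by 0.1 mg/kg, and the class means are treated as
authoritative).

**Transduction.** Sensor `s` responds by a first-order adsorption approach
to steady state,

    R_s(t) = B_s − A_s (1 − e^(−t/τ_s)) + ε,   ε ~ N(0, σ_noise) i.i.d.,

with amplitude `A_s = Σ_k M[s,k] c_k` linear in the class contents. This is
the simplest mechanism consistent with MOS adsorption kinetics; the
reference study reports no curve model, so the transduction is an artifact
of this package, not a reproduction. The sensitivity matrix `M` (ohm per
mg/kg) is random but fixed (entries uniform in `[0.5, 2.0]`, seeded once,
identical for both regions) so that any class separation in the generated
curves arises from concentration differences alone. Baselines (2300–3600 Ω,
typical clean-air magnitudes for TGS-type sensors) exceed the worst-case
amplitude by an order of magnitude; configurations where an amplitude could
reach its baseline are rejected rather than silently clipped (a 1 Ω
positivity floor guards the noise tail only). Time constants τ span
30–50 s so sensors differ in response speed. The default per-reading noise
is `σ_noise = 5 Ω` ("moderate": ≈ 15–20% of the between-region amplitude
difference); "low-noise" analyses in the test suite use 0.5 Ω. One RNG
seeded per cohort drives all draws, so cohorts are bitwise reproducible.

**What the generator does not emulate:** drift and hysteresis of real MOS
sensors, humidity/temperature interference, inter-class correlation of
contents (classes are drawn independently), non-linear or saturating
transduction, and replicate measurement structure. Passing tests therefore
demonstrate correctness of the *analysis chain* under the assumed
generating model, not instrument-level realism.

## Feature extraction

Seven descriptors per sensor and sample: LP (last reading), INT
(trapezoidal integral over the recorded grid, ohm·s), MAX, MIN, SUM, MEAN,
and SD. SD uses the n−1 denominator (chemometrics convention; the choice is
ours). Features are computed on raw resistances without baseline
subtraction or normalization. On a uniform grid the identity
`INT = Δt·(SUM − (first+last)/2)` holds and is asserted as a property test.
Columns are ordered sensor-major (`S1_LP … S1_SD, S2_LP …`).

## Two-group statistics

For each variable: F-test with the larger sample variance in the numerator
and a two-sided p-value `2·min(P(F≤f), P(F≥f))` (the underlying study does
not state sidedness; two-sided is the conservative reading). Variances are
deemed equal when `p ≥ 0.05`, selecting the pooled Student test
(df = n₁+n₂−2) versus Welch's test (Satterthwaite df). Letters "a"/"b"
reproduce the tables' display convention (larger mean gets "a" when
p < 0.05). No multiple-testing correction is applied, matching the original
analysis. A variable that cannot be tested (zero variance in a group)
yields an error-carrying result rather than aborting the whole table.

## PCA

Columns are always mean-centered and by default scaled to unit variance
(correlation-matrix PCA): the variables mix ohms, ohm·seconds and mg/kg, so
autoscaling is the defensible default and is exposed as a flag.
Decomposition is by SVD; each component's sign is fixed so its
largest-magnitude loading is positive, making scores deterministic. A
`separation_score` (leave-one-out nearest-centroid accuracy in the 3-PC
score space) quantifies the visual two-group split of score plots.

## LDA with SA subset selection

Fisher LDA with **equal priors** (balanced treatment of the two regions
regardless of cohort imbalance) and pooled within-class covariance;
prediction is nearest class mean in discriminant space (midpoint threshold
on the single discriminant axis). When the pooled covariance is singular it
is ridge-regularized by `1e-8 · trace/p · I` (absolute `1e-8` if the trace
is zero); a feature constant across the whole table is an error, but zero
within-class spread with distinct means is legitimate, perfectly separating
data. Subset size is capped at n−2 (n−3 inside LOO folds).

LOO-CV refits the discriminant n times; a failing fold is recorded by
sample id, never silently skipped. From the 2×2 confusion matrix
(rows = true class): overall sensitivity = total correct/total;
per-class specificity of one class is the recall of the other; overall
specificity is the class-size-weighted mean of per-class specificities.
The weighting choice is documented because no standard definition
reproduces the reference study's printed 98.4% exactly from its stated
single misclassification; the definition here is fixed and self-consistent.

**Annealer.** State = non-empty feature subset of bounded size; moves add,
drop or swap one feature (uniform over legal moves); Metropolis acceptance
`exp(−ΔE/T)`; geometric cooling `T ← γT` every `steps_per_temp` moves;
several restarts; best-ever state returned; energies memoized per run.
Defaults: T₀ = 0.5, γ = 0.95, 50 steps/temperature, 5000 moves, 3 restarts.
`γ = 0` degenerates to greedy descent, which the tests exercise. The
classification energy is `1 − (sensitivity + specificity)/2 + ε·|subset|`
with ε = 1e-6, so ties break toward parsimony. The reference study states
no schedule; these defaults were sized so that, on pools of ≤ 12 features,
the annealer attains the exhaustively verified optimum in ≥ 95% of seeded
runs.

## MLR with SA subset selection

Ordinary least squares with intercept; rank-deficient designs are rejected
with the offending columns named (greedy QR-growth diagnosis). LOO-CV uses
the exact hat-matrix identity `ŷ₋ᵢ(xᵢ) = yᵢ − eᵢ/(1−hᵢᵢ)` — algebraically
equal to n refits (asserted against an explicit refit loop in the tests)
and cheap enough to sit inside the annealing loop. `loocv_R2` is the
squared Pearson correlation between LOO predictions and observations
(bounded [0,1]); the cross-validated reading is committed because the
reference tables group R² under their LOO-CV heading. The SA energy is the
LOO RMSE with the same parsimony tie-break; the candidate pool is all 63
features, the subset cap defaults to 29, and models are fitted separately
per region. Quantitation targets: alcohols, aldehydes, total.

## Slope/intercept validation

Predictions are regressed on the reference values (reference on x, the
axis convention of predicted-versus-experimental plots). Closed-form simple
linear regression gives `slope ± t(1−α/2, n−2)·SE` and likewise for the
intercept; the method passes when the slope CI contains 1 **and** the
intercept CI contains 0 (two separate intervals, not a joint ellipse —
matching how such validations are reported). Validation uses LOO
predictions, not resubstitution fits, to keep the comparison honest. Note
the joint verdict's type-I rate for a truly unbiased method is above α
(measured ≈ 7% at α = 0.05, n = 30 in the test suite's 10 000-replicate
null simulation), so an occasional failing verdict on a perfect model is
expected behavior, not a defect.

## Pipeline and problem sizes

`run_pipeline` derives per-stage seeds from one top-level seed
(`seed + stage index`), writes every intermediate CSV, and emits a
versioned JSON summary; identical configurations produce byte-identical
summaries. The acceptance script runs the pipeline at the default cohort
size (67 samples) with annealing budgets of 2000 moves × 2 restarts
(classification) and 1500 moves × 2 restarts per quantitation model —
sizes at which repeated runs of the subset search are stable for this
problem while the whole script completes in well under a minute. Test-suite
simulations use smaller cohorts and budgets chosen the same way.

## Known limitations

- The published headline figures (98.5% sensitivity on the real 67 oils,
  R² 0.981–0.998, 82.5–97% PCA variance) depend on raw data that were never
  deposited; this package reproduces the *procedures* and demonstrates them
  on synthetic cohorts with the published group structure. Numbers it
  reports are properties of that generator, not re-measurements of the
  original oils.
- Class contents are sampled independently within a region; real volatile
  classes are correlated, which would change (likely improve) multivariate
  separability relative to the synthetic case.
- The SA wrapper offers stochastic, not guaranteed, optimality for pools
  larger than exhaustive verification allows (the 63-feature pool).
- Only two-class problems are supported in the discriminant module (one
  discriminant function), which is all the study design requires.
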