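# Methods

## Compositional geometry

Time use is analysed as a 7-part composition closed to 1440 min/day. All
statistics are computed in isometric log-ratio (ilr) coordinates defined by a
sequential binary partition (SBP): row *k* of the sign matrix splits a group
of parts into a +1 set (size *r*) and a −1 set (size *s*), giving the balance
z_k = √(rs/(r+s)) · ln(g₊/g₋) with g the geometric means. The induced 6×7
contrast matrix Ψ is validated to be orthonormal (ΨΨᵀ = I to 1e-10) at
construction, and `ilr` computes z = Ψ ln x, which is closure-invariant
because each row of Ψ sums to zero. The default basis is pivot coordinates in
the fixed part order (sleep, screen, physical_activity, quiet,
passive_transport, school, domestic_selfcare). The basis is serialized inside
every fitted model, so predictions always use the basis the model was fit
under; the choice is otherwise immaterial — the quadratic feature space is
invariant under the rotation connecting any two SBPs, so F-tests and
substitution estimates agree across bases (tested to 1e-9). `ilr_inverse`
subtracts the max log-part before exponentiating, so even extreme coordinates
(‖z‖ ≈ 20) return a closed, strictly positive composition.

## Zero replacement

Two regimes, matching how zeros arise:

* **User input** (a single composition entering prediction): every zero part
  is set to 3.25 min — 65% of the 5-minute recall sampling frame — and the
  non-zero parts are shrunk multiplicatively so the 1440-min total is exact.
  Zeros are imputed rather than forbidden.
* **Datasets** (before fitting): zeros are treated as unobserved small
  durations. Each zero entry is imputed at its conditional geometric
  expectation: ln(part) is regressed (OLS with intercept) on the pivot-ilr
  coordinates of the 6-part subcomposition of the remaining parts, over the
  rows where the part was observed, iterating imputation and re-closure to a
  1e-6 relative tolerance (max 50 iterations; convergence is typically
  immediate because imputed entries barely move the regressors). Rows without
  zeros are untouched beyond closure; rows with zeros preserve their total by
  rescaling only the observed parts. With a single row, or fewer than 12
  observed rows for a part, the fixed 3.25-min rule is the fallback. Imputed
  values are *not* capped at the sampling frame: the regression predicts the
  value the part would have taken, which is what keeps downstream coefficient
  estimates unbiased when zeros are random censorings (verified by the
  pipeline-recovery study below).

## Regression model

Each outcome is fit by OLS (statsmodels) on a fixed 35-column design:
intercept; z₁…z₆; z₁²…z₆²; the 15 products z_j z_k in lexicographic order;
then sex (female=1), age (years), socioeconomic z-score, and 4 pubertal
indicators against a pre-pubertal reference. The column order is frozen so
serialized coefficients are unambiguous. Complete cases only; the fit refuses
rank-deficient designs (e.g. an empty factor level) instead of falling back
to a pseudo-inverse. Stored per model: coefficients, the full coefficient
covariance σ̂²(XᵀX)⁻¹, residual df = n − 35, RSS and n. The full covariance
(not just SEs) is required because a substitution CI needs Var(x₁ᵀβ̂ − x₀ᵀβ̂),
which involves every off-diagonal element. Body fat percentage is ln-
transformed before fitting to normalise its right-skewed residuals.

The composition block is tested with a partial F-test against the
covariate-only model on the same rows: F = [(RSS_red − RSS_full)/27] /
[RSS_full/df], df = (27, n − 35). AIC uses the Gaussian convention
n·ln(RSS/n) + 2k with k = 36 (35 mean parameters + variance); the additive
constant is dropped, so only within-data comparisons are meaningful.

The JSON model artifact is versioned and validated on load against a strict
key whitelist — any extra key (in particular record-level arrays) is
rejected — plus symmetry/PSD checks on the covariance and the df = n − 35
identity. Round-trips are bit-exact (Python's shortest-repr floats).

## Substitution inference

A reallocation must net to exactly zero, keep |δ| within a configurable
per-part cap (default 60 min), and leave every part non-negative; violations
raise errors naming the part and shortfall. For identity-scale outcomes the
difference is the linear contrast d = (x₁−x₀)ᵀβ̂ with a t(residual df)
interval — by construction identical to the difference of the two
predictions. For the log-scale outcome the point difference is
exp(ŷ₁) − exp(ŷ₀) and the CI is the MOVER construction: with raw-scale
limits (l_i, u_i) = exp(ŷ_i ∓ t·se_i) and r = corr(ŷ₁, ŷ₀) = x₁ᵀVx₀/(se₁se₀),

    L = θ̂₁ − θ̂₀ − √((θ̂₁−l₁)² + (u₀−θ̂₀)² − 2r(θ̂₁−l₁)(u₀−θ̂₀))
    U = θ̂₁ − θ̂₀ + √((u₁−θ̂₁)² + (θ̂₀−l₀)² − 2r(u₁−θ̂₁)(θ̂₀−l₀))

A null reallocation is special-cased to difference 0 with a zero-width
interval: the raw-scale MOVER radicals do not cancel exactly at θ̂₁ = θ̂₀
(a lognormal's limits are asymmetric), and "no change in, no change out" is
the correct semantics for an interactive tool. Percent differences divide by
the prediction at the *initial* composition (not the sample mean outcome),
consistent with per-user reporting. t rather than normal quantiles are used
throughout — indistinguishable at df ≈ 1637, exact at small n. When a user
supplies only sex and age, the remaining covariates default to ses_z = 0 and
mid-pubertal (the sample mode); covariate terms cancel in linear differences
and enter log-scale differences only through the baseline level.

## Synthetic cohort

The generator emulates the reference cohort of 11–12-year-olds: n = 1685;
compositions logistic-normal on the ilr scale, centred on the published
compositional mean (709.7, 175.0, 116.9, 70.2, 35.8, 129.1, 203.3 min/day)
with diagonal ilr covariance, sd 0.45 (chosen to give realistic day-to-day
spread in the part minutes); covariates sex ~ Bernoulli(0.484 female), age ~
N(12.0, 0.4²), ses_z ~ N(0.20, 0.99²), pubertal status multinomial (9.6,
25.8, 51.0, 13.1, 0.5)%. Outcomes are y = Xβ_true + N(0, σ²) in the model's
own column convention; body fat is generated on the log scale and
exponentiated (σ_log = 0.38, level set to a ~19.9% median), psychosocial has
mean ≈ 77 (σ = 13.5), academic mean ≈ 533.5 (σ = 62, trimmed at ±4 SD in one
pass). True compositional coefficients point along the polynomial-feature
contrast of a 60-min screen→physical-activity swap at the centre, scaled so
that swap reproduces the magnitudes the source analysis reported (≈ −4.2%
body fat, +1.9 psychosocial, +4.5 writing) — this puts genuine weight on the
second-order terms, so starting-composition dependence is real. Intercepts
are set from the closed-form expectation of the design row (E[z_jz_k] =
m_jm_k + S_jk for MVN ilr), so population means hit their targets without
tuning loops. Per-outcome missingness (13, 6, 391 missing at n = 1685,
scaled proportionally at other n) reproduces the published complete-case
sizes, hence residual dfs 1637/1644/1259 arise from complete-case fitting.

Structural zeros are injected by setting a Bernoulli(rate, default 5%)
subset of the low-duration entries (quiet time, passive transport) to zero
and re-closing the row; sleep and other large parts are never zeroed. Zeros
are injected *after* outcomes are generated from the true compositions, so
replacement quality is measurable against the truth. Multi-day recall data
add MVN ilr noise (sd 0.25/day) around each participant's usual composition,
2 weekdays + 1 weekend day, feeding the 5:2 weekly weighting.

What the generator does **not** emulate: real covariance between activities
beyond closure (the ilr covariance is diagonal), covariate–composition
dependence (e.g. sex differences in activity), measurement error in the
recall instrument, or the survey design of the source cohort. Passing tests
therefore demonstrate that the estimators are correct for the model class
they assume, not that the model class captures any particular population.

## Validation studies and problem sizes

`isotemporal.validation` measures operating characteristics by simulation;
the test suite and the acceptance script run the same code. Replicates whose
design is rank-deficient (at n = 500 the 0.5% post-pubertal stratum is empty
in ~8% of draws) are skipped and regenerated — rank depends only on X, so
conditioning on estimability leaves coverage and size exact. Problem sizes:
CI coverage 2000 replicates at n = 500 per construction; partial-F type-I
error 2000 replicates at n = 500; full-pipeline coefficient recovery 200
replicates at n = 1685 with 5% zero injection and regression imputation,
coverage aggregated over all 35 coefficients (a per-coefficient rate over
200 replicates has ±1.5% binomial noise, too wide to test individually);
contrast-SE Monte-Carlo check 100 000 draws from MVN(β̂, V).

## Known limitations

* The dataset zero-replacement scheme is a deliberately simple iterated
  regression imputation, not a full censored-likelihood EM; it targets the
  conditional expectation of the *value*, not of a value below a detection
  limit, and is appropriate when zeros are (near-)random censorings of small
  durations.
* One fixed 35-column design: no covariate×composition interactions, mixed
  effects, survey weights, or covariate imputation.
* The MOVER interval is approximate; its coverage is verified by simulation
  at the SE magnitudes this application produces, not proven globally.
* Percent differences are undefined at a zero baseline prediction (possible
  in principle for identity-scale models) and raise an error.
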