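# Methods

## Data model and assumptions

A subject in group `j` carries a latent event time `X_j` with CDF `F_j`, a
truncation (entry) time `U_j` and a censoring time `C_j`. The pair
`(U_j, C_j)` is independent of `X_j`, `U_j` and `C_j` may depend on each
other, and `P(U_j ≤ C_j) = 1`. Only subjects with `U_j ≤ X_j` are observed,
and for those the record is `(U, Y, Δ)` with `Y = min(X, C)`,
`Δ = I[X ≤ C]`; the assumption `P(U ≤ C) = 1` makes `U ≤ Y` automatic.
The tested hypothesis is `H0: F_1 = … = F_k` against any difference on the
identifiable window. Identifiability requires the support of `U_j` to start
at or before that of `X_j` and to end at or before that of `Y_j`; no
difference to the right of the smallest per-group upper support bound of
the *uncensored* observations can be detected by any method.

The bootstrap additionally assumes the residual censoring time
`D_j = C_j − U_j` is independent of `(U_j, X_j)` on the observable region.
This is what makes `Q_j = P(D_j ≤ ·)` estimable by a plain Kaplan–Meier
estimator on `(Y − U, 1 − Δ)` even though the censoring distribution itself
is not identifiable when `U` and `C` are dependent.

## Estimators

* **Event-time CDF** `F̂_j`: product-limit over the distinct uncensored
  times, `1 − Π (1 − d_i/r_i)`, with the *inclusive* risk-set convention
  `U ≤ t ≤ Y` on both sides. This differs from R's `survfit`, which uses
  strict inequalities and refuses records with `U = Y`; with continuous
  data the two agree, with ties they do not, and the inclusive convention
  is the one under which all hand-checked examples in the test suite hold.
* **Hole correction** (`hole_correction=True`, the package-wide default):
  `d_i/r_i → d_i/(r_i + 1)`. A unitary risk set otherwise zeroes the
  survival estimate from that time on, which both distorts the statistics
  in small samples and starves the bootstrap of resampling atoms. The
  corrected estimator is always defective (total mass < 1) and is
  pointwise dominated by the uncorrected one (a tested invariant).
* **Truncation CDF** `Ĝ_j`: weights `∝ 1/Ŝ_j(U_l)` on the distinct entry
  times, normalised to a proper CDF. `Ŝ` is evaluated right-continuously
  when an entry time ties an event time. The hole-corrected `Ŝ` guarantees
  the weights exist; feeding an uncorrected fit with a hole at or before an
  entry time raises a dedicated error.
* **Nontruncation probability** `γ̂_j = n_j (Σ_l Ŝ_j(U_l)^{-1})^{-1}` —
  the normalising constant of `Ĝ_j` (harmonic-mean-of-survival form).
* **Residual censoring CDF** `Q̂_j`: Kaplan–Meier on `(V_l, 1 − Δ_l)` with
  `V_l = Y_l − U_l`. At tied residual times D-events precede D-censorings
  (the standard KM tie rule). Any remaining mass is moved to the largest
  residual time so the estimate is proper and directly samplable.

## Test statistics

`D_KS = sup_t Σ_j n_j (F̂_j − F_n)²` and
`D_CvM = Σ_t Σ_j n_j (F̂_j − F_n)² ΔF_n(t)` with `F_n = Σ p_j F̂_j`.
Because every `F̂_j` is a step function jumping only at its group's
uncensored times, both statistics are computed exactly on the union of
those times, which is precisely the window `[â, b̂]` between the smallest
and largest pooled uncensored times; a dense-grid sweep can never beat the
atom grid (tested). The merged-sample product-limit fit is *not* used for
`F_n`: under group-specific truncation/censoring it is inconsistent for
the mixture. Default weights are `p_j = n_j/n`; any strictly positive
probability vector may be supplied (e.g. `1/k`).

For `k = 2` both statistics reduce exactly to
`(n₁p₂² + n₂p₁²)` times the classical two-sample quantities; the test
suite verifies the identity to 1e-10 on 100 random LTRC datasets.

The weighted log-rank family uses the pooled distinct event times,
per-group hypergeometric increments `d_ji − d_i r_ji/r_i`, weights
`S̃(t_{i−1})^p F̃(t_{i−1})^q` from the hole-corrected product-limit fit of
the combined sample (before the first event `S̃ = 1`, `F̃ = 0`, with
`0⁰ = 1`), and the standard k-sample covariance with the
`(r_i − d_i)/(r_i − 1)` tie factor, dropping unit-risk-set terms. The
chi-square statistic is the quadratic form over the first `k − 1`
components; a singular covariance falls back to a pseudo-inverse and flags
the result. p-values are asymptotic upper chi-square tails — the bootstrap
is reserved for the omnibus statistics. The implementation agrees with R's
`survival::coxph` score test on LTRC data to four decimals and with
lifelines' `multivariate_logrank_test` on untruncated data to 1e-8.

## Bootstrap null distribution

One resampled record for slot group `j` is produced by drawing, in order, a
group index `j* ~ (p_1..p_k)`, `U ~ Ĝ_j`, `X ~ F̂_{j*}`, `D ~ Q̂_j`,
accepting when `U ≤ X` (ties accepted), and recording
`(U, min(X, U + D), I[X ≤ U + D])`. Drawing `X` from a freshly selected
group imposes the null; keeping `Ĝ_j`/`Q̂_j` group-specific preserves each
group's truncation and censoring mechanisms. p-values are
`(1/B) #{b : D^b ≥ D⁰}`.

Numerical choices:

* Sampling from a step CDF is inverse transform on its atoms. A defective
  `F̂` is made proper by assigning the deficit to its largest atom before
  sampling (Efron's convention); `Q̂` is proper by construction.
* Draws are batched: each batch draws group indices, then `U`, `X`, `D`
  for all pending records from one shared generator, rejected records
  re-enter the next batch. Results are bit-for-bit reproducible for a given
  seed (tested); the attempt budget (1e6 per record) turns near-disjoint
  `Ĝ`/`F̂` supports into a clear error instead of a hang.
* Under extreme censoring a resample can contain a group with no events;
  its product-limit fit is then the empty step function `F ≡ 0`, which the
  statistics handle (an all-empty replicate contributes zero statistics).

## Monte Carlo engine

The scenario catalogue encodes fifteen three-group designs by their latent
`(X, U, D)` distributions. Conventions: `Exp(λ)` has mean `1/λ`; `W(a, b)`
is Weibull with shape `a`, scale `b`; `N(μ, σ²)` takes mean and variance;
compound variables E1/E2/L2 keep a base draw below a switch threshold
(6, 6, 10) and otherwise substitute a uniform tail draw (U(6,10),
U(6,10), U(10,16)); their bases are N(5.5, 2), Exp(0.1527), Exp(1/10).
Group samples are produced by batched rejection on `U ≤ X` with a 1e8
attempt cap (the smallest catalogued nontruncation probability is 0.50).

`theoretical_gamma` returns `γ_T = P(U ≤ X)` (closed form for
normal–normal and exponential–exponential pairs, Monte Carlo otherwise)
and the noncensoring probability under *both* conventions — conditional
`P(X ≤ C | U ≤ X)` and unconditional `P(X ≤ U + D)` — because the two
differ and catalogued reference values mix the conventions; only `γ_T` is
used quantitatively downstream.

Rejection-proportion studies use warp-speed Monte Carlo: each trial
simulates the `k` samples, computes the observed statistics and exactly one
H0 bootstrap replicate; the trial's p-value is the fraction of all `M`
pooled replicate statistics at or above its observed statistic (its own
replicate included, `≥` comparison matching the p-value definition), and
the rejection proportion is the fraction of trials with p-value below `α`.
Rank tests use their per-trial chi-square p-values. One master seed spawns
an independent stream per trial, so cells are reproducible and
embarrassingly restartable. Warp-speed agrees with the per-trial full
bootstrap (B=199) to within 0.03 under the null at `n_j = 100` (tested);
at small samples under heavy truncation it is mildly anti-conservative
relative to the full bootstrap (about one point of level at `n_j = 100`
with `γ_T = 0.5`), which is the expected finite-sample price of pooling
conditional null distributions across trials.

Default study sizes in the acceptance suite: M = 5000 trials for
calibration and the `n_j ≤ 200` power cells, M = 1000 for the
`n_j = 500` log-rank cell — sizes at which the binomial standard error
(≈ 0.003–0.007) is small against the effects of interest.

## Synthetic demo fixture

`fixture_unemployment_like` emulates the *shape* of a three-group
unemployment-duration survey — group sizes (246, 413, 350), roughly half
the population lost to truncation, ~80% censoring — with a single common
mechanism: durations Exp(mean 12 months), entry U(0, 22) months, residual
censoring U(0, 6) months. It is purely synthetic (all three groups share
one distribution, so it is a null dataset); it reproduces no real
measurements and supports CLI demos and integration tests. What passing
tests on catalogue data and this fixture do *not* show: robustness to
dependence between censoring and survival (competing-risk withdrawal),
covariate effects, or discrete/heavily tied real-world time scales beyond
the tie rules stated above.

## Known limitations

* The omnibus tests cannot detect differences to the right of the smallest
  per-group upper bound of the uncensored-time support; that is a property
  of the identifiable window, not of the implementation.
* Warp-speed levels at `n_j ≈ 100` under strong truncation run about one
  point above nominal (see above); the per-trial full bootstrap
  (`bootstrap_pvalues`) is the reference for data analysis.
* Quasi-independence of `(U, X)` and the residual-censoring independence
  assumption are *assumed*, not tested; diagnostic tests for them are out
  of scope.
* No post-hoc pairwise machinery: a rejection says at least two groups
  differ, not which ones.
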