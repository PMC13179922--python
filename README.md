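# ltrcks — omnibus k-sample tests for left-truncated, right-censored data

Survival studies often need to decide whether a time-to-event variable
follows the same distribution in `k ≥ 2` populations when the data suffer
from **left truncation** (a subject enters the study at a random time `U`
and is observed only if its event time `X` satisfies `U ≤ X`) and **right
censoring** (only `Y = min(X, C)` and `Δ = I[X ≤ C]` are recorded).
Rank-based tests such as the log-rank are the usual tool, but they are
directional: there are alternatives — crossing hazards, local vertical gaps
— against which they have essentially no power.

`ltrcks` implements omnibus Kolmogorov–Smirnov and Cramér–von Mises type
statistics for this setting, together with the bootstrap machinery needed to
calibrate them, a weighted log-rank comparator family, and a Monte Carlo
engine for calibration/power studies. It is aimed at biostatisticians and
econometricians working with delayed-entry cohort or cross-sectional
duration data.

## The statistics

Each group's event-time CDF is estimated by the product-limit
(Tsai–Jewell–Wang) estimator

    F_j(t) = 1 − Π_{x_i ≤ t} (1 − d_i / r_i),

with risk sets `r_i = #{l : U_l ≤ x_i ≤ Y_l}` (inclusive on both sides).
By default the package uses the `d_i/(r_i + 1)` variant, which keeps the
estimated survival positive when a risk set is unitary (a "hole"). With the
pooled estimate `F_n = Σ_j p_j F_j` (weights `p_j = n_j/n` by default), the
test statistics are

    D_KS  = sup_t Σ_j n_j (F_j(t) − F_n(t))²
    D_CvM = Σ_j n_j ∫ (F_j(t) − F_n(t))² dF_n(t)

evaluated over the window spanned by the pooled uncensored event times.
p-values come from the *obvious bootstrap*: truncation times are redrawn
from each group's estimated `Ĝ_j`, residual-censoring times `D = C − U`
from each group's Kaplan–Meier estimate `Q̂_j`, and — imposing the null —
event times from the `F̂` of a freshly drawn group index with probabilities
`p_1..p_k`, keeping only draws with `U ≤ X`.

The weighted log-rank family `W(t_i) = S̃(t_{i−1})^p F̃(t_{i−1})^q` (LR,
LR_E, LR_M, LR_L for `(p,q)` = (0,0), (1,0), (0.5,0.5), (0,1)) is included
for comparison, with asymptotic chi-square p-values.

## Worked example

The built-in synthetic fixture mimics a three-group unemployment-duration
study (durations in months, ~50% of the population lost to truncation,
~80% censoring):

```python
import ltrcks as lk

samples = lk.fixture_unemployment_like(7)
res = lk.bootstrap_pvalues(samples, B=500, rng=7)
ranks = lk.weighted_logrank_suite(samples)

print(f"D_KS = {res.d_ks:.4f}, p_KS = {res.p_ks:.4f}")
print(f"D_CvM = {res.d_cvm:.4f}, p_CvM = {res.p_cvm:.4f}")
for name, r in ranks.items():
    print(f"{name}: chi2 = {r.chi_square:.4f}, p = {r.p_value:.4f}")
for s in samples:
    print(s.label, s.n, "gamma_hat =", round(lk.estimate_nontruncation(s), 4))
```

prints

```
D_KS = 9.5516, p_KS = 0.1040
D_CvM = 3.5157, p_CvM = 0.0800
LR: chi2 = 0.2603, p = 0.8780
LR_E: chi2 = 1.3832, p = 0.5008
LR_M: chi2 = 0.0299, p = 0.9851
LR_L: chi2 = 0.1942, p = 0.9075
none 246 gamma_hat = 0.3891
one 413 gamma_hat = 0.4874
two_plus 350 gamma_hat = 0.5043
```

The three groups share one generating mechanism, so none of the tests
rejects at the 5% level: `p_KS`/`p_CvM` are the fractions of the 500
bootstrap replicate statistics at or above the observed ones, and
`gamma_hat` estimates each group's nontruncation probability `P(U ≤ X)` —
here about one half, i.e. truncation discarded half of the population.

The same analysis is available from a shell:

```sh
ltrcks fixture --out demo.tsv --seed 7
ltrcks test --input demo.tsv --B 500 --seed 7 --out report.json
ltrcks simulate --scenario 11 --sizes 100,100,100 --M 500 --seed 1 --out study.tsv
```

## Simulation studies

`ltrcks.scenario_catalog()` holds fifteen three-group scenarios (six null,
nine alternatives — proportional hazards, stochastic ordering, crossing
hazards, early/late differences) with known nontruncation and noncensoring
probabilities. `ltrcks.warp_speed_study()` estimates rejection proportions
using one bootstrap replicate per Monte Carlo trial, pooling the replicates
across trials into the null reference distribution, which makes
thousand-trial studies run in seconds.

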