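# Methods

## The testing problem

Given $k$ p-values $P_1,\dots,P_k$ for individual null hypotheses
$H_{i,0}$, the package tests the global null $H_0=\bigcap_i H_{i,0}$
against $H_1=\bigcup_i H_{i,1}$.  Under $H_0$ each $P_i\sim U(0,1)$, but
the $P_i$ may be arbitrarily dependent — the typical situation for
gene- or set-based association tests, and for meta-analyses where
one-sided p-values in both directions are derived from the same
statistics.

## The combiners

**Cauchy combination (CCT).**  Each p-value is mapped to the standard
Cauchy scale, $T_i=\tan[(0.5-P_i)\pi]$, and combined as
$T=\sum_i w_i T_i$ with $w_i\ge 0$, $\sum_i w_i=1$ (equal weights by
default).  The combined p-value is $P[C(0,1)\ge T]$.  Under
independence a convex combination of standard Cauchy variables is
standard Cauchy, so the combined p-value is *exactly* uniform; under
dependence the heavy tail still yields asymptotic type-I control at
small levels.  Two structural facts shape everything else:

* $P_{(1)}\le p_{CCT}\le P_{(k)}$ — the combination can never provide
  stronger evidence than its best input;
* a complementary pair $\{p, 1-p\}$ has cancelling transforms, so
  $p_{CCT}=1/2$ regardless of $p$: combining left- and right-sided
  p-values from the same statistic leaves the CCT powerless below
  $\alpha=1/2$.

**MinP.**  Based on $P_{(1)}$, calibrated by Šidák,
$1-(1-P_{(1)})^k$ (exact under independence), or Bonferroni,
$\min(1, kP_{(1)})$ (valid under arbitrary dependence).  Defaults:
Šidák when combining independent p-values, Bonferroni inside the
two-stage tests and for dependent pairs.

**MCM (MinP-CCT-MinP)** applies CCT and MinP to the same input and
Bonferroni-combines them: $p_{MCM}=2\min\{p_{CCT},p_{MinP},1/2\}$.

**CMC (CCT-MinP-CCT)** combines the pair with an equal-weight CCT:
$p_{CMC}=CCT\{p_{CCT},p_{MinP}\}$.

Both inherit small-level type-I control from their ingredients and hedge
between the regimes where CCT (many small, positively associated
p-values) or MinP (one strong signal, or mixed directions) dominates.

**Fisher and Stouffer** are provided for the independent stage of the
meta-analysis pipeline: $X^2=-2\sum\ln P_i\sim\chi^2_{2k}$ and
$Z=\sum\Phi^{-1}(1-P_i)/\sqrt{k}$.

## Numerical choices

* The Cauchy transform is evaluated as $\cot(p\pi)$ for $p<1/2$ and
  $-\cot((1-p)\pi)$ for $p>1/2$ (0 at $p=1/2$) — exactly equivalent to
  the tangent form but accurate to a few ulp across the whole interval,
  including $p=10^{-300}$, where the direct tangent loses several digits
  near its pole.  The Cauchy upper tail is inverted as
  $\arctan\!2(1,t)/\pi$, which avoids cancellation for large $|t|$;
  a single p-value round-trips through CCT with relative error below
  $10^{-6}$ down to $10^{-300}$ (property-tested).
* $p=1$ is clipped to $1-10^{-15}$ before transforming (the transform is
  $-\infty$ in the limit); $p\le 0$ is a domain error everywhere — a zero
  p-value already falsifies the global null and callers must clip
  explicitly if they mean "very small".
* Šidák uses `-expm1(k*log1p(-p))`; Stouffer uses $-\Phi^{-1}(P_i)$
  instead of $\Phi^{-1}(1-P_i)$ so small p-values keep full precision.
* One-sided pairs are constructed as (smaller tail, 1 − smaller tail),
  so `p_left + p_right == 1` holds exactly in doubles.  The complementary
  cancellation ($p_{CCT}=1/2$) then holds to ~$10^{-10}$ for $|z|\le 5$
  and degrades as the larger member becomes indistinguishable from 1
  (|z| beyond ≈ 6.5, where the deviation for a positive effect is toward
  1, i.e. conservative).  This is an information limit of
  double-precision p-values, not of the algorithm.
* Rejection uses $p\le\alpha$; at the levels studied the boundary has
  negligible mass but the convention is fixed.

## Correlation models and sampling

Three $k\times k$ correlation families drive the simulations:
AR(1) (`expo`, $\sigma_{ij}=\rho^{|i-j|}$, $\rho\in[0,1)$), polynomial
decay (`poly`, $\sigma_{ij}=1/(0.7+|i-j|^r)$, unit diagonal, $r>0$), and
a singular family (`sig`): $A$ is the $k/5\times k$ matrix with
$a_{ij}=d^{|i-j|}$, $d\in(0,1)$, and $\Sigma$ is $A^TA$ rescaled to unit
diagonal, giving rank exactly $k/5$.  Two consequences of that
construction are worth knowing: at $k=5$ it degenerates to the all-ones
matrix (perfect correlation, under which every combiner reduces to a
function of one uniform p-value and CCT is exactly calibrated), and the
`poly` family is not positive definite for every $(k,r)$, so
eigenvalues are validated at construction and failures raise rather than
being silently repaired.

Sampling always factorizes $\Sigma=B^TB$ via symmetric
eigendecomposition with eigenvalues in $[-10^{-8}\lambda_{max},0)$
clipped to zero — one code path for the definite and singular families
(Cholesky would reject the latter).  A sample-correlation recovery test
(200k draws, max absolute deviation < 0.01) pins the factorization.

## Simulation design

Defaults mirror the study conditions: $10^6$ replicates for type-I
tables, levels $\{0.05, 0.01, 0.001, 10^{-4}\}$, left-sided p-values,
$k\in\{5,10,20,100\}$ with $\rho=0.5$, $r=1.5$, $d=0.5$, Šidák MinP.
Under the alternative, `n_significant` coordinates receive mean
$\pm\mu$ with `n_negative` of them negative (the mixed-direction case
that separates MinP from CCT; the reference power setting is $k=20$,
10 significant, $\mu=2$).  Which coordinates are shifted matters under
structured correlation, so placement is explicit: the leading block
(default, deterministic), evenly spread, or a seeded random subset.

Replicates are processed in fixed chunks of $10^5$ with one
`SeedSequence`-spawned substream per chunk: memory stays bounded
(~160 MB at $k=100$) and results are bit-reproducible for a given seed
and chunk size.  Chunk size is a documented constant, not a
memory-adaptive value, precisely so it never silently changes results.

The Monte-Carlo generator emulates correlated z-scores with Gaussian
dependence only.  It does not emulate non-Gaussian tails, estimated
(noisy) correlation structures, or p-values from discrete tests, so
passing calibration here demonstrates correctness of the combiners and
their stated null behaviour, not robustness to those real-data features.

## Meta-analysis pipeline

Per study, $z=\ln(OR)/(\ln(U/L)/3.92)$ recovers the log-scale z-score
from a 95% CI; an alternative `midpoint` formula
($1.96\ln(UL)/\ln(U/L)$) replaces $\ln OR$ with the CI midpoint, which
differs slightly when the published OR is rounded — `log_or` is the
default.  Stage 1 combines the independent left/right/two-sided p-value
sets with MinP (Šidák), Fisher, and Stouffer; stage 2 combines each
method's dependent (left, right) pair with CCT, MinP (Bonferroni), MCM,
and CMC.  Stage 2 always consumes unrounded stage-1 values: the second
Cauchy stage amplifies perturbations of its inputs (the CMC output can
move by ~0.03 when inputs are rounded to 4 dp), so report rounding is
strictly a formatting step.  Stage-1 combiners are identities at $k=1$,
so a single-study table degenerates gracefully.

## Known limitations

* Combined p-values inherit the resolution of their inputs; below
  ~$10^{-15}$ the Bonferroni-style doublings and Šidák map are exact in
  expectation but the inputs themselves rarely deserve that precision.
* The CCT's anti-conservatism at large $\alpha$ (ratios ~1.1–1.2 at
  $\alpha=0.05$ under positive dependence) is real and expected; its
  guarantee is asymptotic in the tail.
* The singular model's published behaviour at larger $k$ is sensitive to
  construction details; only the construction defined above is
  implemented, and its measured calibration (not external table values)
  is what the non-acceptance suite asserts.
* No weights estimated from data; no copulas or non-Gaussian dependence;
  no pooled-OR or heterogeneity estimation in the meta pipeline.
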