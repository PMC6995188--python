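# Methods

## Setting and model

`polyarm` designs fixed-sample multi-arm trials in which K experimental
treatments (K ≤ 5) are each compared with a shared control arm.  Outcomes
X_ik accrue from n_k patients on arm k ∈ {0, …, K}, arm 0 being control.
The hypotheses are one-sided superiority tests

    H_k : τ_k ≤ 0,   k = 1, …, K,

with τ_k the treatment effect of arm k versus control.  Each H_k is
tested with a Wald statistic z_k = τ̂_k √I_k, where I_k is the information
level of the contrast, and converted to a p-value p_k = 1 − Φ(z_k).

Two outcome families are supported:

* **Normal, known variances.**  X_ik ~ N(μ_k, σ_k²) with the σ_k known.
  τ_k = μ_k − μ_0, I_k = 1/(σ₀²/n₀ + σ_k²/n_k).  The arm means never
  enter: the law of (Z_1, …, Z_K) depends only on the contrasts, so they
  are not inputs.  In this family the MVN law below is exact.
* **Bernoulli.**  X_ik ~ Bern(π_k), τ_k = π_k − π_0,
  I_k = 1/(π₀(1−π₀)/n₀ + π_k(1−π_k)/n_k).  The information depends on
  the unknown rates, so design-stage calculations plug in the rates
  assumed by the effect scenario, while the trial simulator uses the
  analysis-stage plug-in with estimated rates.  The MVN law is only
  asymptotic here (see *Limitations*).

Jointly, Z = (Z_1, …, Z_K) is (asymptotically) multivariate normal with
E(Z_l) = τ_l √I_l, unit variances, and Cov(Z_i, Z_j) = √(I_i I_j)·v₀/n₀,
where v₀/n₀ is the control-arm variance contribution (σ₀²/n₀, or
π₀(1−π₀)/n₀).  Because the only source of dependence is the shared
control estimate, the correlation matrix always has the **one-factor**
form Cov(Z_i, Z_j) = c_i c_j with c_l = √(I_l v₀/n₀) ∈ (0, 1).

## Multiple-comparison corrections

Nine corrections (plus no correction, which controls the per-hypothesis
error rate to α) are represented by a threshold vector γ_1 ≤ … ≤ γ_K and
a rule family:

| correction | family | γ_k |
|---|---|---|
| none | single-step | α |
| Bonferroni | single-step | α/K |
| Šidák | single-step | 1 − (1−α)^{1/K} |
| Dunnett | single-step | 1 − Φ(z_D), α = 1 − Φ_K(z_D·1; 0, Cov Z) |
| Holm–Bonferroni | step-down | α/(K+1−k) |
| Holm–Šidák | step-down | 1 − (1−α)^{1/(K+1−k)} |
| step-down Dunnett | step-down | 1 − Φ(z_{Dk}), (K+1−k)-dim. Dunnett equation |
| Hochberg | step-up | α/(K+1−k) |
| Benjamini–Hochberg | step-up | kα/K |
| Benjamini–Yekutieli | step-up | kα/(K·Σ_{i≤K} 1/i) |

Step-down rules rank p-values ascending, find the smallest rank whose
p-value exceeds its threshold and reject all strictly lower ranks; this
classical (Holm) form is the one with strong familywise-error control.
Step-up rules reject up to and including the largest rank whose p-value
meets its threshold.  The step-down Dunnett correction requires
exchangeable correlations (equal c_l) and refuses other configurations.
Dunnett-type critical values are obtained by bracketed Brent root solves
(|z| ≤ 10, tolerance 1e-10) on MVN rectangle probabilities, and are
calibrated to the **global-null covariance** (Bernoulli: all rates π₀) —
this is what makes FWER_I1 = α hold exactly under H_G; the null
correlation depends on the allocation ratios only, not on n₀, so the
thresholds stay fixed during sample-size searches.

## Exact computation of the rejection-set distribution

All operating characteristics derive from the distribution of the set S
of rejected hypotheses.  Exploiting the one-factor structure,
Z_l = η_l + c_l X₀ + √(1−c_l²) ε_l with X₀, ε_l i.i.d. N(0,1):

* **Single-step rules.**  P(S) is a rectangle probability; conditional
  on X₀ the coordinates are independent, so each rectangle is a 1-D
  Gauss–Hermite integral of a product of univariate normal CDFs.
* **Step-wise rules, K ≤ 3.**  The sample space is partitioned on the
  K! orderings of the statistics and the stop index m of the procedure
  (number of rejections).  Each (ordering, m) cell is a "staircase"
  region {y_1 ≥ y_2 ≥ …} with per-rank constant bounds; because the
  thresholds are monotone in rank, the nested integration limits never
  cross and every integrand stays smooth, so fixed Gauss–Legendre rules
  converge spectrally.  Cells are evaluated by nested quadrature
  (innermost level in closed form) under the X₀-conditional law.
* **Step-wise rules, K ∈ {4, 5}.**  The K!·(K+1) cell count and the
  nesting depth make exact integration expensive, so a deterministic
  quasi-Monte-Carlo evaluation of the rejection rule is used instead:
  2^18 scrambled-Sobol points (fixed scrambling seed, so results are
  reproducible), transformed through the one-factor representation.  A
  runtime warning is emitted, mirroring the long-execution caveat such
  designs carry.

Numerical choices: Gauss–Hermite 72 nodes for the shared factor,
Gauss–Legendre 56 nodes per ordered rank, tails truncated at 8.5
conditional SDs.  Under stress configurations (loadings c ≈ 0.95–0.99,
means up to |η| ≈ 10) the total mass of all cells deviates from 1 by
~1e-9.  Computed distributions are clipped at 0 and renormalised if the
total is within 1e-6 of 1; a larger drift raises an error rather than
returning silently wrong probabilities.  scipy's Genz MVN CDF is used in
the test suite as an independent oracle for the same quantities, never
as the implementation.

## Operating characteristics

With V = rejections of true nulls, T = non-rejections of false nulls,
R = |S|, and H_k counted true iff τ_k ≤ 0 (the boundary belongs to the
null): conjunctive power P(R = K); disjunctive power P(R ≥ 1); marginal
powers P(k ∈ S); PHER = E V / K; FWER_Ia = P(V ≥ a) and
FWER_IIa = P(T ≥ a) for a = 1…K; FDR = E[V/max(R,1)];
FNDR = E[T/max(K−R,1)]; pFDR = FDR / P(R > 0); sensitivity
= E[R−V]/#false nulls; specificity = E[#true nulls − V]/#true nulls.
Where a denominator is structurally zero (sensitivity under H_G,
specificity under H_A, pFDR when P(R>0) = 0) the quantity is reported as
NaN rather than a conventional value.

## Sample size and allocation

Sample size controls one of three power types to 1−β: conjunctive or
disjunctive power under the global alternative H_A (all τ_k = δ₁), or
the minimum marginal power under the least favourable configurations
LFC_k (τ_k = δ₁, τ_l = δ₀ for l ≠ k).  With ratios fixed, power is
monotone in n₀; the solver brackets geometrically from n₀ = 1 (verifying
monotonicity empirically and erroring on violation), then Brent-solves to
xtol 1e-8, capped at n₀ = 1e7.  Requesting integer sizes rounds every arm
up, recalibrates Dunnett-type thresholds to the rounded ratios, and
reports the achieved power of both the continuous and integer designs.

Allocation ratios r_k = n_k/n₀ are either explicit or optimal under A-,
D- or E-optimality of the design's information matrix, evaluated at unit
total sample size (the fixed-total convention).  A-optimality has the
closed form r_k = √(v_k/(K v₀)) — Neyman allocation at K = 1 and the
1/√K control-weighting rule for equal variances — verified against a
numerical optimiser; D and E are solved by Nelder–Mead over log-ratios
with multiple restarts (E's smallest-eigenvalue objective is non-smooth,
hence the restarts), cross-checked in tests by an independent Powell
optimiser from random starts.  Bernoulli optimal allocation needs
assumed response rates; if none are given, π₀ and π₀+δ₁ are used.

## Simulator and validation

The simulator draws sufficient statistics per replicate (arm sample
means, or binomial counts), forms τ̂ and the analysis-stage information —
Bernoulli: plug-in estimated rates with a (x+0.5)/(n+1) continuity
adjustment inside the information when an arm shows 0 or n responses —
applies the correction, and tallies all eleven quantities with per-field
Monte-Carlo standard errors.  It is deterministic given its seed.

`validation_sweep` draws random valid design specifications (documented
ranges: α ∈ [0.01, 0.2], β ∈ [0.1, 0.3], δ₁ ∈ [0.1, 1], δ₀ ∈ [−0.1, 0],
σ ∈ [0.5, 2], ratios ∈ [0.5, 2], K ∈ {2, 3}, all ten corrections, all
three power types; step-down Dunnett scenarios use the exchangeable
configuration it requires), solves each design, and compares analytic
operating characteristics with 100,000-replicate empirical estimates
under H_G, H_A and every LFC_k.  By default scenarios use normal
outcomes, for which the analytic route is exact and any difference is
pure Monte-Carlo noise; at 100 scenarios the observed global maximum
difference is ~3–6×10⁻³ depending on the seed — the extremum of several
thousand comparisons whose individual standard errors are ~1.5×10⁻³ at
10⁵ replicates, so its typical value sits near 3.5 standard errors.
Bernoulli scenarios can be included
explicitly; their differences additionally contain the genuine
O(n^{-1/2}) normal-approximation error of the method (≈1×10⁻² at
n ≈ 100–350 per arm), so they measure the asymptotic regime rather than
the implementation, and scenarios with fewer than 100 patients on an arm
are redrawn as outside the method's intended operating regime.

## What the generator emulates, and what it does not

Simulated trials draw exactly the sufficient statistics the analysis
uses, under the stated parametric models with known variances and fixed
sample sizes.  Real trials add features deliberately out of scope here:
unknown variances (t rather than z statistics), dropout and staggered
accrual, non-normal/overdispersed outcomes, interim looks.  Passing
validation therefore certifies the internal consistency of the analytic
integration and the test pipeline under the design model, not robustness
to violations of that model.

## Known limitations

* Bernoulli designs rest on the asymptotic normality of the Wald
  statistic; for small arms (tens of patients) attained error rates can
  deviate from nominal by ~0.01 — the simulator exists precisely to
  quantify this for any concrete design.
* Step-down Dunnett supports exchangeable correlation structures only.
* K is capped at 5; step-wise corrections at K ∈ {4, 5} are evaluated by
  deterministic QMC with absolute accuracy ~5×10⁻⁴ rather than exactly.
* Time-to-event outcomes and adaptive designs are not supported.
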