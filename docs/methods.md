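# Methods

## The estimation problem

Two-sample MR treats per-SNP GWAS associations as instrumental-variable
moments: if SNP *j* has effect `bx_j` (SE `sex_j`) on the exposure in one
study and `by_j` (SE `sey_j`) on the outcome in another, and the three IV
assumptions (relevance, independence from confounders, exclusion
restriction) hold, then every ratio `by_j / bx_j` estimates the same causal
effect. Two-step mediation decomposes a total effect βc (exposure→outcome)
into βa·βb (exposure→mediator times mediator→outcome-given-exposure) plus
a direct effect; βb must come from *multivariable* MR so that the mediator
coefficient is conditional on the exposure.

All confidence intervals in the package are Wald-type, `beta ± 1.96·se`,
and all p-values are two-sided normal except Cochran's Q (upper chi-square
tail). Effects on binary traits are log-odds ratios; `exp(beta)` is
reported as the OR.

## Univariable estimators

* **IVW** — weighted least squares of `by` on `bx` through the origin with
  weights `1/sey²`; fixed-effect SE `1/√Σ(bx²/sey²)`. The random-effects
  variant uses multiplicative overdispersion: the fixed SE is scaled by
  `max(1, √(Q/df))`, so it can never be smaller than the fixed SE and the
  point estimate is unchanged.
* **Cochran's Q / I²** — `Q = Σ (bx²/sey²)(by/bx − β̂)²`, `df = n−1`,
  `I² = max(0, (Q−df)/Q)`. The heterogeneity trigger in the decision tree
  is the literal conjunction `I² > 0.25 and p(Q) < 0.05`.
* **MR-Egger** — WLS of `by` on `bx` *with* intercept after orienting all
  SNPs to `bx ≥ 0`; the intercept is the directional-pleiotropy test and
  the slope a pleiotropy-adjusted estimate (valid under InSIDE). The
  coefficient covariance uses the same overdispersion floor as IVW.
* **Weighted / penalised weighted median** — the per-SNP ratios are
  ordered, weighted by the inverse first-order ratio variance
  (`bx²/sey²`), and the 50th weighted percentile is found with the
  midpoint rule `p_j = 100(S_j − w_j/2)` and linear interpolation.
  Penalisation multiplies each weight by `min(1, 20·q_j)`, `q_j` the
  chi-square(1) tail of the SNP's Q contribution at the unpenalised
  estimate. SEs come from a parametric bootstrap (default 1000 draws,
  seeded) that re-runs the whole procedure per replicate.
* **Profile maximum likelihood** — `(bx_j, by_j)` are modelled as
  independent normals with means `(ξ_j, θξ_j)`; profiling out ξ reduces
  −2·logL to `Σ (by−θbx)²/(sey²+θ²sex²)`, minimised by bounded scalar
  search started at the IVW estimate (xatol 1e−12); the SE is the inverse
  root of the observed profile information (central-difference second
  derivative). Reduces to the Wald ratio for one SNP and to fixed IVW as
  `sex → 0`.
* **Radial IVW** — modified second-order weights
  `w_j = 1/(sey²/bx² + by²sex²/bx⁴)`; regressing `√w·(by/bx)` on `√w`
  without intercept gives `β̂ = Σw·ratio/Σw`. Its residual variance is
  floored at 1 in the SE, mirroring the IVW convention.
* **IVW-SIMEX** — for each λ in {0, 0.5, 1, 1.5, 2}, noise of variance
  `λ·sex²` is added to `bx` (200 re-draws, averaged), a quadratic in λ is
  fitted to the mean estimates and extrapolated to λ = −1, undoing the
  no-measurement-error (NOME) violation; the SE is a nonparametric
  bootstrap over SNPs of the full procedure. A grid of {0} degenerates to
  plain IVW by construction.
* **MR-PRESSO** — the observed weighted residual sum of squares around
  leave-one-out IVW fits is compared with `n_sim` parametric simulations
  (global p uses the (1+k)/(1+n) estimator so it is never exactly zero).
  Per-SNP outlier tests use the raw simulation fraction against a
  Bonferroni-corrected α and are reported only when the global test is
  significant at 0.05 — without that gate the per-SNP p granularity at
  small `n_sim` would dominate the null false-flag rate. The corrected
  estimate is fixed-effect IVW on the retained SNPs; the distortion p
  compares the observed shift with removal of random same-size subsets.
* **Power** — normal approximation for a binary outcome:
  non-centrality `√(n·r²·cf(1−cf))·|log OR|` against a two-sided z-test,
  so power equals α exactly at OR = 1.

## Multivariable estimators

`mvmr_ivw` is WLS of `by` on the K exposure-effect columns without
intercept (weights `1/sey²`, overdispersion floored at 1); `mvmr_egger`
adds an intercept after orienting SNPs so the chosen exposure's effects
are non-negative. `qhet` minimises
`Q(θ) = Σ (by − Σθ_k bx_k)² / (sey² + Σθ_k² sex_k²)` (weights that absorb
weak-instrument noise in the exposure effects) by Nelder–Mead from the
MV-IVW start, with seeded nonparametric bootstrap over SNPs for CIs
(percentile) and SEs. An identically-zero exposure column is dropped from
the design and reported as beta 0 with infinite SE — so a degenerate
mediator column reproduces the univariable IVW exactly — whereas genuinely
collinear non-zero columns raise an error naming the pair. Conditional
instrument strength per exposure is reported as a heuristic diagnostic,
never as a filter.

## Harmonisation and instrument handling

Instruments are SNPs with exposure p < 5×10⁻⁸, greedily clumped in
ascending-p order against an r² matrix (keep if r² < 0.01 with everything
kept) or, lacking one, a closed 1 Mb window on the same chromosome;
"strict" replication mode tightens this to r² < 0.001 within 10 Mb.
Exclusions apply in a fixed order — confounder blacklist, missing in
outcome, ambiguous palindrome — so reports are deterministic and each SNP
is counted once. Palindromic (A/T, C/G) variants are resolved by
effect-allele-frequency concordance and dropped when either study's EAF
falls inside (0.42, 0.58) or is missing. Non-palindromic mismatches are
complemented before concluding incompatibility. Alignment is involutive:
re-harmonising an aligned set is a no-op. The multivariable instrument set
is the deduplicated union of the two univariable IV lists, re-pruned for
mutual LD only when an r² matrix is supplied, then aligned across all
three studies to the exposure's effect allele.

With fewer than 3 instruments the Egger intercept test does not exist; the
decision tree then falls through to the IVW branch (heterogeneity decides
fixed vs random at n = 2; a single SNP gives the Wald-equivalent fixed
IVW), and the rule trace records that pleiotropy was untestable.

## Mediation inference

Indirect effect `βa·βb`, delta SE `√(βb²SEa² + βa²SEb²)` (the square root
is essential; dropping it does not reproduce published CIs), Sobel p from
the normal tail of effect/SE. Proportion mediated `100·βa·βb/βc` with a
delta-method ratio SE assuming independence of the indirect and total
estimates ("delta-ratio"; the two share instruments, so this is an
approximation — values outside [0, 100] are allowed and flagged). When
only CIs are published, SEs are recovered as width/3.92.

## Synthetic data

`simulate_mediation_dag` draws three *independent* studies (two-sample
design, no overlap knob) from the chain X→M→Y with direct effect
`theta_direct` and mediated path `beta_a·beta_b`. Two instrument families
are generated: `n_snp` exposure instruments (true effects ξ on X, scaled
so the per-SNP expected F statistic at the exposure sample size hits
`mean_f_target`) and `n_snp_mediator` mediator-specific instruments with
no exposure effect — without them βb is unidentified in multivariable MR,
just as a real mediator needs its own GWAS hits. Per-study SEs follow the
GWAS formula `1/√(2·maf(1−maf)·n)` exactly; observed effects add
independent study noise. Invalid instruments receive pleiotropic effects
α (on the mediator, propagating to the outcome through it) and γ (on the
outcome), centred at zero (BALANCED) or `pleiotropy_mean` (DIRECTIONAL);
directional draws are oriented to the trait-increasing allele, since a
constant shift under arbitrary allele orientation would average out.
A configurable fraction of SNPs gets palindromic allele pairs, and
`selection_p` optionally truncates the exposure table at genome-wide
significance, reproducing winner's-curse inflation (`mean |bx|` of the
survivors exceeds `mean |ξ|`).

Defaults emulate a consortium-scale triple: exposure n = 237 627,
mediator n = 173 005, outcome n = 184 305, a mostly-direct effect
(`theta_direct = 0.346`, `beta_a = 0.73`, `beta_b = 0.05`, ≈9% mediated)
and mean F 30 — the "adequately powered" regime. What the generator does
*not* emulate: LD between instruments (they are drawn independent and
placed 20 Mb apart), sample overlap, liability-scale binary traits
(effects are generated directly on the log-odds scale), allele-frequency
differences between studies, and population stratification. Passing tests
therefore demonstrate estimator correctness under the stated model, not
robustness to those real-data complications.

## Simulation sizes used in the validation suite

Chosen from a pilot delta-method power analysis so Monte-Carlo noise is
small relative to each check's acceptance band:

* IVW coverage and null rejection: 1000 datasets each (2000 in the
  acceptance script), 50 SNPs, mean F 30 — expected coverage ≈94%
  (slightly below nominal because instrument measurement error attenuates
  the estimate by roughly 1/F; visible but inside the [93%, 97%] band).
* Sobel type-I error: 500 full two-step runs with `beta_a = 0.5`,
  `beta_b = 0` and mean F 100. A single-null configuration is used
  deliberately: with both paths null the Sobel test is well-known to be
  conservative and no calibration band around 5% would be informative.
* Mediation-proportion recovery: 50 runs of the 50%-mediated DAG
  (`theta_direct = 0.1`, `beta_a = 0.5`, `beta_b = 0.2`), 100+100 SNPs,
  consortium sample sizes with a 977k outcome study, and mean F 300.
  The strong-instrument choice makes NOME effectively satisfied, so the
  ±5-percentage-point check isolates the correctness of the mediation
  composition; at weaker instruments the occasional (≈5% false-positive)
  Egger pick by the decision tree widens the error tail, which is a
  property of the decision tree, not of the mediation algebra.
* QHET bootstrap defaults to 1000 resamples as a library call; pipeline
  runs default to 200 (`MRSettings.qhet_boot`) and the simulation suites
  use 100, which changes CIs by far less than their Monte-Carlo width.

## Numerical conventions and degenerate inputs

1.96 is used literally for all 95% CIs (not the 1.959964 quantile),
matching the delta-formula convention above. Ties in instrument selection
break by SNP id, making results invariant to input row order. `bx = 0`
raises for ratio-based methods (Wald, Q, radial); an all-zero exposure
column is the documented MVMR degeneracy; empty instrument sets raise
dedicated errors rather than returning empty results, except exclusion
filtering, which may legitimately return an empty list plus its report.
All stochastic components (median/SIMEX/QHET bootstraps, MR-PRESSO,
the generator) take explicit seeds and are bit-reproducible.

## Known limitations

No Steiger filtering, mode-based or contamination-mixture estimators, and
no bidirectional MR. One mediator at a time. The proportion-mediated CI
ignores the covariance between the indirect and total estimates. LD-aware
selection requires a user-supplied r² matrix (the package never computes
LD from genotypes), and confounder exclusion is a user-supplied blacklist
rather than an online catalogue lookup.
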