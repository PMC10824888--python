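# Methods

## Data model

The unit of counting is the report.  For a target drug *i* and ADR *j*,
`n_ij` is the number of reports mentioning both, `n_i.` the number of
reports mentioning the drug, `n_.j` those mentioning the ADR, and `n` the
total.  Aggregated input is long format: one row per (exposure stratum,
ADR) with an event count, the stratum denominator, and 0/1 drug-indicator
covariates — two strata for one drug, four (neither / only-1 / only-2 /
both) for a pair.  ADRs with zero counts in a stratum keep an explicit row:
they are exactly the cases the mixed model can still estimate.  Within a
report a repeated ADR term counts once, so counts never exceed
denominators and the binomial/Poisson sampling models are coherent.

## Traditional measures

PRR, ROR and the relative reporting ratio (observed over expected,
E = n_i. n_.j / n) use the standard closed forms with log-scale Wald 95%
intervals (`se²(log PRR) = 1/a − 1/n_i. + 1/c − 1/(n − n_i.)`,
`se²(log ROR) = 1/a + 1/b + 1/c + 1/d`, z = 1.96).  A pair is a signal
when the lower limit exceeds 1.  When a required cell is zero the interval
is undefined and the pair cannot be flagged; this failure mode is kept by
default (a Haldane +0.5 correction is available behind a flag) because the
mixed model's handling of those cells is one of its selling points.  For
drug pairs the comparator is the saturated per-ADR GLM with both drug
factors and their product; with four cells and four parameters its MLEs
are closed-form contrasts of cell rates (Poisson) or cell odds (binomial).

## The mixed screening model

One Poisson (PRR) or binomial (ROR) mixed model covers all J ADRs.  Fixed
effects: intercept and the drug indicator(s), plus the product term for a
pair.  Random effects: per-ADR coefficients on the same columns —
a random intercept `b₀ⱼ` (between-ADR variation in baseline reporting) and
a random slope `b₁ⱼ` (between-ADR variation in the drug effect), each with
a single variance component shared across ADRs; the pair model adds random
main-effect and interaction slopes (γ₀, γ₁, γ₂, γ₁₂).  The Poisson model
carries offset log(denominator); without it exp(β+b) would be a count
ratio rather than the reporting-proportion ratio the PRR is defined as.
The ADR-specific measure is exp(β + bⱼ) and its interval is
exp((β̂+b̂ⱼ) ± 1.96·se), where se is the prediction standard error of the
estimable-plus-predictable combination (below).  No multiplicity
adjustment is applied across ADRs — the flag rule is deliberately the same
per-ADR rule as the traditional measures.

A `var_structure="by_group"` option estimates one variance per ADR per
random term instead.  That is the saturated reading of the model; it is
weakly identified (each variance sees essentially one observation, so
roughly half the estimates sit on the zero bound under homogeneity) and it
makes the outer fixed point noticeably more oscillatory, so the shared
structure is the default.

## Estimation: restricted pseudo-likelihood

The engine alternates two steps until the fixed effects and variance
parameters are stable:

1. **Linearisation** at the current (β̂, b̂): working response
   `z = η + (y − μ)/(dμ/dη)` and weights `w` equal to the inverse
   conditional variance times (dμ/dη)²; for Poisson/log `z = (η − offset) +
   (y − μ)/μ, w = μ`, for binomial/logit `z = η + (y/m − p)/(p(1−p)),
   w = m·p(1−p)`.  Conditional means and binomial variances are floored at
   1e-8 (with a warning) so zero-count cells stay finite.
2. **REML fit of the working linear mixed model** `z = Xβ + Zb + e`,
   `Var(e) = φ W⁻¹`, with φ ≡ 1 by default (the exact-family assumption;
   `scale_fixed=False` profiles φ instead).  Because every random term has
   one column per ADR and rows are grouped by ADR, the marginal covariance
   is block diagonal with J blocks of size 2 or 4, so the REML deviance and
   its analytic gradient cost O(J) per evaluation.  Variance components are
   maximised by L-BFGS-B with lower bound 0 (start 0.1, warm-started across
   outer iterations, ftol 1e-12); γ̂ on the bound is legitimate, not an
   error.  β̂ and the BLUPs then solve the mixed-model equations at γ̂.

Outer convergence: maximum relative change in (β, γ) below 1e-8
(denominator |old| + 0.01), capped at 100 iterations.  The fixed point can
oscillate at the inner optimizer's precision floor (amplitudes around
1e-9–1e-7 in small-count drug-pair fits), so a stall criterion also accepts
convergence once the REML objective is stable to 1e-9 relative and
parameters to 1e-5.  Residual non-convergence raises an error carrying the
iteration trace; the experiment harness counts and excludes such
replicates (about 2% in the hardest null scenario) rather than dropping
them silently.

Prediction variances for `l_f'β + l_r'b` come from the inverse of the
mixed-model-equations coefficient matrix — the covariance of
(β̂ − β, b̂ − b) — computed blockwise (Var(b̂−b) = G − GZ'PZG and its
cross-term), which matches the dense inverse to machine precision in the
test suite.  When a variance component is estimated at zero its BLUPs are
exactly zero and the combination reduces to the fixed part.

Starting values: β from the fixed-effects-only IRLS fit, b = 0.  Identical
inputs yield bitwise-identical fits; there is no internal randomness.

## Synthetic data and the experiment harness

The generator mirrors the standard operating-characteristics design for
disproportionality methods.  Single drug: J independent ADRs,
`n_1j ~ Bin(n₁., p₁ⱼ)` exposed and `n_j − n_1j ~ Bin(n − n₁., p₁₋ⱼ)`
unexposed, with defaults n = 10,000,000, n₁. = 10,000 (alternatively
50,000), J = 100 (or 500), incidence probabilities entered in percent
(0.05–0.25% in the reference settings).  Drug pair: four independent
binomial strata with denominators 10⁷/10⁵/10⁵/10⁴; the screened quantity
is the multiplicative interaction p₀₀p₁₁/(p₁₀p₀₁).  Named scenario tables
cover equal-probability nulls, additive-but-not-multiplicative nulls
(ratio 1), and elevated-interaction settings (ratio 1.5–4.5).  Each
replicate uses an independent substream keyed by (seed, replicate index).
`run_experiment` averages the per-replicate flagged fraction over
replicates (1,000 by default; scaled-down runs report their Monte-Carlo
SE so bands can widen accordingly).

**What the generator does not emulate:** real report databases have
heavily heterogeneous ADR frequencies and drug effects, co-reporting
correlation between ADRs on the same report, duplicated and incomplete
reports.  The reference settings draw *every* ADR from the same incidence
probability within a run.  That homogeneity matters for reading the
results: with no true between-ADR variation the REML estimate of the
random-slope variance is at or near zero, all ADR-specific estimates
collapse toward the common exp(β̂), and the mixed model behaves as a
*pooled* test — under a null it flags essentially all or none of the ADRs
in a replicate (replicate-average false-positive rate a little under the
one-sided 2.5% tail), and when every ADR is truly elevated by the same
factor its sensitivity approaches 100%, far above that of the per-ADR
traditional measures.  Passing null-calibration checks here therefore
demonstrates correct pooling under homogeneity, not per-ADR error control;
on heterogeneous data (as in the worked example, where γ̂₁ > 0) the model
genuinely separates ADRs.  This is a property of any honestly-pooling
mixed model fitted to these homogeneous settings, and it is why several
reference operating characteristics that coincide with the traditional
per-ADR values are not recovered by this implementation.

## Numerical choices and edge cases

* z-quantile (1.96) for all intervals; with J ≥ 100 ADR groups,
  degrees-of-freedom corrections would be negligible.
* CI on the measure scale by exponentiating the linear-scale interval.
* Rank-deficient fixed designs are rejected naming the aliased column;
  mixed screening requires J ≥ 2 ADRs (a single ADR cannot identify the
  variance components — the classic measures handle that case).
* Zero-cell ADRs: the working weight of an empty cell tends to the 1e-8
  floor, the BLUP shrinks toward the common effect, and the ADR receives a
  finite interval; the traditional measures return an undefined CI and no
  signal for the same input.
* Probabilities in scenario specifications are percentages, matching how
  such settings are usually printed; conversion happens internally.

## Known limitations

* The engine supports the screening structure (per-ADR random coefficients
  on shared covariates, equal-size groups), not arbitrary crossed or
  nested random effects.
* Pseudo-likelihood is a linearised approximation; for very small counts
  its variance components are biased relative to quadrature-based ML, and
  no quadrature option is provided.
* Three-or-more-drug interactions are representable in the data structures
  but no model builder is shipped for them.
* FAERS ingestion (quarterly ASCII files, MedDRA term mapping, report
  deduplication) is out of scope; inputs are the delimited formats
  described in the README.
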