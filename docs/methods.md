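# Methods

## Model

Two-sample Mendelian randomization treats genetic variants as instruments
for an exposure X on an outcome Y.  Writing γᵢ for the true effect of
variant *i* on X and Γᵢ for its effect on Y, a valid instrument satisfies
Γᵢ = θγᵢ, where θ is the causal effect of X on Y.  The observed GWAS
estimates β̂ˣᵢ ~ N(γᵢ, SEˣᵢ²) and β̂ʸᵢ ~ N(Γᵢ + αᵢ, SEʸᵢ²) may carry a
direct (horizontally pleiotropic) effect αᵢ that violates the exclusion
restriction.  All binary-trait effects are log odds ratios; reported ORs
are exp(β) with 95% Wald intervals exp(β ± 1.96·SE).

Estimators and their validity conditions:

| estimator       | point estimate                                         | valid when |
|-----------------|--------------------------------------------------------|------------|
| Wald ratio      | β̂ʸ/β̂ˣ, SE = SEʸ/\|β̂ˣ\| (first order)                 | single valid instrument |
| IVW             | slope of no-intercept WLS of β̂ʸ on β̂ˣ, weights 1/SEʸ² | all αᵢ = 0 |
| MR-Egger        | slope of the same WLS with free intercept              | InSIDE: cov(γ, α) = 0 |
| weighted median | inverse-variance-weighted median of ratios              | ≥ 50% of weight valid |
| weighted mode   | argmax of smoothed weighted ratio density               | plurality of concordant ratios valid |

Inference conventions: normal reference for Wald/IVW/median/mode; t(k−2)
for the Egger slope and intercept (with only four instruments the t tail
matters).  The Egger residual standard deviation σ̂ = √(Q_egger/(k−2)) is
floored at 1 — equivalent to refusing to deflate coefficient SEs when the
fit is better than its weights predict — and instruments are oriented so
β̂ˣᵢ > 0 before the Egger fit (both betas flipped otherwise) because the
intercept is not invariant to allele-coding signs.  IVW defaults to the
fixed-effect SE; the multiplicative-random-effects option scales the SE by
max(1, √(Q/(k−1))), so the two coincide whenever Q ≤ k−1, as they do on
the bundled example.

Heterogeneity: Q = Σwᵢ(β̂ʸᵢ − fittedᵢ)² with wᵢ = 1/SEʸᵢ², df = k−1 (IVW)
or k−2 (Egger), I² = max(0, (Q−df)/Q) (Higgins convention, truncated at
zero), p from the upper chi-square tail.  The published table this example
reproduces prints df = 2 for both fits and I²/P cells that are not
consistent with their own Q and df; this package reports the standard
df = k−1 for IVW and the recomputed chi-square p-values instead.

## Instrument screening and harmonization

Defaults (all overridable in `SelectionConfig`): exposure significance
P ≤ 5×10⁻⁸; greedy LD pruning at r² < 0.01 within a 10,000 kb window;
minimum instrument F of 10; palindromic-frequency band 0.08.

Variance explained and instrument strength use the summary-statistic
forms R² = 2β²f(1−f)/[2β²f(1−f) + 2·SE²·N·f(1−f)] and F = R²(N−2)/(1−R²),
computed from the exposure block only (instruments are
exposure-ascertained).  The allele-frequency factor cancels in R²; the
expression is evaluated as defined so the code matches the formula term
for term.

LD pruning is a contract over a *supplied* pairwise LD table (variants are
sorted by ascending p; a variant is kept iff its r² with every kept
variant in the window is below threshold).  Computing LD from a genotype
reference panel is out of scope; without a table the pruner degrades to
one-variant-per-window distance pruning and logs that LD was not checked.
The bundled instrument set was clumped against a genotype reference before
publication, so the pipeline treats it as pre-selected: re-applying the
distance-only fallback would discard two of the three chromosome-6
instruments that are physically close but uncorrelated.

Harmonization aligns the outcome record to the exposure effect allele:
identical coding passes through; swapped coding negates β̂ʸ and replaces
its allele frequency f by 1−f; strand-complemented codings (A↔T, C↔G on
both alleles) are complemented first.  Palindromic variants (A/T, C/G)
cannot be disambiguated by letters; they are kept only when both allele
frequencies lie outside 0.5 ± 0.08, with orientation inferred from
frequency concordance (same side of 0.5 ⇒ aligned, opposite ⇒ flipped).
Proxy-variant substitution is deliberately unsupported.  Every exclusion
carries exactly one reason code (`absent_in_outcome`, `allele_mismatch`,
`palindromic_ambiguous_frequency`, `weak_instrument`).

## Bootstrap and bandwidth choices

The weighted-median and weighted-mode SEs come from a parametric
bootstrap: each replicate redraws every β̂ from N(β̂, SE) (SEs held fixed),
recomputes ratios and weights, and re-evaluates the estimator; the SE is
the SD over replicates.  Defaults: 1,000 replicates, seed mandatory in the
pipeline (bit-reproducible given the seed), minimum 100 replicates
enforced.

Weighted-median point estimate: ratios sorted ascending, standardized
cumulative weights pᵢ = (Σ_{j≤i}wⱼ − wᵢ/2)/Σw, linear interpolation to
p = 0.5.  Weighted-mode bandwidth: h = φ·0.9·min(sd, MAD/0.6745)·k^(−1/5)
with φ = 1 by default; the density is evaluated on a 2,048-point grid over
[min−3h, max+3h], kernel arguments clipped at 40σ to avoid spurious
overflow, and the argmax clamped to the ratio range (the density of a
Gaussian mixture peaks inside the convex hull of its centers; clamping
removes a one-grid-step excursion).  When the MAD is zero but the SD is
positive (duplicated ratios), the bandwidth falls back to the SD term
rather than collapsing to zero.  When all ratios coincide the common ratio
is returned directly.

## Synthetic generator

`simulate_pair` emulates the summary-level generative model above: per
variant, maf ~ U(0.05, 0.5), γ magnitude ~ U(0.02, 0.1) (effect allele
coded exposure-increasing by default, so directional pleiotropy is
genuinely directional after Egger orientation), α ~ N(mean, sd)
independent of γ (InSIDE holds by construction), and
SE = 1/√(2·N·f(1−f)), the standardized-trait approximation, which yields
instrument-strength gradients comparable to biobank-scale GWAS.  Alleles
are assigned non-palindromic; variants are placed ≥ 25 Mb apart so no LD
structure exists or is pruned away.

Reference scenarios (`scenario_suite`): null (θ = 0, k = 50, N = 100,000),
causal (θ = 0.1, k = 100, N_exp = 300,000, N_out = 200,000), balanced
pleiotropy (α ~ N(0, 0.02)), directional pleiotropy (α ~ N(0.02, 0.01)),
and weak instruments (γ ~ U(0.012, 0.03) at N = 100,000, putting the
median F near the screening boundary).  Calibration tests use 500
replicates of these scenarios, skipping the significance/strength filters
(`simulate_instruments`) so winner's-curse selection does not bias the
estimator checks.

What the generator does *not* emulate, and hence what passing tests do not
establish for real data: LD between instruments, case-control
liability-scale effects, winner's curse from in-sample instrument
discovery, sample overlap between the two GWAS, population stratification,
and InSIDE violations (correlated pleiotropy).

## Numerical and degenerate-input conventions

- P-values are clipped to (0, 1]; simulated p-values floored at 1e-300.
- A Wald ratio with β̂ʸ = 0 returns β = 0, p = 1; β̂ˣ = 0 is an error.
- IVW with < 2 instruments errors (pointing to the Wald ratio); Egger and
  weighted mode require ≥ 3; leave-one-out requires ≥ 3 so every reduced
  fit is defined.  The model front-end records skipped estimators rather
  than failing the whole fit.
- TSV writers print 12 significant digits; write→read round-trips agree to
  at least 10.
- Ties in LD pruning are broken by (p-value, rsid); outputs are ordered by
  (chromosome, position).

## Worked-example tolerances

The bundled exposure betas are published rounded to one significant
figure.  Recomputed from the bundled table: IVW β = 0.0821 (published
0.092 from unrounded data), OR 1.086 vs 1.096 (≈1%), p = 0.0150 vs 0.015
(printed precision); Egger slope 0.0152 vs 0.015 and intercept 2.44×10⁻⁴
vs 0.00025 (printed precision); Q_IVW 2.745 vs 2.734 and Q_Egger 2.233 vs
2.239 (< 0.5%); ΣR² = 0.00306, rounding to the published 0.0031.  The
weighted-median/mode SEs depend on unpublished bootstrap and bandwidth
settings and are matched in direction and magnitude only.

## Limitations

No multivariable MR, Steiger filtering, MR-PRESSO/Radial outlier removal,
proxy lookup, or reference-panel LD computation; indels and multi-allelic
variants are rejected at ingestion; no network retrieval of GWAS data.
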