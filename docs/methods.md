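# Methods

## Setting and model

`finemr` estimates the causal effect θ of an exposure X on an outcome Y from
*summarized* genetic data in a single fine-mapped gene region: per-variant
univariable association estimates β̂_Xj (SE σ_Xj) and β̂_Yj (SE σ_Yj) for
J variants, plus a signed correlation (LD) matrix ρ over the same variants,
typically estimated from a reference panel.  All estimators assume the
variants are valid instruments for the same causal parameter (a fixed-effect
model, appropriate within one gene region) and that the outcome associations
are linear in the exposure associations, β_Yj = θ β_Xj.

With uncorrelated variants the inverse-variance weighted (IVW) estimate is

    θ̂ = Σ_j β̂_Yj β̂_Xj σ_Yj⁻² / Σ_j β̂_Xj² σ_Yj⁻² ,
    se(θ̂) = (Σ_j β̂_Xj² σ_Yj⁻²)^(-1/2) ,

the fixed-effect pooling of the per-variant ratio estimates β̂_Yj/β̂_Xj.
With correlated variants the same estimate arises from generalized weighted
least squares of β̂_Y on β̂_X with weighting matrix
Ω_{j1 j2} = σ_Yj1 σ_Yj2 ρ_{j1 j2}:

    θ̂ = (β̂_Xᵀ Ω⁻¹ β̂_X)⁻¹ β̂_Xᵀ Ω⁻¹ β̂_Y ,   var(θ̂) = (β̂_Xᵀ Ω⁻¹ β̂_X)⁻¹ .

This is asymptotically equivalent to two-stage least squares (2SLS) on the
underlying individual-level data; the package carries a 2SLS implementation
(`two_stage_least_squares`) whose sole role is to serve as an independent
oracle for that equivalence in tests.  Uncertainty in β̂_X is ignored
throughout: exposure associations are usually much more precisely estimated
than outcome ones and ignoring this does not inflate type-I error in
realistic regimes.

## Why variant selection is needed, and what can go wrong

Fine-mapped regions contain hundreds of highly correlated candidate
variants.  Using all of them requires inverting Ω.  When ρ is
*near-singular* — which happens routinely when many variants lie on few
haplotypes — elements of ρ⁻¹ become enormous, and any small inconsistency
between the association estimates and the correlation matrix (rounding of
published estimates, LD estimated in a different sample) is magnified into
an overly precise, badly biased estimate, usually with no error raised.  If
Ω is numerically indefinite the "variance" (β̂_XᵀΩ⁻¹β̂_X)⁻¹ can even be
negative; `finemr` reports this as `se_defined=False` rather than raising,
so simulation loops can count such outcomes.

Three responses are implemented:

* **Pruning** (`selection.prune`): greedily keep the variant with the lowest
  marginal exposure p-value, discard everything with |ρ| strictly above a
  threshold to it, repeat.  P-value ties are broken by larger |β̂_X/σ_X|,
  then input order (the procedure is otherwise order-ambiguous; this makes
  it deterministic).  Marginal p-values are computed once and never
  recomputed.
* **Stepwise conditional selection** (`selection.stepwise_conditional`):
  forward selection on *conditional* p-values reconstructed from summary
  statistics.  The joint model treats D^{1/2} ρ D^{1/2} as a scaled proxy
  for the genotype cross-product matrix, with per-variant genotype variances
  D_j = 2 p_j (1 − p_j) from allele frequencies when available and a
  unit-variance convention otherwise, and the phenotype variance normalized
  to 1.  The reference sample size, when not supplied, is inferred from the
  marginal identity σ_Xj² ≈ (1 − D_j β̂_Xj²)/(n D_j) (median across
  variants).  Candidates with |ρ| > 0.9 (configurable) to any selected
  variant are excluded at each step, which prevents the near-singularity
  pathology from arising inside selection itself.  This reconstruction is
  validated against joint least-squares fits on simulated individual-level
  data, not against any external tool's output.
* **PCA instruments** (`pca`, `estimators.pca_ivw`): unscaled principal
  components (no centering, no row scaling) of the weighted matrix
  Ψ_{j1 j2} = β̂_Xj1 β̂_Xj2 σ_Yj1⁻¹ σ_Yj2⁻¹ ρ_{j1 j2}, whose diagonal is the
  per-variant inverse-variance weight — the precision of the single-variant
  causal estimate.  The first k components (smallest k reaching a cumulative
  variance fraction, default 99%) replace the variants:
  β̃_X = W_kᵀβ̂_X, β̃_Y = W_kᵀβ̂_Y, Ω̃ = W_kᵀ Ω W_k, and the GLS machinery is
  applied to the transformed triple.  With k = J this is an invertible
  transform and reproduces the correlated IVW estimate exactly; with
  k < J the discarded directions are precisely the near-null eigenvalue
  directions that cause instability.  Weighting by β̂_X/σ_Y (rather than
  decomposing ρ itself) makes the leading components the combinations that
  explain the most exposure variance, so a precisely measured variant is
  preferred over a noisy perfect proxy of it.

Numerical conventions: eigenvector signs are fixed by making each column's
largest-magnitude loading positive (estimates are sign-invariant, but
serialized loadings should be reproducible).  Eigenvalues of Ψ below
−1e-8·λ₁ trigger a non-PSD warning (they indicate inconsistent inputs) and
negative eigenvalues are floored at zero when computing variance fractions.
Exact singularity of Ω raises an explicit error advising pruning or PCA; a
pseudo-inverse exists only behind an explicit flag, because silently
pseudo-inverting is exactly the failure mode the diagnostics exist to catch.
Confidence intervals use the normal 97.5% quantile 1.959964.

## Diagnostics

`diagnostics.audit` reports the condition number λ_max/λ_min of ρ, the
largest |element| of ρ⁻¹, positive-definiteness, and a *ridge probe*: the
correlated-IVW estimate with and without a small constant (default 0.1)
added to the correlation diagonal, with the shift expressed in units of the
raw SE.  A large shift indicates near-singular behaviour.  The ridge option
on the estimator itself is exposed (`ivw_correlated(..., ridge=...)`) but
documented as diagnostic-only: it deliberately misspecifies the correlation
matrix, and a stricter pruning threshold or PCA is preferable for
estimation.  Warning thresholds (condition number 1e6, max inverse element
1e4) are heuristics calibrated to the magnitudes at which the pathologies
appear in practice; there is no principled universal cutoff, so they are
configurable and always printed.  `diagnostics.rounding_probe` rounds all
betas and SEs to a given number of decimals and reports the estimate shift —
in near-singular regions two-decimal rounding routinely moves the estimate
by more than one SE.

## Synthetic data

The generator produces the inputs, so no external data is required.

**LD.** Two mechanisms. `ar1` builds block-diagonal matrices with
correlation decay^|i−j| inside blocks — positive definite, well conditioned,
a convenient stand-in for a region with several moderately correlated LD
blocks. `haplotype` simulates K ancestral haplotypes (Dirichlet
frequencies; each variant carried by a distinct contiguous interval of
haplotypes with population frequency in [0.02, 0.98]), draws a diploid
reference panel of finite size, and returns the panel correlation matrix.
Because J variants span only K ≪ J haplotypes, the true matrix is low-rank;
the returned matrix gets a spectral floor (minimum eigenvalue 1e-7, then
rescaled to unit diagonal), standing in for the tiny independent variation
(genotyping error, rare recombinants) that makes real reference-panel
matrices invertible yet near-singular — condition numbers around 1e8, max
inverse elements in the millions, pairwise |ρ| up to ~1, and a mix of
positive and negative correlations.  Bootstrap replicates in
`run_ld_bootstrap` use the raw resampled panel correlations (no floor),
exactly as a practitioner would compute them; these are rank-deficient, so
liberal pruning thresholds frequently leave an exactly singular weighting
matrix and an undefined SE.

**Summary data.** `draw_summary` draws β̂_X ~ MVN(μ_X, Ω_X) with
Ω_X = σ_X σ_Xᵀ ∘ ρ and β̂_Y ~ MVN(θ·m, Ω).  For the outcome mean m the
package defaults to the *drawn* β̂_X of the same iteration, which makes
every estimator exactly conditionally unbiased (E[θ̂ | β̂_X] = θ) and
matches the observed behaviour that mean estimates sit on the true value
under all selection strategies; centring on the fixed μ_X instead (available
via `outcome_mean_from_drawn=False`) introduces a regression-dilution
attenuation of order tr(Ω⁻¹Ω_X)/(μ_Xᵀ Ω⁻¹ μ_X), which is a weak-instrument
artefact of the simulation design rather than a property of the estimators.
Optional rounding of all betas and SEs to a fixed number of decimals
emulates associations transcribed from publications.

**Study regions.** Defaults are fixed once as a realistic portrait of a
fine-mapped region and not tuned per experiment:

* `example_region` — 100 variants, five AR(1) blocks of 20 with decay 0.8;
  six causal exposure signals (sparse effects γ of ±0.25–0.45, marginal
  associations μ_X = ρ·γ so the marginal profile respects LD; strongest
  marginal z ≈ 18, consistent with the lead signals of a fine-mapped
  quantitative-trait locus); σ_X = 0.025 (a single-cohort GWAS of a few
  thousand individuals), σ_Y = 0.05 (log odds ratios from a moderate
  case-control consortium).
* `high_ld_region` — 60 variants on 12 haplotypes (panel of 503), the same
  sparse-signal construction, σ_X = 0.025 and σ_Y = 0.015 (a large
  consortium — precisely the scale at which two-decimal rounding is
  comparable to the SE and the rounding pathology bites).

**Individual-level data.** `gen_individual` builds diallelic genotypes from
haplotype pairs (for `ar1`, latent Gaussian haplotypes dichotomised at the
minor-allele-frequency quantile; the implied dosage correlations are
attenuated relative to the latent ones, which is immaterial for oracle
comparisons that estimate LD from the sample itself), then
X = Gγ + c·U + ε_X and Y = θX + c·U + ε_Y with a shared confounder U.
`marginal_summaries` turns such samples into GWAS-shaped summary statistics.

**What the generator does not emulate:** coalescent-realistic LD decay,
allele-frequency spectra, population stratification, sample overlap between
exposure and outcome GWAS, horizontal pleiotropy, or winner's-curse in the
exposure associations.  Passing simulation tests therefore demonstrates the
statistical and numerical behaviour of the estimators under the stated
sampling model, not robustness to instrument invalidity.

## Simulation studies and reported quantities

`run_calibration` loops draw → (selection) → estimation and reports, per
estimator: mean and SD of estimates, mean SE, the percentage of 95% CIs
excluding zero (type-I error under θ=0, power otherwise), and the count of
iterations with an undefined SE or a singular weighting matrix (those are
excluded from the other summaries).  Selection is re-run on each iteration's
drawn exposure p-values, as in a data-driven analysis.  Under the null with
exact LD this z-test is exactly calibrated for every pruning threshold —
selection depends only on β̂_X, which is independent of β̂_Y — so observed
rates differ from 5% only by Monte-Carlo noise (binomial SE
√(p(1−p)/n_iter); checks use a ±3·SE convention).  The interesting failures
appear when the data are rounded or the LD matrix is re-estimated.

`run_subset_sensitivity` fixes one dataset and repeats the analysis on
random half-subsets of variants; `run_ld_bootstrap` fixes one dataset and
repeats it with bootstrap-resampled panel correlation matrices.  In the
near-singular region with rounded data, liberal pruning (|ρ| ≤ 0.8) shows
estimate SDs across subsets an order of magnitude above the PCA approach,
and bootstrap LD produces frequent undefined SEs at liberal thresholds —
while PCA instruments remain stable; these orderings, not exact values, are
the reproducible content.

Problem sizes used in the shipped tests and acceptance script (chosen to
characterise the behaviour at comfortable Monte-Carlo precision): 5,000
iterations for the null calibration of the 100-variant region, 2,000 for
mean recovery, 1,000 for the rounded high-LD calibration, 200–400 replicates
for the subset and bootstrap studies, and 50 repetitions of the n = 20,000 /
J = 5 individual-level equivalence check (agreement with 2SLS to 1%
relative; the equivalence is asymptotic, with O(1/n) finite-sample
differences from degrees-of-freedom and intercept handling).

## Known limitations

* The conditional-selection reconstruction assumes Hardy-Weinberg genotype
  variances and a homogeneous reference sample size; with rounded or
  incompatible inputs its σ² estimate can be crude (it is floored at a tiny
  positive value).  It is a selection device, not an estimator of record.
* Allele harmonization handles swaps and strand flips and drops mismatched
  palindromic variants; it does not use allele frequencies to resolve
  strand, and without allele columns it can only warn.
* The spectral floor on haplotype LD matrices is a modelling choice for how
  real panels escape exact singularity; conclusions about *how far* into
  near-singularity an analysis can go depend on it, and it is exposed as
  `LDSpec.eig_floor`.
* Fixed-effect inference only; combining regions, random-effects models and
  pleiotropy-robust estimators are out of scope.
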