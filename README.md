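# finemr

Mendelian randomization (MR) with many **correlated** genetic variants from a
fine-mapped gene region, using only summarized data: per-variant association
estimates with an exposure and an outcome, plus a signed LD correlation
matrix from a reference panel.

In a densely genotyped region there may be hundreds of correlated candidate
instruments.  Using too many requires inverting a near-singular correlation
matrix, which silently magnifies small data inconsistencies (e.g. rounding
of published estimates) into overly precise, misleading causal estimates and
inflated type-I error.  Using too few makes the estimate hostage to the
arbitrary choice of variants.  `finemr` implements the standard estimators
and selection strategies on either side of that trade-off, a
principal-components construction that avoids it, diagnostics that flag the
danger zone, and the simulation machinery to study all of the above.

## What is implemented

* **Estimators** — inverse-variance weighted (IVW) estimate for
  uncorrelated variants; correlated-variant IVW via generalized weighted
  least squares with Ω[j1,j2] = se(β̂_Yj1)·se(β̂_Yj2)·ρ[j1,j2]:

      θ̂ = (β̂_Xᵀ Ω⁻¹ β̂_X)⁻¹ β̂_Xᵀ Ω⁻¹ β̂_Y,   var(θ̂) = (β̂_Xᵀ Ω⁻¹ β̂_X)⁻¹

  a ridge-adjusted variant (diagnostic only); PCA-IVW using the leading
  components of the weighted matrix
  Ψ[j1,j2] = β̂_Xj1·β̂_Xj2·se(β̂_Yj1)⁻¹·se(β̂_Yj2)⁻¹·ρ[j1,j2] as instruments;
  and two-stage least squares on individual-level data (used as a test
  oracle for the summary estimators).
* **Selection** — greedy LD pruning on marginal p-values at a |ρ| threshold,
  and stepwise conditional selection reconstructed from summary statistics
  plus the LD matrix, with conditional (joint) exposure coefficients
  available as optimal allele-score weights.
* **Diagnostics** — condition number and maximal inverse element of ρ,
  positive-definiteness / negative-variance flags, a ridge sensitivity
  probe, and a rounding probe.
* **Synthetic data** — block-AR(1) and haplotype-panel LD generators, a
  summary-statistics sampler, individual-level genotype simulation, and
  three study designs: type-I error / power calibration, subset
  sensitivity, and LD-bootstrap sensitivity.

See `docs/methods.md` for the model, assumptions, numerical conventions and
the design of the synthetic regions.

## Worked example

Everything below is reproducible without external data — the package
generates a synthetic 100-variant fine-mapped region (six causal signals,
true causal effect 0.1) and analyses it:

```python
import numpy as np
from finemr import ivw_correlated, pca_ivw, prune, audit
from finemr.simulate import example_region, draw_summary, gen_ld

config = example_region(theta=0.1, seed=7)
ld = gen_ld(config.ld_spec, config.ld_seed)
data = draw_summary(config, np.random.default_rng(7), ld)

sel = prune(data, ld, rho_threshold=0.4)
est = ivw_correlated(data.subset_ids(sel.kept_ids), ld.subset_ids(sel.kept_ids))
print(f"pruning |rho|<=0.4 kept {sel.n_kept}/100 variants")
print(f"IVW (correlated): {est.estimate:.3f} (SE {est.se:.3f}), "
      f"95% CI {est.ci_lower:.3f} to {est.ci_upper:.3f}")

pc = pca_ivw(data, ld, variance_threshold=0.99)
print(f"PCA-IVW with k={pc.n_instruments} components "
      f"({100*pc.info['cumulative_variance']:.1f}% of variance): "
      f"{pc.estimate:.3f} (SE {pc.se:.3f})")

rep = audit(data, ld)
print(f"condition number {rep.condition_number:.1f}, "
      f"max |inverse element| {rep.max_inverse_element:.1f}, "
      f"ridge shift {rep.ridge_sensitivity[2]:.3f} SE")
```

Output:

```
pruning |rho|<=0.4 kept 18/100 variants
IVW (correlated): 0.132 (SE 0.062), 95% CI 0.011 to 0.254
PCA-IVW with k=61 components (99.0% of variance): 0.133 (SE 0.061)
condition number 64.7, max |inverse element| 4.6, ridge shift 0.179 SE
```

Both routes recover an estimate near the true effect 0.1 with a 95% CI
excluding zero; the diagnostics confirm this region is numerically benign
(small condition number; adding 0.1 to the correlation diagonal moves the
estimate by only a fraction of its SE).  Re-running with
`finemr.simulate.high_ld_region` and `decimals=2` shows the opposite regime:
a near-singular correlation matrix where liberal pruning produces spuriously
precise estimates and the audit raises loud warnings.

## Command line

The same functionality is exposed as `mr` with subcommands `estimate`,
`select`, `pca`, `audit` and `simulate`, reading TSV/CSV summary statistics
(columns `snp`, `beta`, `se`, optional alleles/frequency) and
whitespace-delimited LD matrices (square with ID header, or `ID_A ID_B R`
triples):

```sh
mr select   --method prune --rho 0.4 \
            --exposure exp.tsv --outcome out.tsv --ld ld.txt --out kept.tsv
mr estimate --method ivw-corr --keep kept.tsv \
            --exposure exp.tsv --outcome out.tsv --ld ld.txt
mr audit    --exposure exp.tsv --outcome out.tsv --ld ld.txt
mr simulate --config sim.yaml --seed 1 --out report.tsv
```

`mr estimate` prints a one-row TSV (`method`, `n_instruments`, `estimate`,
`se`, `ci_lower`, `ci_upper`, `se_defined`) plus a JSON diagnostics block on
stderr.  Exit codes: 0 success, 2 validation errors, 3 terminal numerical
conditions (singular weighting matrix / undefined SE).

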