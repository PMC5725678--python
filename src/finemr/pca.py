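"""Principal components of the weighted LD matrix as instruments.

Instead of selecting a subset of correlated variants, linear combinations of
all variants can serve as instruments.  We take unscaled (covariance-style,
no centering or row scaling) principal components of the weighted matrix

    Psi[j1, j2] = beta_x[j1] * beta_x[j2] / (se_y[j1] * se_y[j2]) * rho[j1, j2]

whose diagonal entries are the inverse-variance weights — the precision of
the causal estimate based on each variant alone, proportional to the variance
in the exposure explained by that variant when all associations come from a
common sample size.  Leading components therefore capture the directions of
variant space that explain the most exposure variance, and (unlike components
of the raw correlation matrix) preferentially weight precisely measured
variants.  The components are orthogonal, so estimation with them does not
inherit the near-singularity of the raw LD matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .summarydata import LDMatrix, SummarySet, ValidationError

__all__ = ["WeightedPsi", "build_psi", "select_k"]

#: Eigenvalues below -NEG_EIG_TOL * lambda_1 indicate inconsistent inputs.
NEG_EIG_TOL = 1e-8


@dataclass
class WeightedPsi:
    """Eigendecomposition of the weighted correlation matrix Psi.

    ``loadings`` columns are unit eigenvectors ordered by descending
    eigenvalue; ``cumvar[k-1]`` is the fraction of total variance captured by
    the first ``k`` components (negative eigenvalues floored at zero).
    """

    variant_ids: list[str]
    psi: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)
    loadings: np.ndarray = field(repr=False)
    cumvar: np.ndarray = field(repr=False)
    non_psd: bool = False

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


def build_psi(data: SummarySet, ld: LDMatrix) -> WeightedPsi:
    """Build Psi and its symmetric eigendecomposition.

    Eigenvector signs are fixed by making each column's largest-magnitude
    loading positive, so serialized loadings are reproducible (GLS estimates
    are invariant to the sign).  Numerically negative eigenvalues more
    negative than ``-1e-8 * lambda_1`` trigger a non-PSD warning — Psi is
    positive semi-definite for a consistent (rho PSD) input — and negative
    eigenvalues are floored at zero when accumulating variance fractions.
    """
    if data.variant_ids != ld.variant_ids:
        raise ValidationError("summary set and LD matrix are not aligned")
    w = data.beta_x / data.se_y
    psi = np.outer(w, w) * ld.rho
    psi = 0.5 * (psi + psi.T)
    eigvals, eigvecs = np.linalg.eigh(psi)
    order = np.argsort(eigvals, kind="stable")[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # reproducible sign: largest-|loading| entry of each column positive
    anchor = np.argmax(np.abs(eigvecs), axis=0)
    signs = np.sign(eigvecs[anchor, np.arange(eigvecs.shape[1])])
    signs[signs == 0] = 1.0
    eigvecs = eigvecs * signs

    non_psd = False
    lam1 = eigvals[0] if eigvals.size else 0.0
    if lam1 > 0 and eigvals[-1] < -NEG_EIG_TOL * lam1:
        non_psd = True
        warnings.warn(
            f"Psi has a negative eigenvalue ({eigvals[-1]:.3g}); inputs are "
            "inconsistent (non-PSD); flooring at zero for variance fractions",
            stacklevel=2,
        )
    floored = np.maximum(eigvals, 0.0)
    total = floored.sum()
    if total <= 0:
        raise ValidationError("Psi has no positive eigenvalue (all beta_x zero?)")
    cumvar = np.cumsum(floored) / total
    cumvar[-1] = 1.0  # guard float drift so the final fraction is exactly 1
    return WeightedPsi(
        variant_ids=list(data.variant_ids),
        psi=psi,
        eigenvalues=eigvals,
        loadings=eigvecs,
        cumvar=cumvar,
        non_psd=non_psd,
    )


def select_k(psi: WeightedPsi, variance_threshold: float) -> int:
    """Smallest number of components whose cumulative variance fraction
    reaches ``variance_threshold`` (a fraction in ``(0, 1]``)."""
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    return int(np.searchsorted(psi.cumvar, variance_threshold - 1e-12) + 1)
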