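"""Causal-effect estimators for summarized and individual-level data.

All summary-data estimators are inverse-variance weighted (IVW) estimators:
with uncorrelated variants the causal effect of the exposure on the outcome
is the weight-``se_y**-2`` average of the per-variant ratio estimates
``beta_y / beta_x``; with correlated variants the same estimate arises from
generalized weighted least squares of ``beta_y`` on ``beta_x`` with weighting
matrix ``Omega[j1, j2] = se_y[j1] * se_y[j2] * rho[j1, j2]``:

    theta_hat = (bx' Omega^-1 bx)^-1 bx' Omega^-1 by
    var(theta_hat) = (bx' Omega^-1 bx)^-1

which is asymptotically equivalent to two-stage least squares (2SLS) on the
underlying individual-level data.  The PCA variant applies the same machinery
after projecting the association vectors and Omega onto the leading
components of the weighted LD matrix (see :mod:`finemr.pca`).  Uncertainty
in the exposure associations is ignored throughout (a fixed-effect model);
these associations are typically far more precise than the outcome ones and
ignoring them does not inflate type-I error in realistic settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import diagnostics as _diag
from . import pca as _pca
from .summarydata import LDMatrix, SummarySet, ValidationError

__all__ = [
    "MREstimate",
    "WeightMatrix",
    "SingularMatrixError",
    "DegenerateInstrumentError",
    "Z_95",
    "ivw_uncorrelated",
    "build_omega",
    "ivw_correlated",
    "pca_ivw",
    "two_stage_least_squares",
]

#: 97.5% standard-normal quantile used for all 95% confidence intervals.
Z_95 = 1.959964


class SingularMatrixError(np.linalg.LinAlgError):
    """The weighting matrix is exactly singular and cannot be inverted.

    Raised instead of silently falling back to a pseudo-inverse, because
    near-singular weighting matrices produce overly precise and misleading
    estimates; consider pruning the variants or using PCA instruments.
    """


class DegenerateInstrumentError(ValueError):
    """All instruments have zero exposure association; no ratio is defined."""


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty and provenance.

    ``se_defined`` is False when the computed variance was non-positive
    (a non-positive-definite weighting matrix, arising from inconsistent
    inputs); the point estimate is still reported but ``se``/CI are NaN.
    """

    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    method: str
    n_instruments: int
    se_defined: bool = True
    diagnostics: _diag.DiagnosticsReport | None = None
    info: dict = field(default_factory=dict)

    @property
    def p_value(self) -> float:
        """Two-sided normal p-value against a null effect of zero."""
        from scipy.stats import norm

        if not self.se_defined or self.se <= 0:
            return float("nan")
        return 2.0 * float(norm.sf(abs(self.estimate / self.se)))

    def rejects_null(self) -> bool:
        """True when the 95% CI excludes zero (requires a defined SE)."""
        return bool(self.se_defined and abs(self.estimate) > Z_95 * self.se)


@dataclass
class WeightMatrix:
    """The GLS weighting matrix Omega built from outcome SEs and LD."""

    omega: np.ndarray


def _finalize(estimate: float, variance: float, method: str, k: int,
              report: _diag.DiagnosticsReport | None = None,
              info: dict | None = None) -> MREstimate:
    se_defined = variance > 0 and np.isfinite(variance)
    se = float(np.sqrt(variance)) if se_defined else float("nan")
    if report is not None and not se_defined:
        report.negative_variance = True
        report.warnings.append(
            "variance estimate is non-positive: weighting matrix not positive "
            "definite (SEs imprecise or incompatible with the correlation matrix)"
        )
    return MREstimate(
        estimate=float(estimate),
        se=se,
        ci_lower=float(estimate - Z_95 * se) if se_defined else float("nan"),
        ci_upper=float(estimate + Z_95 * se) if se_defined else float("nan"),
        method=method,
        n_instruments=k,
        se_defined=bool(se_defined),
        diagnostics=report,
        info=info or {},
    )


def ivw_uncorrelated(data: SummarySet) -> MREstimate:
    """Fixed-effect IVW estimate assuming uncorrelated variants.

    Equivalent to zero-intercept weighted regression of ``beta_y`` on
    ``beta_x`` with weights ``se_y**-2``, and to a fixed-effect meta-analysis
    of the per-variant ratio estimates.
    """
    w = data.se_y ** -2.0
    denom = float(np.sum(data.beta_x ** 2 * w))
    if denom <= 0:
        raise DegenerateInstrumentError("all exposure associations are zero")
    estimate = float(np.sum(data.beta_y * data.beta_x * w)) / denom
    return _finalize(estimate, 1.0 / denom, "ivw", data.n_variants)


def build_omega(data: SummarySet, ld: LDMatrix, ridge: float = 0.0) -> WeightMatrix:
    """Omega[j1, j2] = se_y[j1] * se_y[j2] * rho[j1, j2].

    ``ridge`` is added to the *correlation* diagonal before weighting (a
    regularization sometimes used with dense LD; diagnostic-only here, since
    it deliberately misspecifies the correlation matrix).
    """
    if data.variant_ids != ld.variant_ids:
        raise ValidationError("summary set and LD matrix are not aligned")
    rho = ld.rho
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    if ridge:
        rho = rho + ridge * np.eye(len(data))
    return WeightMatrix(omega=np.outer(data.se_y, data.se_y) * rho)


def _gls(bx: np.ndarray, by: np.ndarray, omega: np.ndarray,
         use_pseudo_inverse: bool = False) -> tuple[float, float]:
    """Solve the GLS normal equations; returns (estimate, variance).

    Inversion goes through an exact solve so that an exactly singular Omega
    raises :class:`SingularMatrixError`; a pseudo-inverse is applied only on
    explicit request because it can mask rank deficiency.
    """
    if use_pseudo_inverse:
        oinv = np.linalg.pinv(omega, hermitian=True)
        a = float(bx @ oinv @ bx)
        b = float(bx @ oinv @ by)
    else:
        try:
            sol = np.linalg.solve(omega, np.column_stack([bx, by]))
        except np.linalg.LinAlgError:
            raise SingularMatrixError(
                "weighting matrix is exactly singular (perfectly collinear "
                "variants?); prune the variants or use PCA instruments"
            ) from None
        # solve() can succeed on numerically singular input; reject garbage
        residual = omega @ sol - np.column_stack([bx, by])
        scale = max(np.max(np.abs(bx)), np.max(np.abs(by)), 1e-300)
        if not np.all(np.isfinite(sol)) or np.max(np.abs(residual)) > 1e-6 * scale:
            raise SingularMatrixError(
                "weighting matrix is numerically singular; prune the variants "
                "or use PCA instruments"
            )
        a = float(bx @ sol[:, 0])
        b = float(bx @ sol[:, 1])
    if a == 0:
        raise DegenerateInstrumentError("all exposure associations are zero")
    return b / a, 1.0 / a


def ivw_correlated(
    data: SummarySet,
    ld: LDMatrix,
    ridge: float = 0.0,
    use_pseudo_inverse: bool = False,
    attach_diagnostics: bool = True,
) -> MREstimate:
    """IVW estimate accounting for correlation between variants.

    Generalized weighted least squares of ``beta_y`` on ``beta_x`` with the
    weighting matrix built by :func:`build_omega`.  With an identity
    correlation matrix this reduces exactly to :func:`ivw_uncorrelated`.
    A numerical-stability report on the correlation matrix is attached by
    default; a non-positive variance is reported as ``se_defined=False``
    rather than raised, so simulation loops can count such outcomes.
    """
    omega = build_omega(data, ld, ridge=ridge).omega
    estimate, variance = _gls(data.beta_x, data.beta_y, omega, use_pseudo_inverse)
    report = None
    if attach_diagnostics:
        rho = ld.rho if not ridge else ld.rho + ridge * np.eye(len(data))
        report = _diag.matrix_audit(rho)
    method = "ivw-corr" if not ridge else f"ivw-corr(ridge={ridge:g})"
    return _finalize(estimate, variance, method, data.n_variants, report)


def pca_ivw(
    data: SummarySet,
    ld: LDMatrix,
    variance_threshold: float | None = 0.99,
    k: int | None = None,
    attach_diagnostics: bool = True,
) -> MREstimate:
    """IVW estimate using principal components of the weighted LD matrix.

    The association vectors and the weighting matrix are projected onto the
    first ``k`` components of Psi (``k`` chosen so the components capture
    ``variance_threshold`` of the variance when not given explicitly), and
    the correlated-IVW machinery is applied to the transformed triple::

        bx~ = Wk' bx,  by~ = Wk' by,  Omega~ = Wk' Omega Wk

    With ``k`` equal to the number of variants (full rank) this is an
    invertible linear transform of the GLS problem and reproduces
    :func:`ivw_correlated` exactly.
    """
    psi = _pca.build_psi(data, ld)
    if k is None:
        if variance_threshold is None:
            raise ValueError("provide either variance_threshold or k")
        k = _pca.select_k(psi, variance_threshold)
    if not 1 <= k <= psi.n_variants:
        raise ValueError(f"k={k} outside [1, {psi.n_variants}]")
    wk = psi.loadings[:, :k]
    omega = build_omega(data, ld).omega
    bx_t = wk.T @ data.beta_x
    by_t = wk.T @ data.beta_y
    omega_t = wk.T @ omega @ wk
    omega_t = 0.5 * (omega_t + omega_t.T)
    estimate, variance = _gls(bx_t, by_t, omega_t)
    report = None
    if attach_diagnostics:
        report = _diag.matrix_audit(omega_t)
    info = {
        "cumulative_variance": float(psi.cumvar[k - 1]),
        "eigenvalues": psi.eigenvalues[:k].tolist(),
    }
    return _finalize(estimate, variance, f"pca(k={k})", k, report, info)


def two_stage_least_squares(
    X: np.ndarray, Y: np.ndarray, G: np.ndarray
) -> MREstimate:
    """2SLS estimate of the causal effect from individual-level data.

    Stage 1 regresses the exposure ``X`` on the genotype matrix ``G`` (with
    intercept); stage 2 regresses the outcome ``Y`` on the fitted exposure
    (with intercept).  The SE is the usual homoscedastic IV standard error:
    stage-2 residuals are recomputed with the *observed* exposure.  With a
    single binary instrument this reduces to the Wald ratio estimator.
    """
    X = np.asarray(X, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, j = G.shape
    if len(X) != n or len(Y) != n:
        raise ValidationError("X, Y and G must share the number of individuals")
    if n <= j + 1:
        raise ValidationError(f"need more individuals ({n}) than instruments ({j})")
    design = np.column_stack([np.ones(n), G])
    coef, _, rank, _ = np.linalg.lstsq(design, X, rcond=None)
    if rank < design.shape[1]:
        raise SingularMatrixError("genotype matrix is rank deficient")
    xhat = design @ coef
    z = np.column_stack([np.ones(n), xhat])
    theta_vec, _, rank2, _ = np.linalg.lstsq(z, Y, rcond=None)
    if rank2 < 2:
        raise SingularMatrixError("fitted exposure has no variation")
    theta = float(theta_vec[1])
    resid = Y - theta_vec[0] - theta * X  # observed exposure, not fitted
    sigma2 = float(resid @ resid) / (n - 2)
    ztz_inv = np.linalg.inv(z.T @ z)
    variance = sigma2 * float(ztz_inv[1, 1])
    return _finalize(theta, variance, "2sls", j)
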