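"""Detection of near-singular LD pathologies before and alongside estimation.

With fine-mapped data the signed correlation matrix over candidate variants
is often near-singular: it can still be inverted, but elements of the inverse
are huge, so small inconsistencies between association and correlation
estimates (rounding, different samples) are magnified into overly precise and
misleading causal estimates — typically without any error being raised.  The
functions here quantify that danger (condition number, maximal element of the
inverse, a ridge perturbation probe, a rounding probe) so that an analysis
can be flagged rather than silently trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .summarydata import LDMatrix, SummarySet

__all__ = [
    "DiagnosticsReport",
    "RoundingReport",
    "matrix_audit",
    "audit",
    "rounding_probe",
]

#: Condition number above which a correlation matrix is flagged near-singular.
#: Heuristic, motivated by pathological real-data magnitudes (inverse elements
#: in the tens of millions); always configurable and always reported.
DEFAULT_CONDITION_THRESHOLD = 1e6
#: Max |element| of the inverse correlation matrix above which to warn.
DEFAULT_MAX_INVERSE_THRESHOLD = 1e4


@dataclass
class DiagnosticsReport:
    """Numerical-stability report for a correlation/weighting matrix.

    ``ridge_sensitivity`` is ``(raw_estimate, ridge_estimate, shift_in_se)``
    when the ridge probe was run: a large shift after adding a small constant
    to the correlation diagonal indicates near-singular behaviour.
    """

    condition_number: float = float("nan")
    max_inverse_element: float = float("nan")
    is_pd: bool = True
    negative_variance: bool = False
    ridge_sensitivity: tuple[float, float, float] | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "condition_number": self.condition_number,
            "max_inverse_element": self.max_inverse_element,
            "is_pd": self.is_pd,
            "negative_variance": self.negative_variance,
            "ridge_sensitivity": self.ridge_sensitivity,
            "warnings": list(self.warnings),
        }


def matrix_audit(
    rho: np.ndarray,
    condition_threshold: float = DEFAULT_CONDITION_THRESHOLD,
    max_inverse_threshold: float = DEFAULT_MAX_INVERSE_THRESHOLD,
) -> DiagnosticsReport:
    """Condition number and max inverse element of a symmetric matrix.

    Never raises: exact singularity is reported as ``is_pd=False`` with an
    infinite condition number and infinite max inverse element.
    """
    rho = np.asarray(rho, dtype=float)
    report = DiagnosticsReport()
    eigvals = np.linalg.eigvalsh(0.5 * (rho + rho.T))
    lam_max = float(eigvals[-1])
    lam_min = float(eigvals[0])
    report.is_pd = lam_min > 0
    if lam_min <= 0:
        report.condition_number = float("inf")
        report.max_inverse_element = float("inf")
        report.warnings.append(
            "matrix is singular or indefinite (min eigenvalue "
            f"{lam_min:.3g}); it cannot be safely inverted"
        )
        return report
    report.condition_number = lam_max / lam_min
    try:
        inv = np.linalg.inv(rho)
        report.max_inverse_element = float(np.max(np.abs(inv)))
    except np.linalg.LinAlgError:  # pragma: no cover - PD matrices invert
        report.max_inverse_element = float("inf")
    if report.condition_number > condition_threshold:
        report.warnings.append(
            f"condition number {report.condition_number:.3g} exceeds "
            f"{condition_threshold:.3g}: matrix is near-singular"
        )
    if report.max_inverse_element > max_inverse_threshold:
        report.warnings.append(
            f"max |inverse element| {report.max_inverse_element:.3g} exceeds "
            f"{max_inverse_threshold:.3g}: small data inconsistencies will be magnified"
        )
    return report


def audit(
    data: SummarySet,
    ld: LDMatrix,
    ridge_probe: float = 0.1,
    condition_threshold: float = DEFAULT_CONDITION_THRESHOLD,
    max_inverse_threshold: float = DEFAULT_MAX_INVERSE_THRESHOLD,
) -> DiagnosticsReport:
    """Full numerical-stability audit of an aligned dataset.

    Beyond :func:`matrix_audit` of the correlation matrix, runs the
    correlated-IVW estimator with and without ``ridge_probe`` added to the
    correlation diagonal and reports the estimate shift as a fraction of the
    raw SE; a substantial shift is indicative of near-singular behaviour.
    Diagnostics never fail on pathological input.
    """
    from . import estimators  # local import: estimators attaches these reports

    report = matrix_audit(ld.rho, condition_threshold, max_inverse_threshold)
    raw_est = raw_se = float("nan")
    try:
        raw = estimators.ivw_correlated(data, ld, attach_diagnostics=False)
        raw_est = raw.estimate
        raw_se = raw.se if raw.se_defined else float("nan")
        if not raw.se_defined:
            report.negative_variance = True
            report.warnings.append(
                "variance estimate is negative: weighting matrix not positive definite"
            )
    except estimators.SingularMatrixError:
        report.warnings.append("weighting matrix is exactly singular; no raw estimate")
    if ridge_probe and ridge_probe > 0:
        try:
            ridged = estimators.ivw_correlated(
                data, ld, ridge=ridge_probe, attach_diagnostics=False
            )
            shift = (
                abs(ridged.estimate - raw_est) / raw_se
                if np.isfinite(raw_est) and np.isfinite(raw_se) and raw_se > 0
                else float("nan")
            )
            report.ridge_sensitivity = (raw_est, ridged.estimate, shift)
            if np.isfinite(shift) and shift > 1.0:
                report.warnings.append(
                    f"adding {ridge_probe:g} to the correlation diagonal moves the "
                    f"estimate by {shift:.2f} raw SEs: near-singular behaviour"
                )
        except estimators.SingularMatrixError:  # pragma: no cover - ridge fixes rank
            report.warnings.append("ridge-adjusted weighting matrix still singular")
    return report


@dataclass
class RoundingReport:
    """Effect of rounding the association estimates on the causal estimate."""

    decimals: int
    raw_estimate: float
    raw_se: float
    rounded_estimate: float
    rounded_se: float
    estimate_shift: float
    se_shift: float
    excluded_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def shift_in_se(self) -> float:
        if np.isfinite(self.raw_se) and self.raw_se > 0:
            return abs(self.estimate_shift) / self.raw_se
        return float("nan")


def rounding_probe(data: SummarySet, ld: LDMatrix, decimals: int) -> RoundingReport:
    """Round all betas and SEs to ``decimals`` places and re-estimate.

    Published summary statistics are typically rounded; with a near-singular
    weighting matrix that alone can move the estimate by more than its SE.
    Variants whose SE rounds to zero are excluded with a warning.
    """
    from . import estimators

    if decimals < 1:
        raise ValueError("decimals must be >= 1")
    raw = estimators.ivw_correlated(data, ld, attach_diagnostics=False)
    se_x = np.round(data.se_x, decimals)
    se_y = np.round(data.se_y, decimals)
    keep = np.flatnonzero((se_x > 0) & (se_y > 0))
    excluded = [data.variant_ids[i] for i in range(len(data)) if i not in set(keep)]
    warn: list[str] = []
    if excluded:
        warn.append(f"SE rounded to zero for {excluded}; variants excluded")
    rounded = SummarySet(
        variant_ids=[data.variant_ids[i] for i in keep],
        beta_x=np.round(data.beta_x, decimals)[keep],
        se_x=se_x[keep],
        beta_y=np.round(data.beta_y, decimals)[keep],
        se_y=se_y[keep],
    )
    ld_sub = ld.subset(list(keep))
    new = estimators.ivw_correlated(rounded, ld_sub, attach_diagnostics=False)
    return RoundingReport(
        decimals=decimals,
        raw_estimate=raw.estimate,
        raw_se=raw.se if raw.se_defined else float("nan"),
        rounded_estimate=new.estimate,
        rounded_se=new.se if new.se_defined else float("nan"),
        estimate_shift=new.estimate - raw.estimate,
        se_shift=(new.se - raw.se)
        if (raw.se_defined and new.se_defined)
        else float("nan"),
        excluded_ids=excluded,
        warnings=warn,
    )
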