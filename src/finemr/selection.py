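"""Variant-selection strategies preceding IVW estimation.

Two standard ways to thin a fine-mapped region down to an instrument set:

* **Pruning** — greedily pick the variant with the lowest marginal exposure
  p-value, remove every remaining variant correlated with it above a
  threshold, and repeat until every variant is either selected or removed.
  The kept set is marginally associated with the exposure with all pairwise
  correlations at or below the threshold.

* **Stepwise conditional selection** — repeatedly add the variant with the
  smallest *conditional* p-value for the exposure given the already selected
  set, stopping when none falls below the significance cutoff.  Conditional
  (joint-model) estimates are reconstructed from marginal summary statistics
  plus a reference LD matrix by solving the joint-regression normal
  equations, the construction popularized by GCTA-COJO.

The joint-model reconstruction treats ``D^(1/2) R D^(1/2)`` (R the signed LD
matrix, D per-variant genotype variances, from allele frequencies when
available and a unit-variance convention otherwise) as a proxy for the
genotype cross-product matrix, with the phenotype variance normalized to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .estimators import SingularMatrixError
from .summarydata import LDMatrix, SummarySet, ValidationError

__all__ = [
    "SelectionResult",
    "prune",
    "stepwise_conditional",
    "conditional_weights",
]

#: Candidates correlated above this with any selected variant are excluded
#: from stepwise conditional selection (GCTA's collinearity convention);
#: prevents near-singular joint models inside the selection loop itself.
DEFAULT_COLLINEARITY_CUTOFF = 0.9


@dataclass
class SelectionResult:
    """Outcome of a variant-selection pass.

    ``kept_ids`` are in selection order.  ``dropped`` maps each removed
    variant to the reason: for pruning, the id of the selected variant that
    removed it; for conditional selection, ``"step:<k>"`` for candidates that
    never reached significance (k = number of completed steps) or
    ``"collinear:<id>"`` for those excluded by the collinearity guard.
    """

    kept_ids: list[str]
    dropped: dict[str, str]
    threshold: float
    method: str = "prune"

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)


def marginal_p_values(data: SummarySet) -> np.ndarray:
    """Two-sided normal p-values for the marginal exposure associations."""
    z = np.abs(data.beta_x / data.se_x)
    return 2.0 * norm.sf(z)


def prune(data: SummarySet, ld: LDMatrix, rho_threshold: float) -> SelectionResult:
    """Greedy LD pruning on marginal exposure p-values.

    At each step the remaining variant with the lowest marginal p-value is
    selected and every other remaining variant with ``|rho|`` *strictly*
    greater than ``rho_threshold`` to it is removed (recording the selected
    variant as the cause).  P-value ties are broken by larger ``|beta_x/se_x|``
    and then input order, for reproducibility.  Marginal p-values are computed
    once and never revisited.
    """
    if data.variant_ids != ld.variant_ids:
        raise ValidationError("summary set and LD matrix are not aligned")
    if not 0 < rho_threshold <= 1:
        raise ValueError("rho_threshold must be in (0, 1]")
    pvals = marginal_p_values(data)
    z = np.abs(data.beta_x / data.se_x)
    order = sorted(range(len(data)), key=lambda i: (pvals[i], -z[i], i))
    abs_rho = np.abs(ld.rho)
    active = np.ones(len(data), dtype=bool)
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for i in order:
        if not active[i]:
            continue
        kept.append(data.variant_ids[i])
        active[i] = False
        victims = np.flatnonzero(active & (abs_rho[i] > rho_threshold))
        for v in victims:
            dropped[data.variant_ids[v]] = data.variant_ids[i]
            active[v] = False
    return SelectionResult(kept_ids=kept, dropped=dropped,
                           threshold=rho_threshold, method="prune")


# ---------------------------------------------------------------------------
# Summary-statistics conditional (joint) analysis
# ---------------------------------------------------------------------------

def _genotype_variances(data: SummarySet) -> np.ndarray:
    # 2 p (1 - p) for a diallelic SNP in Hardy-Weinberg equilibrium; without
    # frequencies, a unit-variance convention (ranking-neutral when SEs are
    # on a common scale).
    if data.eaf is not None:
        p = np.clip(data.eaf, 1e-6, 1 - 1e-6)
        return 2.0 * p * (1.0 - p)
    return np.ones(data.n_variants)


def _infer_ref_n(data: SummarySet, d: np.ndarray) -> float:
    # From the marginal-regression identity se_j^2 ~= (var_y - D_j b_j^2) / (n D_j)
    # with phenotype variance normalized to 1.
    n_j = (1.0 - d * data.beta_x ** 2) / (d * data.se_x ** 2)
    n = float(np.median(n_j))
    return max(n, data.n_variants + 2.0)


def _joint_fit(
    data: SummarySet,
    ld: LDMatrix,
    idx: Sequence[int],
    d: np.ndarray,
    n: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Joint exposure model for the variants at ``idx``.

    Returns (betas, SEs, residual variance).  Solves
    ``b = [D^(1/2) R D^(1/2)]^-1 D b_marginal`` with
    ``var(b) = sigma^2 / n * [D^(1/2) R D^(1/2)]^-1`` and
    ``sigma^2 = (1 - b' D b_marginal) * n / (n - m - 1)`` under a unit
    phenotype variance.
    """
    idx = list(idx)
    m = len(idx)
    sd = np.sqrt(d[idx])
    a = ld.rho[np.ix_(idx, idx)] * np.outer(sd, sd)
    v = d[idx] * data.beta_x[idx]
    try:
        b = np.linalg.solve(a, v)
    except np.linalg.LinAlgError:
        raise SingularMatrixError(
            "selected-set correlation submatrix is singular; inputs inconsistent"
        ) from None
    explained = float(b @ v)
    dof = max(n - m - 1, 1.0)
    sigma2 = max(1.0 - explained, 1e-12) * n / dof
    cov = sigma2 / n * np.linalg.inv(a)
    ses = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    return b, ses, sigma2


def stepwise_conditional(
    data: SummarySet,
    ld: LDMatrix,
    p_threshold: float = 1e-4,
    ref_n: float | None = None,
    collinearity_cutoff: float = DEFAULT_COLLINEARITY_CUTOFF,
) -> SelectionResult:
    """Forward stepwise selection on conditional exposure p-values.

    At each step every remaining candidate is evaluated jointly with the
    selected set (see module docstring for the reconstruction); the candidate
    with the smallest conditional p-value is added if it falls below
    ``p_threshold``, otherwise selection stops.  Candidates correlated above
    ``collinearity_cutoff`` (in ``|rho|``) with any selected variant are
    excluded from consideration.  ``ref_n`` is the exposure GWAS sample size;
    when omitted it is inferred from the SEs under a unit phenotype variance.
    """
    if data.variant_ids != ld.variant_ids:
        raise ValidationError("summary set and LD matrix are not aligned")
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    d = _genotype_variances(data)
    n = float(ref_n) if ref_n is not None else _infer_ref_n(data, d)
    j = data.n_variants
    abs_rho = np.abs(ld.rho)

    selected: list[int] = []
    dropped: dict[str, str] = {}
    candidates = set(range(j))
    step = 0
    while candidates:
        best_i, best_p = None, np.inf
        for i in sorted(candidates):
            trial = selected + [i]
            try:
                b, ses, _ = _joint_fit(data, ld, trial, d, n)
            except SingularMatrixError:
                continue
            p_i = 2.0 * float(norm.sf(abs(b[-1] / ses[-1])))
            if p_i < best_p:
                best_i, best_p = i, p_i
        if best_i is None or best_p >= p_threshold:
            break
        selected.append(best_i)
        candidates.discard(best_i)
        step += 1
        collinear = [
            i for i in candidates if abs_rho[best_i, i] > collinearity_cutoff
        ]
        for i in collinear:
            dropped[data.variant_ids[i]] = f"collinear:{data.variant_ids[best_i]}"
            candidates.discard(i)
    for i in sorted(candidates):
        dropped[data.variant_ids[i]] = f"step:{step}"
    return SelectionResult(
        kept_ids=[data.variant_ids[i] for i in selected],
        dropped=dropped,
        threshold=p_threshold,
        method="conditional",
    )


def conditional_weights(
    data: SummarySet, ld: LDMatrix, selected: Sequence[str]
) -> np.ndarray:
    """Joint-model (conditional) exposure coefficients for ``selected``.

    These are the optimal allele-score weights with correlated variants: the
    multivariable associations of the selected variants with the exposure.
    With a single variant, or uncorrelated variants, they equal the marginal
    ``beta_x`` values.
    """
    if data.variant_ids != ld.variant_ids:
        raise ValidationError("summary set and LD matrix are not aligned")
    pos = {v: i for i, v in enumerate(data.variant_ids)}
    try:
        idx = [pos[v] for v in selected]
    except KeyError as exc:
        raise ValidationError(f"unknown variant id {exc.args[0]!r}") from None
    if not idx:
        raise ValidationError("selected list is empty")
    d = _genotype_variances(data)
    n = _infer_ref_n(data, d)
    b, _, _ = _joint_fit(data, ld, idx, d, n)
    return b
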