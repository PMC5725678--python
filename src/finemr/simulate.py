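"""Synthetic-data generation and simulation studies for correlated-variant MR.

This module generates everything the estimators consume — LD matrices,
summarized association data, individual-level genotype data — and runs the
three study designs used to characterise variant-selection strategies:

* :func:`run_calibration` — draw summary associations directly from their
  sampling distribution (exposure associations from ``MVN(mu_x, Omega_X)``,
  outcome associations from ``MVN(theta * beta_x, Omega)``), optionally round
  them to a fixed number of decimals, and measure per-estimator type-I error
  / power of the 95% CI over many iterations.
* :func:`run_subset_sensitivity` — fix one summary dataset and repeatedly
  re-run selection + estimation on a random subset of the variants,
  measuring how sensitive each estimator is to which variants happen to be
  available.
* :func:`run_ld_bootstrap` — fix one summary dataset and re-run selection +
  estimation with correlation matrices recomputed from bootstrap resamples
  of a finite reference panel, measuring sensitivity to LD estimation noise.

Two LD generators are provided.  ``ar1`` builds block-diagonal matrices with
within-block AR(1) decay — well-conditioned, convenient for calibration
studies.  ``haplotype`` simulates a small pool of ancestral haplotypes,
draws a finite diploid reference panel from it and returns the panel
correlation matrix: because the variants span only a few haplotypes, the
matrix is low-rank in truth and near-singular after finite-sample estimation
— the regime in which fine-mapped MR analyses misbehave.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import estimators as _est
from . import pca as _pca
from . import selection as _sel
from .summarydata import LDMatrix, SummaryHalf, SummarySet, compute_ld

__all__ = [
    "LDSpec",
    "SimConfig",
    "MethodStats",
    "SimulationReport",
    "gen_ld",
    "gen_reference_panel",
    "draw_summary",
    "run_calibration",
    "run_subset_sensitivity",
    "run_ld_bootstrap",
    "gen_individual",
    "marginal_summaries",
    "example_region",
    "high_ld_region",
]


# ---------------------------------------------------------------------------
# LD specification and generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDSpec:
    """Recipe for a synthetic LD matrix.

    ``kind`` is ``"ar1"`` (block-diagonal, correlation ``decay**|i-j|``
    within each block, zero between blocks), ``"haplotype"`` (sample
    correlation of a diploid panel of ``panel_n`` individuals drawn from
    ``n_haplotypes`` ancestral haplotypes carrying the variants), or
    ``"explicit"`` (use ``matrix`` as given).  ``eig_floor`` is the minimum
    eigenvalue enforced on the returned matrix; for the haplotype model the
    raw panel matrix is exactly rank-deficient, and the spectral floor stands
    in for the tiny amount of independent variation (genotyping error, rare
    recombinants) that makes real panel matrices invertible yet
    near-singular.
    """

    kind: str = "ar1"
    block_sizes: tuple[int, ...] = (10,)
    decay: float = 0.0
    n_haplotypes: int = 12
    panel_n: int = 503
    eig_floor: float = 1e-7
    maf: float = 0.3
    matrix: tuple | None = None  # nested tuple for hashability; or ndarray

    @property
    def n_variants(self) -> int:
        if self.kind == "explicit":
            return len(np.asarray(self.matrix))
        return int(sum(self.block_sizes))


def _variant_ids(j: int) -> list[str]:
    width = max(3, len(str(j)))
    return [f"v{i + 1:0{width}d}" for i in range(j)]


def _ar1_matrix(spec: LDSpec) -> np.ndarray:
    blocks = []
    for size in spec.block_sizes:
        idx = np.arange(size)
        blocks.append(spec.decay ** np.abs(idx[:, None] - idx[None, :]))
    j = spec.n_variants
    rho = np.zeros((j, j))
    start = 0
    for b in blocks:
        s = b.shape[0]
        rho[start:start + s, start:start + s] = b
        start += s
    return rho


def _haplotype_pool(spec: LDSpec, rng: np.random.Generator):
    """Carrier matrix (haplotype x variant) and haplotype frequencies.

    Each variant is carried by a contiguous interval of the (arbitrarily
    ordered) haplotypes, giving nested/overlapping carrier sets and hence a
    wide range of positive and negative pairwise correlations.  Intervals
    are distinct and filtered to population frequency in [0.02, 0.98].
    """
    k = spec.n_haplotypes
    j = spec.n_variants
    freqs = rng.dirichlet(np.full(k, 2.0))
    cum = np.concatenate([[0.0], np.cumsum(freqs)])
    candidates = []
    for a in range(k):
        for b in range(a, k):
            if a == 0 and b == k - 1:
                continue  # carried by every haplotype: monomorphic
            f = cum[b + 1] - cum[a]
            if 0.02 <= f <= 0.98:
                candidates.append((a, b))
    if len(candidates) < j:
        raise ValueError(
            f"infeasible LD spec: only {len(candidates)} distinct variant "
            f"patterns available for {j} variants; increase n_haplotypes"
        )
    chosen = rng.choice(len(candidates), size=j, replace=False)
    carriers = np.zeros((k, j))
    for col, ci in enumerate(chosen):
        a, b = candidates[ci]
        carriers[a:b + 1, col] = 1.0
    return carriers, freqs


def gen_reference_panel(
    spec: LDSpec, n: int, seed: int | np.random.Generator | None = 0
) -> np.ndarray:
    """An ``n x J`` dosage matrix consistent with the LD spec.

    ``ar1`` panels are Gaussian dosages with the target correlation;
    ``haplotype`` panels are diploid 0/1/2 genotypes from sampled haplotype
    pairs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.kind == "ar1":
        rho = _ar1_matrix(spec)
        chol = np.linalg.cholesky(rho + 1e-12 * np.eye(len(rho)))
        return rng.standard_normal((n, len(rho))) @ chol.T
    if spec.kind == "haplotype":
        carriers, freqs = _haplotype_pool(spec, rng)
        k = len(freqs)
        h1 = rng.choice(k, size=n, p=freqs)
        h2 = rng.choice(k, size=n, p=freqs)
        return carriers[h1] + carriers[h2]
    raise ValueError(f"no reference panel for LD spec kind {spec.kind!r}")


def _spectral_floor(rho: np.ndarray, floor: float) -> np.ndarray:
    """Raise eigenvalues below ``floor`` and rescale to unit diagonal."""
    eigval, eigvec = np.linalg.eigh(rho)
    if eigval[0] > floor:
        return rho
    eigval = np.maximum(eigval, floor)
    fixed = (eigvec * eigval) @ eigvec.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return np.clip(0.5 * (fixed + fixed.T), -1.0, 1.0)


def gen_ld(spec: LDSpec, seed: int | None = 0) -> LDMatrix:
    """Generate a positive-definite LD matrix from a spec.

    The minimum eigenvalue is at least ``spec.eig_floor`` (default 1e-7):
    AR(1) blocks satisfy this by construction for ``|decay| < 1`` (the decay
    is shrunk towards zero in the unlikely event they do not); haplotype and
    explicit matrices are repaired with a spectral floor.  ``seed`` controls
    the haplotype pool and panel; the AR(1) construction is deterministic.
    """
    if spec.kind == "explicit":
        rho = np.asarray(spec.matrix, dtype=float)
        ids = _variant_ids(len(rho))
    elif spec.kind == "ar1":
        if not abs(spec.decay) < 1:
            raise ValueError("AR(1) decay must satisfy |decay| < 1")
        working = spec
        for _ in range(8):
            rho = _ar1_matrix(working)
            if np.linalg.eigvalsh(rho)[0] > spec.eig_floor:
                break
            working = replace(working, decay=working.decay * 0.99)
        ids = _variant_ids(spec.n_variants)
    elif spec.kind == "haplotype":
        rng = np.random.default_rng(seed)
        for attempt in range(10):
            panel = gen_reference_panel(spec, spec.panel_n, rng)
            if np.all(panel.var(axis=0) > 0):
                break
        else:
            raise ValueError("infeasible LD spec: monomorphic panel variants persist")
        ld = compute_ld(panel, _variant_ids(spec.n_variants))
        rho, ids = ld.rho, ld.variant_ids
    else:
        raise ValueError(f"unknown LD spec kind {spec.kind!r}")
    rho = _spectral_floor(rho, spec.eig_floor)
    return LDMatrix(variant_ids=ids, rho=rho)


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of a summary-data simulation.

    ``mu_x`` is the vector of true *marginal* exposure associations (built in
    the factory functions as ``rho @ gamma`` from sparse causal effects, so
    the marginal profile respects the LD structure).  ``se_x``/``se_y`` are
    the per-variant SEs of the exposure/outcome associations.  ``theta`` is
    the true causal effect.  With ``outcome_mean_from_drawn`` (the default)
    the outcome associations are drawn with mean ``theta`` times the drawn
    exposure associations of the same iteration, which makes every estimator
    exactly unbiased; set it to False to centre them on ``theta * mu_x``
    instead.  ``decimals`` rounds all betas and SEs after drawing, emulating
    summary statistics transcribed from the literature.
    """

    ld_spec: LDSpec
    mu_x: np.ndarray
    se_x: np.ndarray
    se_y: np.ndarray
    theta: float = 0.0
    n_iter: int = 10_000
    seed: int = 0
    ld_seed: int = 1
    decimals: int | None = None
    outcome_mean_from_drawn: bool = True
    estimator_grid: list[tuple[str, float | None]] = field(
        default_factory=lambda: [
            ("prune", 0.2), ("prune", 0.4), ("prune", 0.6), ("prune", 0.8),
            ("pca", 0.99), ("pca", 0.999),
        ]
    )

    def __post_init__(self) -> None:
        self.mu_x = np.asarray(self.mu_x, dtype=float)
        j = self.ld_spec.n_variants
        self.se_x = np.broadcast_to(np.asarray(self.se_x, dtype=float), (j,)).copy()
        self.se_y = np.broadcast_to(np.asarray(self.se_y, dtype=float), (j,)).copy()
        if len(self.mu_x) != j:
            raise ValueError(f"mu_x has {len(self.mu_x)} entries for {j} variants")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @property
    def n_variants(self) -> int:
        return self.ld_spec.n_variants


def _sparse_gamma(j: int, signals: dict[int, float]) -> np.ndarray:
    gamma = np.zeros(j)
    for idx, val in signals.items():
        gamma[idx] = val
    return gamma


def example_region(
    n_iter: int = 10_000,
    seed: int = 0,
    theta: float = 0.0,
    decimals: int | None = None,
) -> SimConfig:
    """A well-behaved synthetic fine-mapped region of 100 variants.

    Five LD blocks of 20 variants with AR(1) decay 0.8, six causal exposure
    signals spread over the blocks (marginal associations ``rho @ gamma``),
    exposure SEs of 0.025 (a single-cohort quantitative-trait GWAS of a few
    thousand samples; the strongest signal has marginal z around 18) and
    outcome SEs of 0.05 (log odds ratios from a moderately sized
    case-control consortium).
    """
    spec = LDSpec(kind="ar1", block_sizes=(20,) * 5, decay=0.8)
    rho = gen_ld(spec).rho
    gamma = _sparse_gamma(100, {4: 0.45, 15: -0.35, 33: 0.35,
                                47: 0.30, 66: -0.30, 88: 0.25})
    return SimConfig(
        ld_spec=spec,
        mu_x=rho @ gamma,
        se_x=0.025,
        se_y=0.05,
        theta=theta,
        n_iter=n_iter,
        seed=seed,
        decimals=decimals,
    )


def high_ld_region(
    n_iter: int = 10_000,
    seed: int = 0,
    theta: float = 0.0,
    decimals: int | None = None,
) -> SimConfig:
    """A pathological synthetic region: 60 variants on 12 haplotypes.

    The correlation matrix comes from a finite reference panel (503
    individuals) over a small haplotype pool, so it is near-singular with
    pairwise correlations reaching above 0.95 — the regime where liberal
    pruning thresholds combine near-collinear variants.  Outcome SEs of
    0.015 reflect a large case-control consortium, which is exactly where
    rounding associations to two decimals becomes comparable to the SE.
    """
    spec = LDSpec(kind="haplotype", block_sizes=(60,), n_haplotypes=12,
                  panel_n=503)
    rho = gen_ld(spec, seed=1).rho
    gamma = _sparse_gamma(60, {3: 0.45, 13: -0.35, 24: 0.35,
                               35: 0.30, 44: -0.30, 55: 0.25})
    return SimConfig(
        ld_spec=spec,
        mu_x=rho @ gamma,
        se_x=0.025,
        se_y=0.015,
        theta=theta,
        n_iter=n_iter,
        seed=seed,
        ld_seed=1,
        decimals=decimals,
    )


# ---------------------------------------------------------------------------
# Drawing summary datasets
# ---------------------------------------------------------------------------

def _mvn_factor(cov: np.ndarray) -> np.ndarray:
    """A factor A with A A' = cov, robust to (near-)semidefiniteness."""
    eigval, eigvec = np.linalg.eigh(0.5 * (cov + cov.T))
    if eigval[0] < -1e-8 * max(eigval[-1], 1.0):
        raise ValueError("covariance matrix is not positive semi-definite")
    return eigvec * np.sqrt(np.maximum(eigval, 0.0))


def _round_positive(se: np.ndarray, decimals: int) -> np.ndarray:
    rounded = np.round(se, decimals)
    if np.any(rounded <= 0):
        raise ValueError(
            f"rounding SEs to {decimals} decimals produced zeros; "
            "the rounding grid is too coarse for these SEs"
        )
    return rounded


def draw_summary(config: SimConfig, rng: np.random.Generator | None = None,
                 ld: LDMatrix | None = None) -> SummarySet:
    """Draw one summarized dataset from its sampling distribution.

    ``beta_x ~ MVN(mu_x, Omega_X)`` with ``Omega_X = se_x se_x' * rho`` and
    ``beta_y ~ MVN(theta * m, Omega)`` with ``Omega = se_y se_y' * rho``,
    where ``m`` is the drawn ``beta_x`` (default) or ``mu_x`` (see
    :class:`SimConfig`).  Optional rounding to ``config.decimals`` is applied
    to all betas and SEs afterwards.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if ld is None:
        ld = gen_ld(config.ld_spec, config.ld_seed)
    rho = ld.rho
    ax = _mvn_factor(np.outer(config.se_x, config.se_x) * rho)
    ay = _mvn_factor(np.outer(config.se_y, config.se_y) * rho)
    return _draw_with_factors(config, rng, ld, ax, ay)


def _draw_with_factors(config, rng, ld, ax, ay) -> SummarySet:
    j = config.n_variants
    beta_x = config.mu_x + ax @ rng.standard_normal(j)
    mean_y = config.theta * (beta_x if config.outcome_mean_from_drawn else config.mu_x)
    beta_y = mean_y + ay @ rng.standard_normal(j)
    se_x, se_y = config.se_x, config.se_y
    if config.decimals is not None:
        beta_x = np.round(beta_x, config.decimals)
        beta_y = np.round(beta_y, config.decimals)
        se_x = _round_positive(se_x, config.decimals)
        se_y = _round_positive(se_y, config.decimals)
    return SummarySet(
        variant_ids=ld.variant_ids,
        beta_x=beta_x, se_x=se_x, beta_y=beta_y, se_y=se_y,
    )


# ---------------------------------------------------------------------------
# Applying an estimator grid
# ---------------------------------------------------------------------------

def method_label(method: str, param: float | None) -> str:
    if method == "prune":
        return f"prune(rho={param:g})"
    if method == "pca":
        return f"pca(var={param:g})"
    if method == "conditional":
        return f"conditional(p={param:g})"
    return method


def _apply_method(method: str, param: float | None,
                  data: SummarySet, ld: LDMatrix) -> _est.MREstimate | None:
    """One selection + estimation pass; None when no estimate is defined."""
    try:
        if method == "ivw":
            return _est.ivw_uncorrelated(data)
        if method == "ivw-corr":
            return _est.ivw_correlated(data, ld, attach_diagnostics=False)
        if method == "pca":
            return _est.pca_ivw(data, ld, variance_threshold=param,
                                attach_diagnostics=False)
        if method in ("prune", "conditional"):
            if method == "prune":
                sel = _sel.prune(data, ld, param)
            else:
                sel = _sel.stepwise_conditional(data, ld, p_threshold=param)
            if not sel.kept_ids:
                return None
            sub = data.subset_ids(sel.kept_ids)
            ld_sub = ld.subset_ids(sel.kept_ids)
            return _est.ivw_correlated(sub, ld_sub, attach_diagnostics=False)
    except (_est.SingularMatrixError, _est.DegenerateInstrumentError):
        return None
    raise ValueError(f"unknown estimator {method!r}")


@dataclass
class MethodStats:
    """Monte-Carlo summary for one estimator.

    ``rejection_rate`` is the percentage of iterations with a defined SE
    whose 95% CI excluded zero; ``n_undefined`` counts iterations where the
    SE was undefined (non-positive variance) or estimation failed on a
    singular weighting matrix, and such iterations are excluded from the
    mean/SD/rejection summaries.
    """

    method: str
    mean_estimate: float
    sd_estimates: float
    mean_se: float
    rejection_rate: float
    n_undefined: int
    n_iter: int


@dataclass
class SimulationReport:
    """Per-estimator Monte-Carlo summaries, in estimator-grid order."""

    stats: dict[str, MethodStats]
    n_iter: int

    def __getitem__(self, label: str) -> MethodStats:
        return self.stats[label]

    def to_rows(self) -> list[dict]:
        return [
            {
                "method": s.method,
                "mean_estimate": s.mean_estimate,
                "sd": s.sd_estimates,
                "mean_se": s.mean_se,
                "rejection_pct": s.rejection_rate,
                "n_undefined": s.n_undefined,
            }
            for s in self.stats.values()
        ]


class _Accumulator:
    def __init__(self, label: str):
        self.label = label
        self.estimates: list[float] = []
        self.ses: list[float] = []
        self.rejections = 0
        self.n_undefined = 0
        self.n_total = 0

    def add(self, est: _est.MREstimate | None) -> None:
        self.n_total += 1
        if est is None or not est.se_defined:
            self.n_undefined += 1
            return
        self.estimates.append(est.estimate)
        self.ses.append(est.se)
        if est.rejects_null():
            self.rejections += 1

    def stats(self) -> MethodStats:
        n_def = len(self.estimates)
        est = np.array(self.estimates)
        return MethodStats(
            method=self.label,
            mean_estimate=float(est.mean()) if n_def else float("nan"),
            sd_estimates=float(est.std(ddof=1)) if n_def > 1 else float("nan"),
            mean_se=float(np.mean(self.ses)) if n_def else float("nan"),
            rejection_rate=100.0 * self.rejections / n_def if n_def else float("nan"),
            n_undefined=self.n_undefined,
            n_iter=self.n_total,
        )


def _grid_accumulators(config: SimConfig) -> dict[tuple, _Accumulator]:
    return {
        (m, p): _Accumulator(method_label(m, p)) for m, p in config.estimator_grid
    }


def _report(accs: dict, n_iter: int) -> SimulationReport:
    return SimulationReport(
        stats={a.label: a.stats() for a in accs.values()}, n_iter=n_iter
    )


# ---------------------------------------------------------------------------
# Study designs
# ---------------------------------------------------------------------------

def run_calibration(config: SimConfig) -> SimulationReport:
    """Monte-Carlo type-I error / power study.

    Each iteration draws a fresh summarized dataset, re-runs every
    selection + estimation pair in the estimator grid (selection uses the
    drawn exposure p-values, as in a data-driven analysis), and records the
    estimate, its SE and whether the 95% CI excluded zero.
    """
    if not config.estimator_grid:
        raise ValueError("estimator_grid is empty")
    rng = np.random.default_rng(config.seed)
    ld = gen_ld(config.ld_spec, config.ld_seed)
    ax = _mvn_factor(np.outer(config.se_x, config.se_x) * ld.rho)
    ay = _mvn_factor(np.outer(config.se_y, config.se_y) * ld.rho)
    accs = _grid_accumulators(config)
    for _ in range(config.n_iter):
        data = _draw_with_factors(config, rng, ld, ax, ay)
        for (m, p), acc in accs.items():
            acc.add(_apply_method(m, p, data, ld))
    return _report(accs, config.n_iter)


def run_subset_sensitivity(
    config: SimConfig,
    subset_fraction: float = 0.5,
    n_rep: int = 1000,
    always_keep: Sequence[str] = (),
) -> SimulationReport:
    """Sensitivity of each estimator to which variants are available.

    One summarized dataset is drawn and held fixed; each replicate drops a
    random ``1 - subset_fraction`` share of the variants before selection and
    estimation.  A small SD of estimates across replicates means the
    estimator is robust to the (often arbitrary) choice of variants.
    ``always_keep`` pins named variants into every subset.
    """
    if not 0 < subset_fraction <= 1:
        raise ValueError("subset_fraction must be in (0, 1]")
    rng = np.random.default_rng(config.seed)
    ld = gen_ld(config.ld_spec, config.ld_seed)
    data = draw_summary(config, rng, ld)
    j = config.n_variants
    n_keep = max(1, round(subset_fraction * j))
    pinned = [data.variant_ids.index(v) for v in always_keep]
    free = [i for i in range(j) if i not in set(pinned)]
    accs = _grid_accumulators(config)
    for _ in range(n_rep):
        if n_keep >= j:
            idx = list(range(j))
        else:
            extra = max(0, n_keep - len(pinned))
            chosen = rng.choice(len(free), size=extra, replace=False)
            idx = sorted(pinned + [free[c] for c in chosen])
        sub, ld_sub = data.subset(idx), ld.subset(idx)
        for (m, p), acc in accs.items():
            acc.add(_apply_method(m, p, sub, ld_sub))
    return _report(accs, n_rep)


def run_ld_bootstrap(
    config: SimConfig,
    ref_n: int = 503,
    n_rep: int = 1000,
    resample: bool = True,
) -> SimulationReport:
    """Sensitivity of each estimator to correlation-matrix estimation.

    One summarized dataset is drawn and held fixed; a reference dosage panel
    of ``ref_n`` individuals consistent with the LD spec is simulated; each
    replicate bootstraps the panel (sampling individuals with replacement),
    recomputes the correlation matrix, and re-runs selection + estimation.
    Variants monomorphic in a bootstrap replicate are dropped for that
    replicate.  With ``resample=False`` every replicate uses the full panel
    matrix (a baseline).  Near-singular regimes typically produce frequent
    undefined SEs here, because bootstrap correlation matrices are exactly
    rank-deficient.
    """
    rng = np.random.default_rng(config.seed)
    ld = gen_ld(config.ld_spec, config.ld_seed)
    data = draw_summary(config, rng, ld)
    panel = gen_reference_panel(config.ld_spec, ref_n, config.ld_seed)
    accs = _grid_accumulators(config)
    for _ in range(n_rep):
        rows = rng.integers(0, ref_n, size=ref_n) if resample else np.arange(ref_n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                ld_rep = compute_ld(panel[rows], data.variant_ids)
            except ValueError:  # pragma: no cover - all monomorphic
                for acc in accs.values():
                    acc.add(None)
                continue
        if len(ld_rep) < len(data):
            sub = data.subset_ids(ld_rep.variant_ids)
        else:
            sub = data
        for (m, p), acc in accs.items():
            acc.add(_apply_method(m, p, sub, ld_rep))
    return _report(accs, n_rep)


# ---------------------------------------------------------------------------
# Individual-level data (2SLS oracle)
# ---------------------------------------------------------------------------

def gen_individual(
    n: int,
    ld_spec: LDSpec,
    gamma: np.ndarray,
    theta: float,
    confounding: float = 0.0,
    seed: int | np.random.Generator | None = 0,
    noise_x: float = 1.0,
    noise_y: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Individual-level genotypes, exposure and outcome.

    Diallelic genotypes are built from pairs of haplotypes consistent with
    the LD spec: for ``ar1``, latent Gaussian haplotypes with the target
    correlation are dichotomised at the ``maf`` quantile (the dosage
    correlations are attenuated relative to the latent ones, which is fine
    for oracle comparisons that estimate LD from the sample itself); for
    ``haplotype``, pairs are drawn from the simulated pool.  The exposure is
    ``G @ gamma + confounding * U + noise`` and the outcome
    ``theta * X + confounding * U + noise`` with a shared standard-normal
    confounder ``U`` — so ordinary regression of Y on X is biased under
    confounding while instrumental-variable estimates are not.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gamma = np.asarray(gamma, dtype=float)
    j = ld_spec.n_variants
    if len(gamma) != j:
        raise ValueError("gamma length must match the number of variants")
    if ld_spec.kind == "haplotype":
        g = gen_reference_panel(ld_spec, n, rng)
    else:
        from scipy.stats import norm

        rho = gen_ld(ld_spec).rho
        chol = np.linalg.cholesky(rho + 1e-12 * np.eye(j))
        cut = norm.ppf(ld_spec.maf)
        g = np.zeros((n, j))
        for _ in range(2):  # two haplotypes per individual
            latent = rng.standard_normal((n, j)) @ chol.T
            g += (latent < cut).astype(float)
    u = rng.standard_normal(n)
    x = g @ gamma + confounding * u + noise_x * rng.standard_normal(n)
    y = theta * x + confounding * u + noise_y * rng.standard_normal(n)
    return g, x, y


def marginal_summaries(
    G: np.ndarray, X: np.ndarray, Y: np.ndarray,
    variant_ids: Sequence[str] | None = None,
) -> tuple[SummaryHalf, SummaryHalf]:
    """Per-variant univariable regression summaries of X and Y on each variant.

    Returns (exposure half, outcome half) with OLS betas and SEs from simple
    linear regressions with intercept — the shape of GWAS summary statistics.
    """
    G = np.asarray(G, dtype=float)
    n, j = G.shape
    ids = list(variant_ids) if variant_ids is not None else _variant_ids(j)
    gc = G - G.mean(axis=0)
    gg = np.einsum("ij,ij->j", gc, gc)
    if np.any(gg <= 0):
        raise ValueError("monomorphic variant in genotype matrix")
    halves = []
    for v in (np.asarray(X, float), np.asarray(Y, float)):
        vc = v - v.mean()
        beta = gc.T @ vc / gg
        rss = float(vc @ vc) - beta ** 2 * gg
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        se = np.sqrt(np.maximum(sigma2 / gg, 1e-300))
        halves.append(SummaryHalf(variant_ids=ids, beta=beta, se=se))
    return halves[0], halves[1]
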