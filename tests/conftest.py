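import numpy as np
import pytest

from finemr import LDMatrix, SummaryHalf, SummarySet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dataset(rng, j, max_rho=0.6):
    """A random aligned (SummarySet, LDMatrix) pair with a valid PD LD matrix."""
    a = rng.standard_normal((j, j + 5))
    cov = a @ a.T + 0.5 * j * np.eye(j)
    d = np.sqrt(np.diag(cov))
    rho = cov / np.outer(d, d)
    rho = np.clip(rho * max_rho / max(np.max(np.abs(rho - np.eye(j))), 1e-9), -1, 1)
    np.fill_diagonal(rho, 1.0)
    # shrink towards identity until positive definite
    while np.linalg.eigvalsh(rho)[0] < 1e-6:
        rho = 0.9 * rho + 0.1 * np.eye(j)
    ids = [f"rs{i}" for i in range(j)]
    data = SummarySet(
        variant_ids=ids,
        beta_x=rng.normal(0.2, 0.1, j),
        se_x=rng.uniform(0.02, 0.05, j),
        beta_y=rng.normal(0.0, 0.05, j),
        se_y=rng.uniform(0.02, 0.08, j),
    )
    return data, LDMatrix(variant_ids=ids, rho=rho)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng, 8)


@pytest.fixture
def exposure_half():
    return SummaryHalf(
        variant_ids=["rs1", "rs2", "rs3", "rs4", "rs5"],
        beta=np.array([0.30, 0.10, -0.20, 0.05, 0.15]),
        se=np.array([0.03, 0.03, 0.04, 0.03, 0.05]),
        effect_allele=["A", "C", "G", "T", "A"],
        other_allele=["G", "T", "A", "C", "C"],
    )


@pytest.fixture
def outcome_half():
    return SummaryHalf(
        variant_ids=["rs1", "rs2", "rs3", "rs4", "rs5"],
        beta=np.array([0.02, 0.01, -0.015, 0.005, 0.01]),
        se=np.array([0.01, 0.01, 0.012, 0.011, 0.015]),
        effect_allele=["A", "C", "G", "T", "A"],
        other_allele=["G", "T", "A", "C", "C"],
    )


@pytest.fixture
def identity_ld():
    return LDMatrix(variant_ids=["rs1", "rs2", "rs3", "rs4", "rs5"], rho=np.eye(5))
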