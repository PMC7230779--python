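import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from atollconnect.genotypes import GenotypeMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(
    genotypes: np.ndarray,
    depth: int | np.ndarray = 30,
    demes: list[str] | None = None,
    sexes: list[str] | None = None,
    stock: str = "natural",
) -> GenotypeMatrix:
    """Build a GenotypeMatrix around a raw genotype array for tests."""
    genotypes = np.asarray(genotypes, dtype=np.int16)
    n, L = genotypes.shape
    if np.isscalar(depth):
        depth = np.full((n, L), depth, dtype=np.int32)
    locus_meta = pd.DataFrame(
        {
            "scaffold": "scaffold1",
            "pos": np.arange(1, L + 1) * 10,
            "ref": "A",
            "alt": "T",
            "is_complex": False,
        }
    )
    meta = pd.DataFrame(
        {
            "id": [f"ind{i + 1:03d}" for i in range(n)],
            "deme": demes if demes is not None else ["demeA"] * n,
            "stock": stock,
            "age": np.nan,
            "sex": sexes if sexes is not None else ["M"] * n,
            "length_cm": np.nan,
            "cohort": "",
        }
    )
    return GenotypeMatrix(genotypes, depth, locus_meta, meta)


def hwe_matrix(
    rng: np.random.Generator,
    n: int,
    n_loci: int,
    freq_range: tuple[float, float] = (0.05, 0.95),
    demes: list[str] | None = None,
) -> GenotypeMatrix:
    """Unrelated HWE individuals at independent loci."""
    p = rng.uniform(*freq_range, size=n_loci)
    g = rng.binomial(2, p, size=(n, n_loci))
    return make_matrix(g, demes=demes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
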