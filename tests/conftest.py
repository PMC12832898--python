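import numpy as np
import pytest

from sphtract.data import normalize_fodf
from sphtract.phantom import PhantomSpec, generate_phantom
from sphtract.sh import SHBasisSpec, SphereGrid
from sphtract.train import Subject


@pytest.fixture(scope="session")
def sh8() -> SHBasisSpec:
    return SHBasisSpec(8)


@pytest.fixture(scope="session")
def quad_grid() -> SphereGrid:
    """Exact product-quadrature grid with >= 4000 points."""
    return SphereGrid.gauss_legendre(50, 100)


@pytest.fixture(scope="session")
def fib_grid() -> SphereGrid:
    return SphereGrid.fibonacci_hemisphere(724)


@pytest.fixture(scope="session")
def crossing16() -> Subject:
    """Tiny crossing phantom for fast training/inference tests."""
    ds = generate_phantom(
        PhantomSpec(volume_side=16, scenario="crossing", seed=11)
    )
    return Subject("cross16", normalize_fodf(ds.fodf), ds.masks)


@pytest.fixture(scope="session")
def crossing32_dataset():
    """The seeded crossing phantom used by the end-to-end overfit check."""
    return generate_phantom(
        PhantomSpec(volume_side=32, scenario="crossing", seed=7)
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
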