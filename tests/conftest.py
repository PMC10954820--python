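import numpy as np
import pytest

from dtialps import AcquisitionScheme, CohortConfig, PhantomGeometry

# compact phantom: same slab layout and ROI placement as the default
# 64^3 grid, just trimmed to the region of interest for fast tests
COMPACT_SHAPE = (48, 20, 20)


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry.default(COMPACT_SHAPE)


@pytest.fixture(scope="session")
def scheme():
    return AcquisitionScheme.default()


@pytest.fixture(scope="session")
def default_cohort():
    """One default 70-subject cohort (tabular only), generated once."""
    from dtialps import generate_cohort

    return generate_cohort(CohortConfig(master_seed=42))


def random_spd_tensor(rng, scale=1e-3):
    """Random positive-definite tensor with realistic diffusivity scale."""
    evals = rng.uniform(0.2, 2.5, size=3) * scale
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    return (Q * evals) @ Q.T
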