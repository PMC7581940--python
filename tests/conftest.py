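import numpy as np
import pytest

from mepflux import CascadeParams, ScenarioConfig


@pytest.fixture
def control_params() -> CascadeParams:
    """Control-like cascade: pools 2/1/0.5 nmol g-1 DW, J=0.2, plateau 0.85."""
    return CascadeParams(2.0, 1.0, 0.5, flux=0.2, plateau=0.85)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240815)


@pytest.fixture
def small_scenario() -> ScenarioConfig:
    """Down-scaled scenario (3 replicates) for fast end-to-end tests."""
    return ScenarioConfig(n_replicates=3, seed=7)


def random_distinct_params(rng: np.random.Generator, size: int):
    """Random cascade parameter sets with well-separated pools.

    Pools and flux span three orders of magnitude (0.05 .. 50); sets whose
    pools nearly coincide are resampled so the closed form is safe.
    """
    out = []
    while len(out) < size:
        pools = 10.0 ** rng.uniform(-1.3, 1.7, size=3)
        rel = np.abs(np.subtract.outer(pools, pools)) / np.maximum.outer(pools, pools)
        if np.min(rel[np.triu_indices(3, 1)]) < 1e-4:
            continue
        flux = 10.0 ** rng.uniform(-1.3, 1.7)
        m = rng.uniform(0.05, 1.0)
        out.append(CascadeParams(*pools, flux=flux, plateau=m))
    return out
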