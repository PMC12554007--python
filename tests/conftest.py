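import numpy as np
import pytest

from methvc.basis import PenaltyMatrices, build_basis
from methvc.data import RegionDataset
from methvc.simulate import SimulationScenario, generate_scenario


@pytest.fixture(scope="session")
def tiny_region():
    """N=10, P=2 region with one real effect; small enough for oracles."""
    sim = generate_scenario(
        SimulationScenario(
            n_samples=10, n_snps=2, n_causal=1, n_cpgs=12,
            effect_scale=1.2, depth_mean=20, seed=7,
        )
    )
    return sim


@pytest.fixture(scope="session")
def tiny_setup(tiny_region):
    ds = tiny_region.dataset
    basis = build_basis(ds.positions, 4)
    matrices = PenaltyMatrices.from_basis(basis, ds.M)
    return ds, basis, matrices


@pytest.fixture(scope="session")
def signal_region():
    """A mid-size region with clear smooth signal for path/CV checks."""
    return generate_scenario(
        SimulationScenario(
            n_samples=40, n_snps=10, n_causal=3, n_cpgs=60,
            effect_scale=1.3, seed=11,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dataset(rng, n_samples=6, n_snps=2, n_cpgs=8, depth=15):
    """Small random but valid dataset for property checks."""
    positions = np.sort(rng.choice(500, size=n_cpgs, replace=False)) + 1000.0
    Z = rng.integers(0, 3, size=(n_samples, n_snps)).astype(float)
    total = rng.poisson(depth, size=n_samples * n_cpgs) + 1
    meth = rng.binomial(total, rng.uniform(0.2, 0.8, size=total.size))
    return RegionDataset(
        sample_idx=np.repeat(np.arange(n_samples), n_cpgs),
        positions=np.tile(positions, n_samples),
        meth=meth,
        total=total,
        genotypes=Z,
    )
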