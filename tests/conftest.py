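import numpy as np
import pytest

from clonosurv import IRParams, LQParams, SurvivalDataset
from clonosurv.synth import NoiseSpec, SimulationSpec, make_dose_grid, simulate_dataset

# A well-identified IR regime (published in a worked example's original
# fit): visible HRS dip, clearly resolved high-dose slope.
TRUTH_IR = IRParams(alpha_r=0.18, alpha_s=1.86, beta=0.14, d_c=0.27)
TRUTH_LQ = LQParams(alpha=0.3, beta=0.05)


@pytest.fixture(scope="session")
def dose_grid():
    return tuple(make_dose_grid(6.0, n_low=6, n_high=4))


@pytest.fixture(scope="session")
def noise_free_dataset(dose_grid):
    return simulate_dataset(
        SimulationSpec(truth=TRUTH_IR, dose_grid=dose_grid, noise=NoiseSpec(sigma=0.0), seed=1)
    )


@pytest.fixture(scope="session")
def noisy_dataset(dose_grid):
    return simulate_dataset(
        SimulationSpec(
            truth=TRUTH_IR, dose_grid=dose_grid, noise=NoiseSpec(sigma=0.05), seed=2
        )
    )


@pytest.fixture()
def small_lq_dataset():
    """Hand-sized weighted LQ dataset for oracle comparisons."""
    doses = np.array([1.5, 2.0, 3.0, 4.0, 5.0, 6.0])
    rng = np.random.default_rng(42)
    sf = np.exp(np.log(np.exp(-0.25 * doses - 0.03 * doses**2)) + 0.05 * rng.standard_normal(6))
    half = 0.08 * sf
    return SurvivalDataset.from_arrays(doses, sf, sf - half, sf + half)
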