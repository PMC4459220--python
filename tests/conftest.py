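import numpy as np
import pytest

from vmhcpipe.synthdata import CohortSpec, NoiseSpec, RegionEffect, simulate_cohort


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Small fast cohort with one planted region per dysconnectivity type."""
    regions = (
        RegionEffect("ACC", (7.5, 6.0, 4.0), 4.0,
                     {"Control": 0.75, "NonAVH": 0.75, "AVH": 0.30}),
        RegionEffect("STR", (7.5, -6.0, -4.0), 4.0,
                     {"Control": 0.75, "NonAVH": 0.30, "AVH": 0.30}),
    )
    return CohortSpec(
        n_per_group=(6, 6, 6), n_volumes=110, n_discard=10,
        grid_shape=(16, 16, 14), regions=regions,
        noise=NoiseSpec(ar1_coefficient=0.3, background_rho=0.2),
        n_motion_outliers=1, master_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec, tmp_path_factory):
    """A simulated cohort written once per session."""
    root = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(tiny_spec, root)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
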