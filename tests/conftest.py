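import numpy as np
import pytest

import screenlight as sl


@pytest.fixture(scope="session")
def tb_small_gsd():
    """Fitted surrogate GSD of the small-grain Tb sample (mean 1.232 um)."""
    return sl.fit_sample("UKL65/UF-R1")


@pytest.fixture(scope="session")
def tb_optics():
    return sl.OpticalConstants.for_activator("Tb")


@pytest.fixture(scope="session")
def tb_small_table(tb_small_gsd, tb_optics):
    return sl.mie_table(tb_small_gsd, tb_optics, packing_fraction=0.5)


@pytest.fixture(scope="session")
def spike_gsd():
    """Degenerate single-diameter distribution at 3.0 um."""
    return sl.GrainSizeDistribution(
        kind="empirical", support_um=np.array([3.0]), weights=np.array([1.0])
    )


@pytest.fixture(scope="session")
def tb_run_100(tb_small_gsd, tb_optics, tb_small_table):
    """Shared moderate-size transport run: Tb small-grain, 100 um slab."""
    return sl.run_simulation(
        tb_small_gsd, tb_optics, sl.LayerSpec(thickness_um=100.0),
        n_photons=40_000, seed=11, table=tb_small_table,
    )
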