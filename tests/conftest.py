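import dataclasses

import numpy as np
import pytest

from fesip import geochem, sip_gradient, synthetic


@pytest.fixture
def windows():
    return sip_gradient.DensityWindows()


@pytest.fixture
def silent_params():
    """Noiseless generator parameters: the deterministic stoichiometric core."""
    return dataclasses.replace(
        synthetic.SimulationParams(), noise=synthetic.NoiseModel.silent()
    )


@pytest.fixture
def fer_spec():
    return geochem.MicrocosmSpec("NF", "FER", fe_added_umol_per_g=140.0)


@pytest.fixture
def small_profile():
    return sip_gradient.GradientProfile(
        treatment="t", domain="Bacteria",
        fraction_index=[1, 2, 3, 4],
        bd=[1.80, 1.79, 1.78, 1.77],
        copies=[2.0, 8.0, 4.0, 1.0],
    )


@pytest.fixture
def taxon_table():
    """Small deterministic taxon table: 3 labeled + 3 unlabeled FER samples
    plus CTR pairs, two soils not needed."""
    table, _ = synthetic.simulate_taxon_table(
        synthetic.SimulationParams(seed=11), soil="NF",
        rng=np.random.default_rng(11),
    )
    return table
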