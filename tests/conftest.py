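import numpy as np
import pytest
from hypothesis import settings

from defoliascan import synthgen

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_table():
    """One default synthetic spectra table (284 x 145), shared read-only."""
    return synthgen.generate_spectra_dataset(synthgen.SpectraConfig(seed=7))


@pytest.fixture()
def tiny_spectra():
    """Three-band, three-tree table with hand-pickable reflectances."""
    from defoliascan.dataio import SpectraTable

    return SpectraTable(
        tree_id=np.array(["a", "b", "c"], dtype=object),
        stage=np.array([1, 2, 3]),
        dp=np.array([10.0, 40.0, 60.0]),
        reflectance=np.array(
            [
                [0.05, 0.45, 0.35],
                [0.30, 0.30, 0.30],
                [0.20, 0.10, 0.40],
            ]
        ),
        wavelengths=np.array([686.0, 759.0, 926.0]),
    )
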