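import numpy as np
import pytest

from cellsolv.synthetic import BundleSpec, build_ibeta_bundle


@pytest.fixture(scope="session")
def bundle_2x2():
    """4 strands on a 2x2 cross-section, 6 glycans each."""
    return build_ibeta_bundle(
        BundleSpec(n_strands=4, n_glycans_per_strand=6,
                   layout=[(0, 0), (0, 1), (1, 0), (1, 1)])
    )


@pytest.fixture(scope="session")
def bundle_18x12():
    """The small-bundle geometry: 18 strands x 12 glycans."""
    return build_ibeta_bundle(BundleSpec(n_strands=18, n_glycans_per_strand=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
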