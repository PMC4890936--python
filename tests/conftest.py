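import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def helix_traj():
    from ubikin.synthetic_data import build_ideal_helix

    return build_ideal_helix(12)


@pytest.fixture
def sheet_traj():
    from ubikin.synthetic_data import build_antiparallel_sheet

    return build_antiparallel_sheet(8)


@pytest.fixture
def site_spec():
    from ubikin.synthetic_data import SynthSiteSpec

    return SynthSiteSpec(n_kinases=200, sites_per_kinase=4, seed=11)


@pytest.fixture
def toy_alignment():
    """Four kinase-like entries plus a reference with known gap structure."""
    from ubikin.domain_mapping import MultipleAlignment

    return MultipleAlignment([
        ("REF", "MKT-LKDE"),
        ("KIN1", "MKTALKDE"),
        ("KIN2", "M-TALKD-"),
        ("KIN3", "MKTALK-E"),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
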