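import logging

import pytest
from hypothesis import settings

import ivtwin as iv
from ivtwin.synthetic import FIXTURE_KM, FIXTURE_VMAX

logging.disable(logging.WARNING)  # silence intentional default-use warnings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ref_params() -> iv.KineticParams:
    """Apparent-constant parameter set of the reference study."""
    return iv.KineticParams(vmax=FIXTURE_VMAX, Km=dict(FIXTURE_KM))


@pytest.fixture(scope="session")
def bnt_transcript() -> iv.TranscriptSpec:
    return iv.synthetic.bnt_like_transcript()


@pytest.fixture(scope="session")
def equimolar_transcript() -> iv.TranscriptSpec:
    return iv.TranscriptSpec(
        name="equimolar", n_mRNA=100,
        f={"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25},
    )


@pytest.fixture(scope="session")
def ppiase_strong() -> iv.PPiaseParams:
    """Hydrolysis capacity far above any release rate in the tests."""
    return iv.PPiaseParams(k_PPiase=1e6, c_PPase=0.1, Km_PPi=50.0)


@pytest.fixture(scope="session")
def ppiase_off() -> iv.PPiaseParams:
    return iv.PPiaseParams.off()
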