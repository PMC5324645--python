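import pytest

from ivk.assigner import AssignmentConfig, assign
from ivk.generator import ElementRanges
from ivk.synth import MixtureSpec, make_mixture

#: Fixed seed for the reference SRFA-like mixture used across tests.
SRFA_SEED = 20170220


@pytest.fixture(scope="session")
def srfa_mixture():
    """The reference synthetic mixture: 50 series, 0.2 ppm error,
    13C1 satellites on, 100 unassignable noise peaks."""
    spec = MixtureSpec(n_series=50, sigma_ppm=0.2, isotopologues=True,
                       n_noise_peaks=100, seed=SRFA_SEED)
    return make_mixture(spec)


@pytest.fixture(scope="session")
def srfa_config():
    """Assignment settings with element ranges matched to the compound
    classes the mixture emits (CHO/CHNO/CHOS with N<=2, S<=1)."""
    return AssignmentConfig(ranges=ElementRanges(n=(0, 2), s=(0, 1)))


@pytest.fixture(scope="session")
def srfa_assignment(srfa_mixture, srfa_config):
    peaks, _ = srfa_mixture
    return assign(peaks, srfa_config)


@pytest.fixture(scope="session")
def srfa_report_model(srfa_assignment):
    from ivk.report import build_report_model
    return build_report_model(srfa_assignment)
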