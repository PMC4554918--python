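import pytest

import slimsplice as ss


@pytest.fixture(scope="session")
def locus():
    """Default NCoR2-like synthetic locus (internal GT donor on exon 37)."""
    return ss.simulate_locus(seed=11)


@pytest.fixture(scope="session")
def ncor1_locus():
    """NCoR1-like locus: cryptic GA where the paralogue keeps its GT donor."""
    return ss.simulate_locus(ss.ncor1_like_config(), seed=11)


@pytest.fixture(scope="session")
def pwm_model(locus):
    return ss.train_pwm(locus.donors)


@pytest.fixture(scope="session")
def donor_stats(locus, pwm_model):
    return ss.donor_score_stats(locus.donors, pwm_model)


@pytest.fixture(scope="session")
def cornr():
    return ss.parse_slim_pattern(ss.CORNR_CONSENSUS, "CoRNR")
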