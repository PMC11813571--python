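import pytest

from whalesong.okinawa import load_okinawa, load_okinawa_scores


@pytest.fixture(scope="session")
def okinawa():
    return load_okinawa()


@pytest.fixture(scope="session")
def okinawa_scores():
    return load_okinawa_scores()
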