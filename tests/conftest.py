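import pytest

from rufold import pairwise_scheme, unit_scheme


@pytest.fixture
def unit():
    return unit_scheme()


@pytest.fixture(params=["unit", "au2cg3"])
def any_scheme(request):
    """The two scoring regimes exercised throughout: C=2 and C=4."""
    if request.param == "unit":
        return unit_scheme()
    return pairwise_scheme(au=2, cg=3)


def make_schemes(d: int):
    return [unit_scheme(d=d), pairwise_scheme(au=2, cg=3, d=d)]
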