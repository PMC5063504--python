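import numpy as np
import pytest

from tncfret import make_reference_spectra

# Table-style parameter sets used as generator ground truth across tests
DOUBLE_HILL_CA = dict(
    f_min=0.040, f_max1=0.133, n1=2.70, p50_1=7.17, f_max2=-0.082, n2=0.94, p50_2=5.47
)
SINGLE_HILL_MG = dict(f_min=0.043, f_max=0.215, n=1.09, p50=3.28)
FORCE_HILL_WT = dict(model="force", p50=5.74, n=1.37)


@pytest.fixture(scope="session")
def refs():
    return make_reference_spectra()


@pytest.fixture
def rng():
    return np.random.default_rng(20160)
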