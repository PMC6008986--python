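import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def catalog():
    from regchar.motif_scan import default_catalog

    return default_catalog()


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture()
def jaspar_ac_pfm(tmp_path):
    """Synthetic 2-column PFM whose unique argmax word is AC."""
    path = tmp_path / "AC_test.pfm"
    path.write_text(">M0001 AC_test\nA [10 0]\nC [0 10]\nG [0 0]\nT [0 0]\n")
    return path
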