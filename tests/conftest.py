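import pytest
from hypothesis import settings

from npuptake.qcm import BulkLiquid, CrystalParams

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def crystal() -> CrystalParams:
    return CrystalParams()  # 5 MHz AT-cut defaults


@pytest.fixture(scope="session")
def pbs() -> BulkLiquid:
    return BulkLiquid(rho_b=1000.0, eta_b=1e-3)
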