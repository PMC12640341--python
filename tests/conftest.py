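import pytest
from hypothesis import HealthCheck, settings

from capcolony import PackingModel, run_paper_grid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def packing():
    """Reference packing: 1-μm cell, F_2D = 1.2, derived F_3D."""
    return PackingModel(r_c=1.0, f_2d=1.2)


@pytest.fixture(scope="session")
def paper_grid():
    """The 15-run reference grid (3 anisotropy regimes x 5 gamma values)."""
    return run_paper_grid()
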