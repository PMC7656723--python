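import pathlib

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from posegrep.fixtures import FixtureSpec, make_screen_fixture  # noqa: E402


@pytest.fixture(scope="session")
def screen7(tmp_path_factory) -> dict:
    """The reference synthetic screen: seed 7, 100 compounds, 3 poses each,
    40% designed to pass, mixed PDBQT/PDB/SDF formats."""
    root = tmp_path_factory.mktemp("screen7")
    spec = FixtureSpec(seed=7, n_compounds=100, poses_per_compound=3,
                       fraction_designed_to_pass=0.4,
                       formats=("PDBQT", "PDB", "SDF"))
    receptor, compounds, filters, truth = make_screen_fixture(root, spec)
    return {"root": pathlib.Path(root), "receptor": receptor,
            "compounds": compounds, "filters": filters, "truth": truth,
            "spec": spec}


@pytest.fixture()
def small_screen(tmp_path):
    spec = FixtureSpec(seed=11, n_compounds=10, poses_per_compound=2)
    receptor, compounds, filters, truth = make_screen_fixture(tmp_path, spec)
    return receptor, compounds, filters, truth
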