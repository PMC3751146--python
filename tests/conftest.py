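import numpy as np
import pytest

import cardrisk as cr
from cardrisk.dvh import DifferentialDVH

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def gen_settings():
    return cr.GeneratorSettings(seed=1)


@pytest.fixture(scope="session")
def hd_case(gen_settings):
    """Full mediastinal-HD synthetic case (DVHs + dose table), seed 1."""
    return cr.build_case(cr.hd_template(), gen_settings)


@pytest.fixture(scope="session")
def mb_case(gen_settings):
    """Full craniospinal-MB synthetic case (DVHs + dose table), seed 1."""
    return cr.build_case(cr.mb_template(), gen_settings)


@pytest.fixture(scope="session")
def hd_means():
    """Mean-dose-table-only HD case (RR computable, no DVHs)."""
    return cr.build_dose_table_case(cr.hd_template())


@pytest.fixture(scope="session")
def mb_means():
    return cr.build_dose_table_case(cr.mb_template())


def make_dvh(doses, volumes, unit="Gy", bin_width=None, structure="organ"):
    v = np.asarray(volumes, dtype=float)
    return DifferentialDVH(structure, unit, np.asarray(doses, dtype=float), v / v.sum(), bin_width)


@pytest.fixture
def dvh_factory():
    return make_dvh
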