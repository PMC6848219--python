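import numpy as np
import pytest

import mucuswalk as mw


@pytest.fixture(scope="session")
def table1():
    """All rows of the packaged diffusivity table."""
    return mw.load_table1()


@pytest.fixture(scope="session")
def table2():
    """All rows of the packaged viscosity table."""
    return mw.load_table2()


@pytest.fixture(scope="session")
def wt_1pct(table1):
    """Wild-type row at 1% mucin (the headline subdiffusive condition)."""
    return mw.table1_row(table1, 1.0, "wt")


@pytest.fixture(scope="session")
def wt_1pct_params(wt_1pct):
    """Calibrated CTRW parameters at 1% mucin."""
    return mw.ctrw_times_from_diffusivities(wt_1pct)


@pytest.fixture(scope="session")
def dhoc_1pct_brownian():
    """Non-adherent phage model at 1% mucin: plain diffusion, D = 2.54 µm²/s."""
    return mw.CTRWParams(nu=1.0, tau_0=0.0, tau_D=0.01, D=2.54)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
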