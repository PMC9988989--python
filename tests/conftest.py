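import numpy as np
import pandas as pd
import pytest

import crestscope as cs
from crestscope.panel_io import CellMeta, CountMatrix, ProbeClass, ProbePanel
from crestscope.qc_normalize import run_qc

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def nanostring_fixture():
    """Default ~600-cell cohort with ground truth (raw counts)."""
    return cs.generate_nanostring(cs.default_nanostring_spec(FIXTURE_SEED))


@pytest.fixture(scope="session")
def logged_fixture(nanostring_fixture):
    """QC'd, normalized, imputed, logged matrix over the default cohort."""
    m, panel, meta, truth = nanostring_fixture
    logged, report, panel2 = run_qc(m, panel, seed=FIXTURE_SEED)
    return logged, report, panel2, meta, truth


@pytest.fixture(scope="session")
def taqman_fixture():
    return cs.generate_taqman(cs.default_taqman_spec(FIXTURE_SEED))


@pytest.fixture
def tiny_panel():
    return ProbePanel(
        ("g1", "g2", "g3", "hk", "spike"),
        {
            "g1": ProbeClass.ENDOGENOUS,
            "g2": ProbeClass.ENDOGENOUS,
            "g3": ProbeClass.ENDOGENOUS,
            "hk": ProbeClass.HOUSEKEEPING,
            "spike": ProbeClass.SPIKE_IN,
        },
    )


def make_counts(rows, cells=None, probes=None, stage="raw"):
    rows = np.asarray(rows)
    cells = cells or [f"c{i}" for i in range(rows.shape[0])]
    probes = probes or [f"g{j}" for j in range(rows.shape[1])]
    return CountMatrix(pd.DataFrame(rows, index=cells, columns=probes), stage)


def make_meta(cells, sources):
    return CellMeta(pd.DataFrame({"source": sources, "stage_hpf": np.nan}, index=list(cells)))
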