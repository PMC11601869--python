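import numpy as np
import pandas as pd
import pytest

from cycleage import (
    ProteomeConfig,
    SingleCellConfig,
    TimecourseConfig,
    gen_proteome,
    gen_timecourse,
)


@pytest.fixture(scope="session")
def small_timecourse():
    """Noisy 4-timepoint matrix with 20 UDU + 20 DUD planted among 300."""
    cfg = TimecourseConfig(n_genes=300, n_cyclic_udu=20, n_cyclic_dud=20, seed=11)
    return gen_timecourse(cfg)


@pytest.fixture(scope="session")
def noisefree_timecourse():
    cfg = TimecourseConfig(
        n_genes=60, n_cyclic_udu=10, n_cyclic_dud=10, n_monotonic=10,
        amplitude=2.0, noise_sd=0.0, seed=7,
    )
    return gen_timecourse(cfg)


@pytest.fixture(scope="session")
def clean_proteome():
    cfg = ProteomeConfig(n_background=50, n_cyclic=16, missing_rate=0.0, seed=5)
    return gen_proteome(cfg)


@pytest.fixture()
def marker_counts():
    """Hand-built cells x genes counts exercising every label branch."""
    genes = ["Prlr", "Pgr", "Esr1", "Mfge8", "Trf", "Krt14", "Krt5", "Actb"]
    rows = {
        "pure_hs": [30, 30, 30, 0, 0, 0, 0, 1],
        "pure_av": [0, 0, 0, 40, 40, 0, 0, 1],
        "pure_me": [0, 0, 0, 0, 0, 35, 35, 1],
        "mixed": [30, 30, 30, 45, 45, 0, 0, 1],
        "empty": [0, 0, 0, 0, 0, 0, 0, 0],
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=genes)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240321)
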