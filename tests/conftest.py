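import numpy as np
import pytest

import rtwstates as rs
from rtwstates.pipeline import AnalysisConfig, run_full_analysis


@pytest.fixture(scope="session")
def medium_confounded():
    """Confounded-null cohort of ~2000 persons run through the full pipeline."""
    cfg = AnalysisConfig(
        sim=rs.SimConfig.for_n_persons(2000, seed=301, scenario="confounded_null"),
        run_negative_control=True,
        make_figures=False,
    )
    return run_full_analysis(cfg)


@pytest.fixture(scope="session")
def medium_null():
    """Randomised-null cohort (~2000 persons): no confounding, no effect."""
    cfg = AnalysisConfig(
        sim=rs.SimConfig.for_n_persons(2000, seed=302, scenario="null"),
        run_negative_control=False,
        make_figures=False,
    )
    return run_full_analysis(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """Small raw simulated registry (~650 persons), confounded-null."""
    return rs.simulate_cohort(
        rs.SimConfig.for_n_persons(650, seed=303, scenario="confounded_null")
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
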