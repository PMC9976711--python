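import logging

import numpy as np
import pandas as pd
import pytest

from alcres import synthdata
from alcres.config import SimConfig

logging.getLogger("alcres").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_families=300, seed=1)


@pytest.fixture(scope="session")
def panel(small_cfg):
    return synthdata.simulate_panel(small_cfg)


@pytest.fixture(scope="session")
def subjects_frame(panel) -> pd.DataFrame:
    return synthdata.subjects_to_frame(panel[0])


@pytest.fixture(scope="session")
def relatives_frame(panel) -> pd.DataFrame:
    return synthdata.relatives_to_frame(panel[1])


@pytest.fixture(scope="session")
def scores_frame(subjects_frame):
    from alcres import scales

    return scales.score_subjects(subjects_frame)


@pytest.fixture(scope="session")
def genrisk_frame(subjects_frame, relatives_frame):
    from alcres import genrisk

    return genrisk.compute_genetic_risk(subjects_frame, relatives_frame)


@pytest.fixture(scope="session")
def resistance_outputs(subjects_frame, genrisk_frame):
    from alcres import resistance

    return resistance.resistance_phenotypes(
        subjects_frame, genrisk_frame, cluster_mode="robust"
    )


def one_factor_data(n: int, loadings, seed: int = 0, means=None) -> pd.DataFrame:
    """Continuous indicators generated exactly from a one-factor model."""
    rng = np.random.default_rng(seed)
    f = rng.normal(size=n)
    means = means if means is not None else np.zeros(len(loadings))
    cols = {
        f"x{k}": m + lam * f + np.sqrt(1 - lam**2) * rng.normal(size=n)
        for k, (lam, m) in enumerate(zip(loadings, means))
    }
    return pd.DataFrame(cols)
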