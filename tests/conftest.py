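import numpy as np
import pandas as pd
import pytest

from pfasmix.config import PFAS_NAMES, CohortConfig
from pfasmix.exposures import ExposurePanel, filter_by_detection
from pfasmix.synthetic import (
    censor_below_lod,
    generate_cohort,
    generate_replicate_weights,
)


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(n_participants=1500, seed=11, n_replicates=50)


@pytest.fixture(scope="session")
def cohort(default_config):
    """Uncensored synthetic cohort (ground-truth concentrations)."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def prepared(default_config, cohort):
    """Censored -> imputed cohort plus its survey design."""
    cfg = default_config
    cens, _ = censor_below_lod(cohort, cfg.lod)
    panel = ExposurePanel(
        cens[list(PFAS_NAMES)].copy(),
        dict(cfg.lod),
        cens[[f"{a}_nd" for a in PFAS_NAMES]].rename(
            columns={f"{a}_nd": a for a in PFAS_NAMES}
        ),
    )
    panel = filter_by_detection(panel).fit_and_impute(seed=7)
    out = cens.copy()
    for a in panel.analytes:
        out[a] = panel.concentrations[a]
    design = generate_replicate_weights(out, cfg.n_replicates, seed=cfg.seed + 1)
    return out, design


def make_record(**overrides) -> pd.DataFrame:
    """One complete, criterion-negative participant record."""
    base = {
        "sex": "male",
        "asian_flag": False,
        "age": 45.0,
        "wc": 90.0,
        "tg": 1.0,
        "hdl": 1.5,
        "glu": 5.0,
        "sbp": 115.0,
        "dbp": 70.0,
        "hba1c": 5.2,
        "med_lipid": False,
        "med_bp": False,
        "med_diabetes": False,
        "dx_hypertension": False,
        "dx_t2d": False,
    }
    base.update(overrides)
    return pd.DataFrame([base])


@pytest.fixture
def record_factory():
    return make_record
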