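import numpy as np
import pandas as pd
import pytest

from portal_its.synthetic_emr import SynthConfig, generate_population


def make_patient(**overrides):
    """A fully-specified adult patient row for unit tests."""
    base = {
        "patient_id": "P1",
        "birth_date": pd.Timestamp("1970-01-15"),
        "sex": "female",
        "rostered": True,
        "obs_start": pd.Timestamp("2002-01-01"),
        "obs_end": pd.Timestamp("2019-12-31"),
        "portal_date": pd.NaT,
        "income_band": "",
        "education_band": "",
        "dx_cad_onset": pd.NaT,
        "dx_chf_onset": pd.NaT,
        "dx_copd_onset": pd.NaT,
        "dx_dm_onset": pd.NaT,
        "dx_htn_onset": pd.NaT,
    }
    base.update(overrides)
    return pd.Series(base)


@pytest.fixture(scope="session")
def small_bundle():
    """Shared mid-size synthetic bundle (covariate-driven registration)."""
    cfg = SynthConfig(n_patients=1200, seed=20240915)
    return generate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
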