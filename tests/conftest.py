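import numpy as np
import pandas as pd
import pytest

import pleioscan as ps
from pleioscan.assay import PARTICIPANT_COLUMNS, Cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_discovery_cohort():
    """A fast, fully-featured discovery cohort (shared, read-only)."""
    cfg = ps.discovery_default_config(n_proteins=8, seed=42)
    return ps.generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """No censoring/contamination/missingness; 3 proteins with planted effects."""
    cfg = ps.discovery_default_config(
        n_proteins=3, seed=7, lod_quantile_map={}, duplicate_spec=[],
        contamination=(0.0, 0.0), missing_fraction=0.0,
    )
    return ps.generate_cohort(cfg)


def make_toy_cohort(participants: pd.DataFrame, panel=None, label="toy") -> Cohort:
    for col in PARTICIPANT_COLUMNS:
        if col not in participants.columns:
            participants[col] = np.nan
    return Cohort(
        study_label=label,
        participants=participants.loc[:, list(PARTICIPANT_COLUMNS)],
        panel=panel or [],
    )
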