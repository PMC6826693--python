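import numpy as np
import pandas as pd
import pytest

import exopipe as xp
from exopipe.datatypes import NormalizedMatrix


def make_ct(data: dict[str, list], mirnas: list[str]) -> xp.CTMatrix:
    """CTMatrix from {sample_id: [ct, ...]} with NaN for missing."""
    return xp.CTMatrix(pd.DataFrame.from_dict(data, orient="index", columns=mirnas))


def make_norm(delta: pd.DataFrame, detected=None, imputed=None) -> NormalizedMatrix:
    if detected is None:
        detected = delta.notna()
    if imputed is None:
        imputed = pd.DataFrame(False, index=delta.index, columns=delta.columns)
    return NormalizedMatrix(delta, detected, imputed)


@pytest.fixture(scope="session")
def reference_list():
    return xp.load_reference_chemoresistance_list()


@pytest.fixture(scope="session")
def reference_diffexpr():
    return xp.load_reference_diffexpr().set_index("mirna")


@pytest.fixture(scope="session")
def default_cohort():
    return xp.simulate_cohort(xp.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def preprocessed_cohort(default_cohort):
    ct = default_cohort.ct
    rel = xp.filter_reliable_ct(ct)
    norm = xp.normalize_global_mean(rel)
    norm_f, dropped = xp.detection_filter(norm)
    norm_i = xp.impute_missing(norm_f)
    return default_cohort, norm_i, dropped
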