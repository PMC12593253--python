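import numpy as np
import pandas as pd
import pytest

import igsense as ig


@pytest.fixture(scope="session")
def design():
    return ig.generate_design(seed=11)


@pytest.fixture(scope="session")
def metrics(design):
    return ig.compute_design_metrics(design)


@pytest.fixture(scope="session")
def small_cohort(design, metrics):
    """20 infants, no attrition, full design, fast to fit."""
    hp = ig.PopulationHyperparams(attrition_rate=0.0, dropout_rate=0.0)
    infants = ig.simulate_infants(n=20, hyperparams=hp, seed=21)
    records = ig.simulate_study(design, metrics, infants, seed=22, truncate=False)
    return infants, records


def make_outcome_tables(z, fsiq, ses, vci=None, vsi=None, wmi=None):
    """Per-infant sensitivity + outcome tables from raw vectors."""
    n = len(z)
    ids = [f"i{j:03d}" for j in range(n)]
    sens = pd.DataFrame(
        {"infant_id": ids, "slope_mean": z, "slope_sd": 1.0, "slope_z": z}
    )
    fsiq = np.asarray(fsiq, float)
    outc = pd.DataFrame(
        {
            "infant_id": ids,
            "fsiq": fsiq,
            "vci": fsiq if vci is None else vci,
            "vsi": fsiq if vsi is None else vsi,
            "wmi": fsiq if wmi is None else wmi,
            "ses": ses,
        }
    )
    return sens, outc
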