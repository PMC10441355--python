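import numpy as np
import pandas as pd
import pytest

from epiage.io_methylation import BetaMatrix
from epiage.simulate import MethylSimConfig, simulate_methylomes


def make_annotation(sample_ids, **overrides):
    """Minimal valid sample sheet for the given ids."""
    n = len(sample_ids)
    base = {
        "sample_id": list(sample_ids),
        "species": ["rat"] * n,
        "tissue": ["blood"] * n,
        "age": [1.0] * n,
        "sex": ["F"] * n,
        "batch_plate": ["p1"] * n,
        "batch_column": ["c1"] * n,
        "group": ["none"] * n,
        "subject_id": list(sample_ids),
        "timepoint": [0] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


def make_matrix(values, probe_prefix="cg", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    probes = np.array([f"{probe_prefix}{i}" for i in range(values.shape[0])],
                      dtype=object)
    samples = np.array([f"{sample_prefix}{j}" for j in range(values.shape[1])],
                       dtype=object)
    return BetaMatrix(probes, samples, values)


@pytest.fixture(scope="session")
def small_panel():
    """Fast single-tissue aging panel: 30 samples x 120 probes, 20 aging."""
    cfg = MethylSimConfig(
        n_probes=120,
        n_age_probes=20,
        tissues={"blood": 30},
        seed=11,
    )
    return simulate_methylomes(cfg), cfg


@pytest.fixture(scope="session")
def treatment_panel():
    """Single-tissue three-arm study plus a matched training panel."""
    from epiage.simulate import TreatmentSimConfig, simulate_treatment_study

    base = MethylSimConfig(
        n_probes=400,
        n_age_probes=60,
        tissues={"blood": 40},
        seed=21,
    )
    train = simulate_methylomes(base)
    tcfg = TreatmentSimConfig(base=base, planted_rejuvenation=50.0, seed=22)
    study = simulate_treatment_study(tcfg)
    return train, study, tcfg
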