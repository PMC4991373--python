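import numpy as np
import pandas as pd
import pytest

import vitremir as v


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Deterministic cohort with the default fold effects and zero Ct noise."""
    cfg = v.SimConfig(ct_noise_sd=0.0, seed=11)
    records, meta, truth = v.simulate_cohort(cfg)
    return cfg, records, meta, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = v.SimConfig(ct_noise_sd=1.0, seed=7)
    records, meta, truth = v.simulate_cohort(cfg)
    return cfg, records, meta, truth


@pytest.fixture(scope="session")
def hla_g_motif():
    """The documented miR-152-3p binding-site interval in the HLA-G 3'UTR."""
    return pd.DataFrame(
        [
            {"chrom": "6", "start": 29830959, "end": 29830978,
             "mir_id": "miR-152-3p", "gene": "HLA-G", "evidence": "validated", "score": 1.0},
        ]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
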