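import numpy as np
import pandas as pd
import pytest

from atrisk import synth
from atrisk.methylome import BetaMatrix


@pytest.fixture
def small_synth_cfg():
    """Scaled-down generator settings for fast unit tests."""
    return synth.SynthConfig(
        n_per_group_per_cohort=6,
        n_probes=300,
        n_planted_dml=20,
        delta_beta_effect=0.3,
        beta_noise_sd=0.03,
        n_subjects_flow=3,
        n_events_per_subject=600,
        n_subjects_serum={"ctrl": 40, "at_risk": 30, "early_ra": 20},
        seed=7,
    )


@pytest.fixture
def tiny_beta():
    """Hand-built two-group, one-cohort beta matrix (4 probes, 8 samples)."""
    rng = np.random.default_rng(0)
    probes = [f"cg{i}" for i in range(4)]
    cols = {}
    meta = []
    for g, base in (("ctrl", 0.3), ("at_risk", 0.5)):
        for i in range(4):
            sid = f"{g}_{i}"
            cols[sid] = np.clip(base + rng.normal(0, 0.02, size=4), 0, 1)
            meta.append((sid, g, 1, "Tmem", sid))
    values = pd.DataFrame(cols, index=probes)
    meta = pd.DataFrame(meta, columns=["sample", "group", "cohort", "cell_type", "subject"]).set_index("sample")
    return BetaMatrix(values, meta)
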