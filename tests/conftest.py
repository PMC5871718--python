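import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_psm_frame(n, intensities=None, **overrides):
    """Minimal PSM table with passing quality values; columns overridable."""
    base = {
        "protein_group": ["P1"] * n,
        "peptide_sequence": [f"PEPTIDEK{i}" for i in range(n)],
        "is_unique": [True] * n,
        "silac_channel": ["light"] * n,
        "replicate": [1] * n,
        "identification_score": [40.0] * n,
        "precursor_s2b": [10.0] * n,
        "s2i": [0.9] * n,
        "accumulation_time": [50.0] * n,
        "peptide_length": [9] * n,
    }
    base.update(overrides)
    df = pd.DataFrame(base)
    if intensities is not None:
        for channel, values in intensities.items():
            df[f"intensity_{channel}"] = values
    return df


@pytest.fixture
def psm_frame_factory():
    return make_psm_frame
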