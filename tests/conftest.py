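import numpy as np
import pandas as pd
import pytest

from triomics.simulate import MetabolomeTruth, feature_ids, generate_metabolome


@pytest.fixture(scope="session")
def planted_metabolome():
    """Two-group metabolome: 10 differential features, 3 correlated blocks."""
    feats = feature_ids(120)
    truth = MetabolomeTruth(
        diff_features=frozenset(feats[:10]),
        effect_size=2.0,
        module_blocks={
            "b1": feats[20:40],
            "b2": feats[40:55],
            "b3": feats[55:70],
        },
        block_cor=0.8,
    )
    abundance, metadata = generate_metabolome(24, 120, truth, seed=11)
    return abundance, metadata, truth


@pytest.fixture(scope="session")
def log_xy(planted_metabolome):
    """Sample × feature log matrix plus the 0/1 class vector."""
    abundance, metadata, _ = planted_metabolome
    X = np.log(abundance).T
    y = (metadata.set_index("sample_id").loc[X.index, "group"] == "DD").astype(float)
    return X, y.to_numpy()


@pytest.fixture
def toy_instruments():
    """Three instruments with identical Wald ratios of 0.2."""
    return pd.DataFrame(
        {
            "snp": ["rs1", "rs2", "rs3"],
            "beta_exp": [0.1, 0.2, 0.5],
            "se_exp": [0.01, 0.01, 0.02],
            "beta_out": [0.02, 0.04, 0.10],
            "se_out": [0.01, 0.01, 0.02],
            "n_exp": [8000, 8000, 8000],
            "n_out": [50000, 50000, 50000],
        }
    )
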