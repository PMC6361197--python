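import numpy as np
import pandas as pd
import pytest

from lncnet import (
    ExpressionMatrix,
    Group,
    SyntheticDesign,
    TranscriptClass,
    default_blocks,
    generate_matrix,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 transcripts x 6 samples (3 tumor + 3 normal), hand-set intensities.

    t_up:   tumor mean 4x normal.      t_down: tumor mean 1/4 of normal.
    t_flat: identical groups.          t_sub:  fold change just under 2.
    """
    values = pd.DataFrame(
        {
            "T1": [8.8, 1.1, 5.0, 3.98],
            "T2": [8.0, 1.0, 5.2, 3.90],
            "T3": [7.2, 0.9, 4.8, 4.06],
            "N1": [2.2, 4.4, 5.1, 2.00],
            "N2": [2.0, 4.0, 4.9, 1.96],
            "N3": [1.8, 3.6, 5.0, 2.04],
        },
        index=["t_up", "t_down", "t_flat", "t_sub"],
    )
    groups = {s: Group.TUMOR if s.startswith("T") else Group.NORMAL
              for s in values.columns}
    classes = {
        "t_up": TranscriptClass.LNCRNA,
        "t_down": TranscriptClass.LNCRNA,
        "t_flat": TranscriptClass.MRNA,
        "t_sub": TranscriptClass.MRNA,
    }
    return ExpressionMatrix(values, groups, classes)


@pytest.fixture
def blocked_design() -> SyntheticDesign:
    """Blocks only, no planted DE: the planted-network recovery condition."""
    return SyntheticDesign(seed=42, de_fraction=0.0, noise_sd=0.1,
                           blocks=default_blocks())


@pytest.fixture
def blocked_dataset(blocked_design):
    return generate_matrix(blocked_design)


def permutation_corr_pvalue(x, y, n_perm: int, seed: int) -> float:
    """Monte-Carlo two-sided permutation P for the Pearson correlation."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    xc /= np.sqrt((xc ** 2).sum())
    yc = y - y.mean()
    r_obs = float(xc @ (yc / np.sqrt((yc ** 2).sum())))
    idx = np.argsort(rng.random((n_perm, x.size)), axis=1)
    yp = y[idx]
    ypc = yp - yp.mean(axis=1, keepdims=True)
    ypc /= np.sqrt((ypc ** 2).sum(axis=1, keepdims=True))
    r_perm = ypc @ xc
    return float((np.abs(r_perm) >= abs(r_obs) - 1e-12).mean())
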