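import numpy as np
import pandas as pd
import pytest

from methcascade import (
    MethylationMatrix,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def planted_cohort():
    """Strong-effect cohort: 5 planted DMRs, 100 cancer / 100 healthy plasma
    samples, tumor fraction 10-20% over a 2% background."""
    cfg = SimulationConfig(
        n_cancer=100, n_benign=5, n_healthy=100,
        n_tumor_tissue=10, n_wbc=10,
        n_regions=30, n_true_dmr=5,
        healthy_beta_mean=0.02, tumor_beta_mean=0.60,
        tumor_fraction_range=(0.10, 0.20),
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Zero-effect cohort: tumor fraction pinned at 0, so every region is
    noise for the cancer/healthy contrast."""
    cfg = SimulationConfig(
        n_cancer=30, n_benign=5, n_healthy=30,
        n_tumor_tissue=5, n_wbc=5,
        n_regions=60, n_true_dmr=5,
        tumor_fraction_range=(0.0, 0.0),
        seed=11,
    )
    return simulate_cohort(cfg)


def matrix_from_amf(amf_values, detected=1000):
    """Build a count matrix whose AMF column reproduces given fractions."""
    amf_values = np.asarray(amf_values, dtype=float)
    det = np.full(amf_values.shape, detected)
    meth = np.round(amf_values * det).astype(int)
    ids = [f"s{i}" for i in range(len(amf_values))]
    cols = [f"r{j}" for j in range(amf_values.shape[1])] if amf_values.ndim == 2 else ["r0"]
    if amf_values.ndim == 1:
        meth = meth[:, None]
        det = det[:, None]
    return MethylationMatrix(
        pd.DataFrame(meth, index=ids, columns=cols),
        pd.DataFrame(det, index=ids, columns=cols),
    )
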