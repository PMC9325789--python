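import numpy as np
import pandas as pd
import pytest

from mmdep import ScreenMatrix


@pytest.fixture
def small_screen_pair():
    """Complete 200-gene x 10-line CRISPR/shRNA pair with correlated scores."""
    rng = np.random.default_rng(42)
    genes = [f"g{i:03d}" for i in range(200)]
    lines = [f"l{i}" for i in range(10)]
    latent = rng.normal(-0.3, 0.6, (200, 10))
    crispr = pd.DataFrame(latent + rng.normal(0, 0.2, latent.shape), index=genes, columns=lines)
    shrna = pd.DataFrame(latent + rng.normal(0, 0.2, latent.shape), index=genes, columns=lines)
    return ScreenMatrix(crispr, "crispr"), ScreenMatrix(shrna, "shrna")


@pytest.fixture
def clinical_frame():
    """Minimal valid clinical table for 12 patients."""
    rng = np.random.default_rng(0)
    idx = pd.Index([f"P{i}" for i in range(12)], name="patient_id")
    return pd.DataFrame(
        {
            "os_time": rng.uniform(1, 60, 12),
            "os_event": rng.integers(0, 2, 12),
            "pfs_time": rng.uniform(1, 40, 12),
            "pfs_event": rng.integers(0, 2, 12),
            "age": rng.normal(65, 8, 12),
            "sex": rng.integers(0, 2, 12),
            "iss": rng.integers(1, 4, 12).astype(float),
        },
        index=idx,
    )
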