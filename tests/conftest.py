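import numpy as np
import pandas as pd
import pytest

from irindices import simulate


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 1,500-participant synthetic cohort shared across read-only tests."""
    return simulate.generate(simulate.default_config(n=1500, seed=42))


@pytest.fixture(scope="session")
def complete_panels() -> pd.DataFrame:
    """1,000 random valid biochemistry panels (no missingness)."""
    rng = np.random.default_rng(7)
    n = 1000
    return pd.DataFrame(
        {
            "glucose_mmol_l": np.exp(rng.normal(np.log(5.2), 0.15, n)),
            # clipped inside the HOMA2 validity domain so all 7 indices define
            "insulin_pmol_l": np.exp(rng.normal(np.log(70.0), 0.45, n)).clip(25, 380),
            "c_peptide_nmol_l": np.exp(rng.normal(np.log(0.7), 0.35, n)).clip(0.25, 3.3),
            "tg_mmol_l": np.exp(rng.normal(np.log(1.1), 0.4, n)),
            "hdl_mmol_l": np.exp(rng.normal(np.log(1.35), 0.2, n)),
        }
    )
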