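import warnings

import numpy as np
import pandas as pd
import pytest

from methaccord import synthdata

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_sheet() -> pd.DataFrame:
    """The default 238-sample synthetic study, fixed seed."""
    return synthdata.generate_samples(synthdata.default_config(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_sheet(subsets: dict, seed: int = 0, sigma: float = 0.0,
               slope: float = 1.0) -> pd.DataFrame:
    """Small synthetic sample sheet; subsets maps name -> (n, intercept).

    LUMA values are uniform on [40, 80]; LINE-1 = intercept + slope * LUMA
    + N(0, sigma).
    """
    r = np.random.default_rng(seed)
    rows = []
    for name, (n, intercept) in subsets.items():
        x = r.uniform(40, 80, size=n)
        y = intercept + slope * x + r.normal(0, sigma, size=n)
        for i in range(n):
            rows.append({
                "sample_id": f"{name}_{i}", "subset": name, "treatment": "Untreated",
                "line1_pct": y[i], "luma_pct": x[i],
                "qc_excluded": False, "qc_reason": "",
            })
    return pd.DataFrame(rows)
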