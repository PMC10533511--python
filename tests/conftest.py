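import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_chart_csv(tmp_path):
    """Minimal monotone 3-row chart: (175, 40.0), (182, 43.0), (189, 46.0)."""
    path = tmp_path / "chart.csv"
    pd.DataFrame({"ga_days": [175, 182, 189],
                  "median_mm": [40.0, 43.0, 46.0]}).to_csv(path, index=False)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
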