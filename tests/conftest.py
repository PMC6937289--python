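import copy

import numpy as np
import pandas as pd
import pytest

from lodgekit.synthgen import TrialConfig, default_trial_config, gen_field_trial


@pytest.fixture(scope="session")
def trial_config() -> TrialConfig:
    return default_trial_config()


@pytest.fixture(scope="session")
def trial_records(trial_config) -> pd.DataFrame:
    return gen_field_trial(trial_config, seed=11)


@pytest.fixture(scope="session")
def small_trial_config(trial_config) -> TrialConfig:
    """One-variety, geometry-only config for fast Monte-Carlo loops."""
    groups = copy.deepcopy(trial_config.groups)
    keep = ("length_cm", "diameter_mm", "wall_mm")
    small = {
        "YJRZ": {
            tr: {
                "plant_height_cm": g["plant_height_cm"],
                "internodes": {
                    k: {t: v for t, v in tv.items() if t in keep}
                    for k, tv in g["internodes"].items()
                },
            }
            for tr, g in groups["YJRZ"].items()
        }
    }
    return TrialConfig(groups=small, culms_per_plot=5)


@pytest.fixture()
def array_replicate() -> pd.DataFrame:
    rng = np.random.default_rng(3)
    n = 200
    a = rng.uniform(6, 14, n)
    m = rng.normal(0, 0.2, n)
    return pd.DataFrame(
        {
            "probe_id": [f"P{i:04d}" for i in range(n)],
            "cy3": 2.0 ** (a - m / 2),
            "cy5": 2.0 ** (a + m / 2),
            "flag": "ok",
        }
    )
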