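import numpy as np
import pandas as pd
import pytest

from copstrat.synthetic import GeneratorConfig, generate_trial


@pytest.fixture(scope="session")
def default_trial():
    """Moderate-size synthetic trial with the default configuration."""
    cfg = GeneratorConfig(n_per_arm=4000, rho_true=0.8, seed=5)
    dataset, truth = generate_trial(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def null_trial():
    """Arms identical in biomarker and outcome laws (no treatment effect)."""
    cfg = GeneratorConfig(
        n_per_arm=4000, rho_true=0.8, seed=17,
        mean_w1=-0.6, slopes1={
            "egfr0": 0.04, "log_upcr": -0.25, "age": -0.015,
            "sbp": -0.008, "female": 0.3, "diabetes": -0.4,
        },
        resid_shape1=(-0.6, 2.2),
        coef_w=0.0, coef_arm1=0.0, coef_arm2=0.0,
    )
    dataset, truth = generate_trial(cfg)
    return dataset, truth


@pytest.fixture()
def toy_survival():
    """Five-subject dataset small enough for hand enumeration."""
    return pd.DataFrame({
        "time_years": [1.0, 2.0, 3.0, 4.0, 5.0],
        "event_type": [1, 0, 1, 1, 0],
        "x": [1.0, 0.0, 1.0, 0.0, 1.0],
    })
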