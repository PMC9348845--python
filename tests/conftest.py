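import numpy as np
import pandas as pd
import pytest

import betadose as bd


@pytest.fixture()
def seven_dose_design():
    """Log-equally spaced 7-dose design over Dm/30 .. 30*Dm, 3 replicates."""
    logd = np.repeat(np.linspace(np.log(1 / 30), np.log(30), 7), 3)
    return np.exp(logd)


@pytest.fixture()
def clean_beta_data(seven_dose_design):
    """Beta-law responses on the true curve beta0=0, beta1=1, phi=100."""
    d = seven_dose_design
    mu = 1.0 / (1.0 + np.exp(-np.log(d)))
    rng = np.random.default_rng(42)
    return d, rng.beta(mu * 100.0, (1.0 - mu) * 100.0)


@pytest.fixture()
def two_group_frame(seven_dose_design):
    """Two groups drawn from the same true curve (null configuration)."""
    d = seven_dose_design
    mu = 1.0 / (1.0 + np.exp(-np.log(d)))
    rng = np.random.default_rng(7)
    ya = rng.beta(mu * 100.0, (1.0 - mu) * 100.0)
    yb = rng.beta(mu * 100.0, (1.0 - mu) * 100.0)
    return pd.DataFrame({
        "dose": np.concatenate([d, d]),
        "response": np.concatenate([ya, yb]),
        "group": ["A"] * d.size + ["B"] * d.size,
    })


@pytest.fixture()
def fig_style_perturbed():
    """Noiseless on-curve 7-dose data with the lowest response pushed from
    0.005 to 1e-6 (a visually invisible change with gross logit-scale
    leverage)."""
    lo = bd.logit(0.005)
    logd = np.linspace(lo, -lo, 7)
    d = np.exp(logd)
    y = bd.inv_logit(logd)
    y_pert = y.copy()
    y_pert[0] = 1e-6
    return d, y, y_pert
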