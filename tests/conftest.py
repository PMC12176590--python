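import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from psmcea import ParametricSurvival, default_config, fit_mle

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    return default_config()


# Truth models used for parameter-recovery checks: moderate shapes, scales in
# the range of the trial data (cycles).
RECOVERY_TRUTHS = {
    "exponential": (0.1,),
    "weibull": (0.05, 1.32),
    "loglogistic": (9.06, 2.15),
    "lognormal": (1.80, 0.72),
    "gompertz": (0.15, 0.05),
    "gengamma": (2.0, 0.6, 1.0),
}


@pytest.fixture(scope="session")
def recovery_fits():
    """Fit each family to n=5000 uncensored draws from known truth (seed 0)."""
    out = {}
    rng = np.random.default_rng(0)
    for family, truth in RECOVERY_TRUTHS.items():
        model = ParametricSurvival(family, truth)
        t = model.ppf(rng.uniform(size=5000))
        t = np.clip(t, 1e-9, None)
        import pandas as pd

        ipd = pd.DataFrame({"time": t, "event": 1})
        out[family] = (np.asarray(truth), fit_mle(ipd, family))
    return out
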