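import numpy as np
import pandas as pd
import pytest

from mrdsurvey import SimulationConfig, simulate_survey
from mrdsurvey.simulate import DetectionTruth


@pytest.fixture(scope="session")
def default_survey():
    """One full synthetic survey realisation (half-normal truth)."""
    return simulate_survey(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def hazard_survey():
    cfg = SimulationConfig(
        seed=12,
        detection=DetectionTruth(form="hazard_rate", sigma_m=200.0, b=2.5,
                                 p0_mid=0.85, p0_rear=0.7),
    )
    return simulate_survey(cfg)


def halfnormal_sample(n, sigma, left, right, rng):
    """Distances whose boundary-shifted law is half-normal(sigma), by
    inverse-CDF on the truncated scale."""
    from scipy import special
    w = right - left
    cmax = special.erf(w / (np.sqrt(2) * sigma))
    u = rng.uniform(0, cmax, n)
    return left + np.sqrt(2) * sigma * special.erfinv(u)


def hazard_sample(n, sigma, b, left, right, rng):
    """Rejection sampling from the boundary-shifted hazard-rate key."""
    w = right - left
    out = np.empty(0)
    while len(out) < n:
        x = rng.uniform(0, w, 4 * n)
        g = -np.expm1(-(np.maximum(x, 1e-9) / sigma) ** (-b))
        x = x[rng.uniform(size=len(x)) < g]
        out = np.concatenate([out, x])
    return left + out[:n]


def make_sightings(x, sizes=None, transect="T0"):
    n = len(x)
    return pd.DataFrame({
        "perp_distance_m": x,
        "school_size": np.ones(n) if sizes is None else sizes,
        "detected_mid": True,
        "detected_rear": False,
        "transect_id": transect,
        "season": "summer_autumn",
        "beaufort": 2, "cloud_cover": 4, "turbidity": 1, "glare": 0,
    })
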