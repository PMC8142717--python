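import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_cell_design(
    n,
    seed=0,
    set_size=1,
    cue_condition="none",
    presentation="both",
    probed_is_cued=True,
    participant_id="P01",
    aware=False,
):
    """Minimal single-cell trial table for driving the observer simulator."""
    rng = np.random.default_rng(seed)
    pre = rng.uniform(0.0, 360.0, size=n)
    shift = np.where(np.arange(n) % 2 == 0, 1, -1)
    if cue_condition in ("valid", "invalid"):
        cued = "A" if probed_is_cued == (cue_condition == "valid") else "B"
    else:
        cued = ""
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "experiment": 1 if cue_condition == "none" else 2,
            "block": 1,
            "set_size": set_size,
            "cue_condition": cue_condition,
            "presentation": presentation,
            "cued_location": cued,
            "probed_location": "A",
            "location_class": "outer",
            "pre_color_deg": pre,
            "shift_dir": shift,
            "post_color_deg": (pre + shift * 25.0) % 360.0,
            "response_deg": np.nan,
            "saccade_latency_ms": 240.0,
            "aware": aware,
        }
    )


@pytest.fixture(scope="session")
def exp1_design():
    from transsaccade import generate_design

    return generate_design(1, 2, seed=11)


@pytest.fixture(scope="session")
def exp2_design():
    from transsaccade import generate_design

    return generate_design(2, 2, seed=11)


@pytest.fixture(scope="session")
def exp1_trials(exp1_design):
    from transsaccade import ObserverParams, simulate_responses

    return simulate_responses(exp1_design, ObserverParams(seed=11))
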