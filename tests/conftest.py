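import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def em_vl_table():
    """Published control-arm 2x2: electronic monitoring vs viral load.

    Orientation: measure A = EM (positive = poor adherence), measure B =
    viral load (positive = unsuppressed).
    """
    from adheremon import TwoByTwo

    return TwoByTwo(n11=19, n10=33, n01=64, n00=135)


@pytest.fixture(scope="session")
def sr_vl_table():
    """Published control-arm 2x2: self-report vs viral load."""
    from adheremon import TwoByTwo

    return TwoByTwo(n11=2, n10=7, n01=111, n00=208)


@pytest.fixture(scope="session")
def small_trial():
    """A small fully simulated trial (truth, events, self-report, viral load)."""
    from adheremon import SimConfig, simulate_trial

    cfg = SimConfig(n_clinics=6, participants_per_clinic=6, months=3,
                    malfunction_rate=0.0, seed=11)
    truth, events, sr, vl = simulate_trial(cfg)
    return cfg, truth, events, sr, vl


def make_events_csv(rows):
    """CSV text for a device event log from (pid, iso_ts, signal) tuples."""
    lines = ["participant_id,timestamp,signal"]
    lines += [f"{p},{t},{s}" for p, t, s in rows]
    return "\n".join(lines) + "\n"


@pytest.fixture()
def events_csv_factory():
    return make_events_csv
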