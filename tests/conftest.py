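from datetime import date, timedelta

import pytest
from hypothesis import HealthCheck, settings

from bycatchrisk.tracks import Track, TrackPoint, assign_relative_days

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_track(
    turtle_id: str,
    population: str = "EP",
    start: date = date(2000, 1, 1),
    day_offsets=range(10),
    lat: float = -12.0,
    lon: float = 255.0,
    step: float = 0.0,
) -> Track:
    """Stationary or linearly drifting daily track on given day offsets."""
    pts = [
        TrackPoint(start + timedelta(days=int(k)), lat + step * i, lon)
        for i, k in enumerate(day_offsets)
    ]
    return assign_relative_days(Track(turtle_id, population, pts))


@pytest.fixture(scope="session")
def planted_scenario_data():
    from bycatchrisk import make_scenario

    return make_scenario("planted_hotspot", 7).generate()
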