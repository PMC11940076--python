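import numpy as np
import pytest

from tdbscan import GeoPoint, TrackPoint


def make_track(hours, lats, lons, t0=0.0, ids=None):
    """Build TrackPoints from parallel hour/lat/lon sequences."""
    hours = list(hours)
    if np.isscalar(lats):
        lats = [lats] * len(hours)
    if np.isscalar(lons):
        lons = [lons] * len(hours)
    if ids is None:
        ids = range(len(hours))
    return [
        TrackPoint(id=i, pos=GeoPoint(float(la), float(lo)), t=t0 + h * 3600.0)
        for i, h, la, lo in zip(ids, hours, lats, lons)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
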