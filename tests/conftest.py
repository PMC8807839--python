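import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def minutes_from_pattern(pattern: str, fly_id: str = "f0") -> pd.DataFrame:
    """Build a minute-state frame from a pattern string.

    'A' = active, 'I' = inactive, 'X' = invalid minute.  Active minutes
    get dist_mm 6.0, inactive 0.0.
    """
    recs = []
    for i, ch in enumerate(pattern.replace(" ", "")):
        recs.append(
            {
                "fly_id": fly_id,
                "minute_start": 60.0 * i,
                "dist_mm": 6.0 if ch == "A" else 0.0,
                "active": ch == "A",
                "valid": ch != "X",
            }
        )
    return pd.DataFrame(recs)


def frames_from_minute_dists(dists, fly_id="f0", sample_rate=5.0, t0=0.0):
    """Frame-level trace whose per-minute displacement sums equal `dists`."""
    fpm = int(sample_rate * 60)
    rows = []
    for m, total in enumerate(dists):
        t = t0 + 60.0 * m + np.arange(fpm) / sample_rate
        d = np.zeros(fpm)
        d[0] = total  # whole displacement on one frame: sums stay exact
        rows.append(pd.DataFrame({"fly_id": fly_id, "t_s": t, "d_mm": d}))
    return pd.concat(rows, ignore_index=True)
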