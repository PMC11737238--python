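"""Minimal NOAA-style solar position: elevation of the sun centre.

Good to a fraction of a degree, which is ample for a day/night flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def solar_elevation(ts, lat: float, lon: float) -> np.ndarray:
    """Solar elevation angle (degrees) at UTC times ``ts`` for one site.

    Uses the fractional-year approximation of declination and the equation
    of time; ``lon`` is degrees east, ``lat`` degrees north.
    """
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(ts, dtype="datetime64[ns]")))
    doy = ts.dayofyear.to_numpy()
    hours = (
        ts.hour.to_numpy()
        + ts.minute.to_numpy() / 60.0
        + ts.second.to_numpy() / 3600.0
    )
    gamma = 2.0 * np.pi / 365.0 * (doy - 1 + (hours - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma) - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma) - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma)
    )
    time_offset = eqtime + 4.0 * lon            # minutes
    tst = hours * 60.0 + time_offset            # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)          # hour angle
    lat_r = np.deg2rad(lat)
    cos_zen = (
        np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    )
    return 90.0 - np.rad2deg(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
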