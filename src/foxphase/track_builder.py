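"""Fix cleaning, burst construction and step-level movement parameters.

Raw fixes are cleaned (speed-based spatial outlier removal, capture-window
exclusion), partitioned into bursts whose successive time gaps lie within a
configurable window (10-60 min by default), and converted to steps carrying
step length (sl), speed, signed turning angle (ta) and persistence velocity
(pv = speed * cos(ta)).  Coordinates are projected meters, y north-positive;
headings are measured counter-clockwise from east, so mirroring a trajectory
(y -> -y) flips the sign of ta and leaves pv unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FIX_COLUMNS = ("individual_id", "t", "x", "y")


def _check_sorted(fixes: pd.DataFrame) -> None:
    for _, g in fixes.groupby("individual_id", sort=False):
        dt = g["t"].diff().dropna()
        if (dt <= pd.Timedelta(0)).any():
            raise ValueError("timestamps must be strictly increasing per individual")


def _per_individual(fixes, func, *args, **kwargs) -> pd.DataFrame:
    parts = [
        func(g.reset_index(drop=True), *args, **kwargs)
        for _, g in fixes.groupby("individual_id", sort=False)
    ]
    return pd.concat(parts, ignore_index=True) if parts else fixes.iloc[0:0]


def remove_spatial_outliers(fixes: pd.DataFrame, max_speed: float = 8.0) -> pd.DataFrame:
    """Iteratively drop fixes implying speed > ``max_speed`` to both neighbors.

    An interior fix is an outlier when the implied speed to both its temporal
    neighbors exceeds ``max_speed`` (m/s); an end fix when the speed to its
    single neighbor does.  Removal repeats until stable, so the filter is
    idempotent on clean data.  This speed-based double-neighbor test is the
    package's documented spatial outlier filter.
    """
    _check_sorted(fixes)

    def _one(g: pd.DataFrame) -> pd.DataFrame:
        while len(g) >= 2:
            t = g["t"].to_numpy()
            x = g["x"].to_numpy()
            y = g["y"].to_numpy()
            dt = np.diff(t).astype("timedelta64[s]").astype(float)
            v = np.hypot(np.diff(x), np.diff(y)) / dt
            fast_prev = np.concatenate([[True], v > max_speed])   # gap i-1 -> i
            fast_next = np.concatenate([v > max_speed, [True]])   # gap i -> i+1
            bad = fast_prev & fast_next
            if not bad.any():
                break
            # drop the single worst offender per pass to avoid cascades
            worst = np.argmax(
                np.where(bad, np.maximum(
                    np.concatenate([[0.0], v]), np.concatenate([v, [0.0]])
                ), -np.inf)
            )
            g = g.drop(g.index[worst]).reset_index(drop=True)
        return g

    return _per_individual(fixes, _one)


def drop_capture_window(
    fixes: pd.DataFrame,
    capture_time: pd.Timestamp | dict[str, pd.Timestamp] | None = None,
    window_hours: float = 24.0,
) -> pd.DataFrame:
    """Remove fixes within ``window_hours`` after capture (trapping bias).

    ``capture_time`` may be a single timestamp, a mapping individual -> time,
    or None (default: each individual's first fix).
    """

    def _cutoff(ind: str, g: pd.DataFrame) -> pd.Timestamp:
        if capture_time is None:
            t0 = g["t"].iloc[0]
        elif isinstance(capture_time, dict):
            t0 = capture_time[ind]
        else:
            t0 = capture_time
        return t0 + pd.Timedelta(hours=window_hours)

    parts = []
    for ind, g in fixes.groupby("individual_id", sort=False):
        parts.append(g[g["t"] >= _cutoff(ind, g)])
    return pd.concat(parts, ignore_index=True) if parts else fixes.iloc[0:0]


def build_tracks(
    fixes: pd.DataFrame, dt_min: float = 10.0, dt_max: float = 60.0
) -> pd.DataFrame:
    """Partition fixes into bursts whose successive gaps lie in [dt_min, dt_max].

    Rules, applied in one sequential pass per individual: a gap above
    ``dt_max`` minutes closes the current burst and the next fix starts a new
    one; a fix isolated from both neighbors by more than ``dt_max`` ends up in
    a single-fix burst and is discarded; a gap below ``dt_min`` drops the
    later fix, with the gap re-measured from the last retained fix, so every
    emitted pair satisfies ``dt_min <= dt <= dt_max``.  Returns the retained
    fixes with a ``burst_id`` column (unique across individuals).
    """
    if dt_max < dt_min:
        raise ValueError("dt_max must be >= dt_min")
    _check_sorted(fixes)
    if fixes.empty:
        out = fixes.copy()
        out["burst_id"] = pd.Series(dtype=int)
        return out

    counter = {"next": 0}

    def _one(g: pd.DataFrame) -> pd.DataFrame:
        t = g["t"].to_numpy()
        bursts: list[list[int]] = [[0]]
        for i in range(1, len(g)):
            last = bursts[-1][-1]
            gap = (t[i] - t[last]) / np.timedelta64(60, "s")
            if gap < dt_min:
                continue                      # merge: drop later fix
            if gap <= dt_max:
                bursts[-1].append(i)
            else:
                bursts.append([i])
        keep_idx, ids = [], []
        for b in bursts:
            if len(b) < 2:
                continue                      # isolated fixes are discarded
            keep_idx.extend(b)
            ids.extend([counter["next"]] * len(b))
            counter["next"] += 1
        out = g.iloc[keep_idx].copy()
        out["burst_id"] = ids
        return out

    return _per_individual(fixes, _one)


def step_metrics(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-step movement parameters within each burst.

    One row per fix pair: ``sl`` (m), ``dt`` (min), ``speed`` (m/s, sl over
    dt), ``ta`` (radians in [-pi, pi], heading change versus the previous
    step) and ``pv = speed * cos(ta)``.  The first step of a burst has no
    previous heading, and any step adjacent to a zero-length step has an
    undefined heading change; both carry NaN ta/pv and are excluded from
    feature tables upstream.
    """
    parts = []
    for (ind, burst), g in tracks.groupby(["individual_id", "burst_id"], sort=False):
        if len(g) < 2:
            continue
        t = g["t"].to_numpy()
        x = g["x"].to_numpy()
        y = g["y"].to_numpy()
        dx, dy = np.diff(x), np.diff(y)
        sl = np.hypot(dx, dy)
        dt_s = np.diff(t).astype("timedelta64[s]").astype(float)
        speed = sl / dt_s
        heading = np.where(sl > 0, np.arctan2(dy, dx), np.nan)
        ta = np.full(len(sl), np.nan)
        ta[1:] = heading[1:] - heading[:-1]
        ta = np.pi - np.mod(np.pi - ta, 2 * np.pi)  # wrap to (-pi, pi]; NaN stays
        pv = speed * np.cos(ta)
        parts.append(pd.DataFrame({
            "individual_id": ind,
            "burst_id": burst,
            "t_start": t[:-1],
            "t_end": t[1:],
            "dt": dt_s / 60.0,
            "x_start": x[:-1],
            "y_start": y[:-1],
            "x_end": x[1:],
            "y_end": y[1:],
            "sl": sl,
            "speed": speed,
            "ta": ta,
            "pv": pv,
        }))
    if not parts:
        return pd.DataFrame(columns=[
            "individual_id", "burst_id", "t_start", "t_end", "dt",
            "x_start", "y_start", "x_end", "y_end", "sl", "speed", "ta", "pv",
        ])
    return pd.concat(parts, ignore_index=True)


def nsd(
    fixes: pd.DataFrame, origin: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Net squared displacement from an origin (default: the first fix).

    Returns a frame aligned with ``fixes`` holding ``nsd`` (m^2) and its
    square root ``displacement`` (m).
    """
    if origin is None:
        origin = (float(fixes["x"].iloc[0]), float(fixes["y"].iloc[0]))
    d2 = (fixes["x"] - origin[0]) ** 2 + (fixes["y"] - origin[1]) ** 2
    return pd.DataFrame(
        {"nsd": d2.to_numpy(), "displacement": np.sqrt(d2.to_numpy())},
        index=fixes.index,
    )
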