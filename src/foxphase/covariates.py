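"""Habitat and time covariates at step end points; the 11-predictor table.

Each eligible movement step (defined turning angle and persistence velocity)
yields one feature row: the three movement parameters (sl, ta, pv), the land
class and four distance covariates sampled at the step's end point, the
combined linear-anthropogenic distance (minimum over state roads, federal
highways and railways), and the two time covariates (meteorological season
and a solar day/night flag).  The target is the phase of the step's end fix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._solar import solar_elevation
from .landscape import LINEAR_ANTHROPOGENIC, LandscapeStack, RasterSampleError
from .phase_segmentation import PhaseSegmentation

log = logging.getLogger(__name__)

#: The 11 predictors, counting each categorical once.
PREDICTORS = (
    "sl", "ta", "pv",
    "landclass",
    "dist_flowing_waters", "dist_protected_areas",
    "dist_district_road", "dist_agricultural_road",
    "dist_linear_anthropogenic",
    "season", "time_of_day",
)
NUMERIC_PREDICTORS = tuple(
    p for p in PREDICTORS if p not in ("landclass", "season", "time_of_day")
)
CATEGORICAL_LEVELS = {
    "landclass": (1, 2, 3, 4, 5, 6, 7),
    "season": ("winter", "spring", "summer", "autumn"),
    "time_of_day": ("night", "day"),
}
#: Integer serialization of categorical levels (sidecar legend).
CATEGORY_CODES = {
    "season": {"winter": 1, "spring": 2, "summer": 3, "autumn": 4},
    "time_of_day": {"night": 1, "day": 2},
}

#: Study-area reference coordinates (rural southern Germany) for the solar clock.
DEFAULT_LATLON = (47.855, 9.536)

_SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def sample_raster(stack: LandscapeStack, layer: str, x, y):
    """Value of the raster cell containing each point (nearest cell)."""
    return stack.sample(layer, x, y)


def linear_anthropogenic_distance(stack: LandscapeStack, x, y):
    """Minimum distance to state roads, federal highways or railways (m)."""
    missing = [n for n in LINEAR_ANTHROPOGENIC if n not in stack.distance_layers]
    if missing:
        raise KeyError(f"missing distance layers: {missing}")
    samples = [stack.sample(n, x, y) for n in LINEAR_ANTHROPOGENIC]
    return np.minimum.reduce(samples)


def season_of(ts) -> str | pd.Series:
    """Meteorological season by month: Dec-Feb winter, Mar-May spring,
    Jun-Aug summer, Sep-Nov autumn."""
    if isinstance(ts, (pd.Series, pd.DatetimeIndex, np.ndarray, list)):
        months = pd.DatetimeIndex(ts).month
        return pd.Series([_SEASON_BY_MONTH[m] for m in months])
    return _SEASON_BY_MONTH[pd.Timestamp(ts).month]


def time_of_day(
    ts,
    latlon: tuple[float, float] | None = DEFAULT_LATLON,
    fixed_window: tuple[float, float] | None = None,
):
    """Day/night flag: day iff the sun centre is above the horizon.

    The solar test needs a site latitude/longitude (``latlon``); a fixed
    clock window ``(start_hour, end_hour)`` may be supplied instead, flagging
    day iff ``start <= hour-of-day < end``.
    """
    scalar = np.ndim(ts) == 0 and not isinstance(ts, (pd.Series, pd.DatetimeIndex))
    tss = pd.DatetimeIndex(np.atleast_1d(np.asarray(ts, dtype="datetime64[ns]")))
    if fixed_window is not None:
        start, end = fixed_window
        h = tss.hour + tss.minute / 60.0 + tss.second / 3600.0
        day = (h >= start) & (h < end)
    elif latlon is not None:
        day = solar_elevation(tss, *latlon) > 0.0
    else:
        raise ValueError("need either latlon or fixed_window")
    out = np.where(day, "day", "night")
    return out.item() if scalar else pd.Series(out)


@dataclass
class CollinearityReport:
    """Pairwise Spearman correlations of the numeric predictors."""

    rho: pd.DataFrame
    threshold: float
    flagged: list[tuple[str, str, float]]
    undefined: list[str]

    @property
    def all_below_threshold(self) -> bool:
        return not self.flagged


def screen_collinearity(
    rows: pd.DataFrame, threshold: float = 0.4
) -> CollinearityReport:
    """Spearman correlation screen over the numeric predictors.

    Pairs with ``|rho| >= threshold`` are flagged; nothing is excluded
    automatically (screening only).  Constant columns make rho undefined and
    are reported as such.
    """
    cols = [c for c in NUMERIC_PREDICTORS if c in rows.columns]
    if len(rows) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    data = rows[cols].to_numpy(float)
    undefined = [c for i, c in enumerate(cols) if np.all(data[:, i] == data[0, i])]
    rho, _ = spearmanr(data)
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    mat = pd.DataFrame(rho, index=cols, columns=cols)
    for c in undefined:
        mat.loc[c, :] = np.nan
        mat.loc[:, c] = np.nan
        mat.loc[c, c] = 1.0
    flagged = [
        (cols[i], cols[j], float(mat.iloc[i, j]))
        for i in range(len(cols)) for j in range(i + 1, len(cols))
        if np.isfinite(mat.iloc[i, j]) and abs(mat.iloc[i, j]) >= threshold
    ]
    return CollinearityReport(mat, threshold, flagged, undefined)


def build_feature_table(
    steps: pd.DataFrame,
    segmentations: dict[str, PhaseSegmentation],
    stack: LandscapeStack,
    latlon: tuple[float, float] | None = DEFAULT_LATLON,
    fixed_window: tuple[float, float] | None = None,
    anchor: str = "end",
) -> pd.DataFrame:
    """Assemble the feature table: one row per eligible step.

    Covariates are sampled at the step's end point (``anchor="start"`` is
    available for sensitivity checks).  Rows with undefined ta/pv, with an
    end fix outside the raster extent, or without a phase label are dropped
    and counted in the log.
    """
    if anchor not in ("end", "start"):
        raise ValueError("anchor must be 'end' or 'start'")
    n_in = len(steps)
    rows = steps.dropna(subset=["ta", "pv"]).copy()
    n_na = n_in - len(rows)

    # phase of the step's end fix, joined on (individual, end time)
    labels = pd.concat(
        [seg.to_frame(ind)[["individual_id", "t", "phase"]]
         for ind, seg in segmentations.items()],
        ignore_index=True,
    )
    rows = rows.merge(
        labels.rename(columns={"t": "t_end"}),
        on=["individual_id", "t_end"], how="left",
    )
    n_nophase = int(rows["phase"].isna().sum())
    rows = rows.dropna(subset=["phase"])

    if anchor == "end":
        px, py = rows["x_end"].to_numpy(), rows["y_end"].to_numpy()
    else:
        px, py = rows["x_start"].to_numpy(), rows["y_start"].to_numpy()

    ok = stack.inside(px, py) & stack.inside(px, py, layer="flowing_waters")
    n_outside = int((~ok).sum())
    rows = rows[ok]
    px, py = px[ok], py[ok]

    out = pd.DataFrame({
        "individual_id": rows["individual_id"].to_numpy(),
        "phase": rows["phase"].to_numpy(),
        "sl": rows["sl"].to_numpy(),
        "ta": rows["ta"].to_numpy(),
        "pv": rows["pv"].to_numpy(),
        "landclass": stack.sample("landclass", px, py).astype(int),
        "dist_flowing_waters": stack.sample("flowing_waters", px, py),
        "dist_protected_areas": stack.sample("protected_areas", px, py),
        "dist_district_road": stack.sample("district_road", px, py),
        "dist_agricultural_road": stack.sample("agricultural_road", px, py),
        "dist_linear_anthropogenic": linear_anthropogenic_distance(stack, px, py),
        "season": season_of(rows["t_end"]).to_numpy(),
        "time_of_day": time_of_day(
            rows["t_end"], latlon=latlon, fixed_window=fixed_window
        ).to_numpy(),
    })
    log.info(
        "feature table: %d steps -> %d rows (%d undefined ta/pv, "
        "%d unlabelled, %d outside raster)",
        n_in, len(out), n_na, n_nophase, n_outside,
    )
    return out.reset_index(drop=True)


def feature_table_to_csv(rows: pd.DataFrame, path) -> pd.DataFrame:
    """Write the table with integer-coded categoricals plus a legend sidecar."""
    out = rows.copy()
    for col, codes in CATEGORY_CODES.items():
        out[col] = out[col].map(codes)
    out.to_csv(path, index=False)
    legend = pd.DataFrame(
        [(col, lvl, code) for col, codes in CATEGORY_CODES.items()
         for lvl, code in codes.items()],
        columns=["variable", "level", "code"],
    )
    legend.to_csv(str(path) + ".legend.csv", index=False)
    return out
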