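"""Synthetic red-fox telemetry with known ground-truth movement phases.

The generator emulates the data situation of a rural GPS-collaring study of
dispersing subadult red foxes: each simulated individual occupies a first home
range (mean-reverting movement around a centre), performs tortuous out-and-back
excursions beyond its range envelope, then disperses along a directed,
persistent transient path to a second home range, with collar fix intervals
that switch between ~10 min when active (night) and ~1 h when inactive (day),
occasional dropped fixes, and autumn-onward timestamps.  Every fix carries a
ground-truth phase label (stationary / transient / exploratory) so that all
downstream stages can be validated without field data.

The landscape generator produces a patchy 7-class land-cover grid whose class
proportions approximate configurable targets (defaults: 41.5 % tree cover,
25.6 % greenland, 25.5 % agricultural fields, 5.4 % settlement, the remaining
2 % split over sparse vegetation, water and wetland) and random polyline
features per linear class, with exact Euclidean-distance transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .landscape import DISTANCE_LAYERS, LandscapeStack

TWO_PI = 2.0 * math.pi

#: Target land-class area shares, codes 1..7.
DEFAULT_CLASS_PROPORTIONS = {
    1: 0.415,   # tree cover
    2: 0.256,   # greenland
    3: 0.255,   # agricultural fields
    4: 0.054,   # settlement
    5: 0.008,   # sparse vegetation
    6: 0.006,   # water
    7: 0.006,   # wetland
}

#: Rayleigh 98.5% factor: an isotropic Gaussian range with per-axis sd s keeps
#: 98.5% of its displacement mass within RANGE_EDGE_FACTOR * s of the centre.
RANGE_EDGE_FACTOR = math.sqrt(-2.0 * math.log(0.015))  # ~2.894


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated study population.

    The same seed always yields bit-identical output.  Defaults describe a
    strongly phase-separated dispersal: home-range centres ~16-20 km apart,
    night-active movement (10-min fixes at night, hourly by day), a
    multi-night directed transient leg travelled at ~0.35 m/s with high
    heading persistence, and tortuous single-night excursions reaching
    ~8 x the home-range spread.
    """

    n_individuals: int = 12
    center1: tuple[float, float] = (5_000.0, 10_000.0)
    center2: tuple[float, float] = (25_000.0, 10_000.0)
    stationary_sd: float = 300.0          # m, per-axis home-range spread
    excursion_amplitude: float = 2_500.0  # m, minimum excursion reach
    excursion_rate: float = 0.025          # expected excursions per day
    transient_speed_mean: float = 0.35    # m/s while travelling at night
    transient_persistence: float = 30.0   # von Mises heading concentration
    active_interval: float = 10.0         # min between fixes when active
    inactive_interval: float = 60.0       # min between fixes when inactive
    gap_prob: float = 0.05                # probability a fix is dropped
    start_date: str = "2021-09-01"
    duration_days: int = 120
    disperser_type: str = "full"          # full | caught_in_transit | truncated
    seed: int = 0
    # secondary movement parameters (free parameters of the generator)
    exploratory_speed_mean: float = 0.32  # m/s during excursions
    excursion_kappa: float = 1.5          # heading concentration in excursions
    ou_tau_hours: float = 6.0             # home-range relaxation time
    transient_speed_shape: float = 16.0    # gamma shape of travel speeds
    s1_fraction: tuple[float, float] = (0.30, 0.45)  # S1 share of the record
    night_hours: tuple[float, float] = (18.0, 6.0)   # active window (local)
    rest_jitter: float = 15.0             # m, positional noise while resting

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.disperser_type not in ("full", "caught_in_transit", "truncated"):
            raise ValueError(f"unknown disperser_type {self.disperser_type!r}")
        if self.excursion_amplitude <= self.stationary_sd:
            raise ValueError(
                "excursion_amplitude must exceed stationary_sd for a "
                "separable scenario"
            )
        if self.duration_days < 20:
            raise ValueError(
                "duration_days too short to hold S1, transient and S2 phases "
                "(need >= 20 days)"
            )


@dataclass
class LabeledFixSeries:
    """One individual's fixes plus ground truth, for validation only.

    ``fixes`` has columns ``individual_id, t, x, y``; ``true_phase`` is the
    per-fix label; ``true_transient`` bounds the true transient interval
    (None-valued ends for series that start or end mid-transit).
    Downstream modules never see the truth except in tests.
    """

    fixes: pd.DataFrame
    true_phase: pd.Series
    trap_location: tuple[float, float]
    trap_time: pd.Timestamp
    true_transient: tuple[pd.Timestamp | None, pd.Timestamp | None]

    def __post_init__(self) -> None:
        t = self.fixes["t"]
        if not t.is_monotonic_increasing or t.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _random_polyline(rng, width, height, n_knots=6, wiggle=0.15):
    """A polyline crossing the extent between two random opposite edges."""
    horizontal = rng.random() < 0.5
    ts = np.linspace(0.0, 1.0, n_knots)
    offs = rng.uniform(0.2, 0.8) + rng.normal(0.0, wiggle, n_knots).cumsum() * 0.3
    if horizontal:
        xs = ts * width
        ys = np.clip(offs, 0.02, 0.98) * height
    else:
        ys = ts * height
        xs = np.clip(offs, 0.02, 0.98) * width
    return np.column_stack([xs, ys])


def _rasterize_polyline(mask, pts, origin_x, origin_y, cell):
    """Mark all cells touched by densely sampled points along the polyline."""
    nrows, ncols = mask.shape
    top = origin_y + nrows * cell
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        seg = math.hypot(x1 - x0, y1 - y0)
        n = max(2, int(seg / (cell * 0.5)) + 1)
        xs = np.linspace(x0, x1, n)
        ys = np.linspace(y0, y1, n)
        col = np.floor((xs - origin_x) / cell).astype(int)
        row = np.ceil((top - ys) / cell).astype(int) - 1
        ok = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
        mask[row[ok], col[ok]] = True


_N_LINES = {
    "flowing_waters": 3,
    "district_road": 4,
    "agricultural_road": 8,
    "state_road": 2,
    "federal_highway": 1,
    "railway": 1,
}


def simulate_landscape(
    extent: tuple[float, float],
    seed: int,
    cell_size: float = 10.0,
    distance_cell: float | None = None,
    class_proportions: dict[int, float] | None = None,
    n_patches: int = 800,
    corridor: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> LandscapeStack:
    """Generate a patchy landscape with linear features and distance layers.

    Land classes are laid out as Voronoi patches of ``n_patches`` seed points
    whose class counts follow ``class_proportions`` (largest-remainder
    apportionment), which makes realized area shares concentrate tightly
    around the targets.  Linear features are random polylines crossing the
    extent; ``corridor``, if given, adds one state road along the stated
    segment (e.g. between two home-range centres).  Distance layers are exact
    Euclidean distance transforms of the rasterized features, so a cell
    intersecting its feature has distance 0.

    Raises
    ------
    ValueError
        For a zero-area extent.
    """
    width, height = float(extent[0]), float(extent[1])
    if width <= 0 or height <= 0:
        raise ValueError(f"extent must be positive, got {extent}")
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    total = sum(props.values())
    props = {k: v / total for k, v in props.items()}

    rng = np.random.default_rng(seed)
    ncols = int(math.ceil(width / cell_size))
    nrows = int(math.ceil(height / cell_size))

    # class seed counts by largest remainder
    quotas = {k: props[k] * n_patches for k in sorted(props)}
    counts = {k: int(q) for k, q in quotas.items()}
    short = n_patches - sum(counts.values())
    for k in sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    seed_classes = np.repeat(
        list(counts.keys()), list(counts.values())
    ).astype(np.int8)
    rng.shuffle(seed_classes)
    seed_xy = rng.uniform([0, 0], [width, height], size=(n_patches, 2))

    xs = (np.arange(ncols) + 0.5) * cell_size
    ys = height - (np.arange(nrows) + 0.5) * cell_size  # row 0 = north
    gx, gy = np.meshgrid(xs, ys)
    _, nearest = cKDTree(seed_xy).query(
        np.column_stack([gx.ravel(), gy.ravel()]), k=1
    )
    landclass = seed_classes[nearest].reshape(nrows, ncols)

    dcell = cell_size if distance_cell is None else distance_cell
    dncols = int(math.ceil(width / dcell))
    dnrows = int(math.ceil(height / dcell))
    layers: dict[str, np.ndarray] = {}
    for name in DISTANCE_LAYERS:
        mask = np.zeros((dnrows, dncols), dtype=bool)
        if name == "protected_areas":
            xs_c = (np.arange(dncols) + 0.5) * dcell
            ys_c = height - (np.arange(dnrows) + 0.5) * dcell
            for _ in range(3):
                cx, cy = rng.uniform([0, 0], [width, height])
                r = rng.uniform(800.0, 2_000.0)
                mask |= (
                    (ys_c - cy)[:, None] ** 2 + (xs_c - cx)[None, :] ** 2
                    <= r * r
                )
        else:
            for _ in range(_N_LINES[name]):
                pts = _random_polyline(rng, width, height)
                _rasterize_polyline(mask, pts, 0.0, 0.0, dcell)
            if name == "state_road" and corridor is not None:
                _rasterize_polyline(
                    mask, np.asarray(corridor, dtype=float), 0.0, 0.0, dcell
                )
        if not mask.any():  # degenerate; keep the layer well defined
            mask[dnrows // 2, dncols // 2] = True
        layers[name] = distance_transform_edt(
            ~mask, sampling=dcell
        ).astype(np.float32)

    return LandscapeStack(
        landclass=landclass,
        distance_layers=layers,
        origin_x=0.0,
        origin_y=0.0,
        landclass_cell=cell_size,
        distance_cell=dcell,
        meta={"seed": seed, "extent": (width, height)},
    )


# ---------------------------------------------------------------------------
# individual trajectories
# ---------------------------------------------------------------------------

def _is_night(ts: pd.Timestamp, night: tuple[float, float]) -> bool:
    h = ts.hour + ts.minute / 60.0
    start, end = night
    if start > end:
        return h >= start or h < end
    return start <= h < end


def _vm(rng, kappa: float) -> float:
    """von Mises heading noise; kappa = inf means no noise."""
    if math.isinf(kappa):
        return 0.0
    return float(rng.vonmises(0.0, kappa))


def simulate_individual(
    scenario: SimScenario, landscape: LandscapeStack | None = None
) -> LabeledFixSeries:
    """Simulate one collared fox with ground-truth phase labels.

    The trajectory is built fix by fix: a mean-reverting (OU-like) walk around
    ``center1`` (S1), Poisson-scheduled out-and-back excursions with high
    turning-angle variance reaching at least ``excursion_amplitude``, a
    von Mises-persistent night-travelling transient leg toward ``center2``
    (resting with small jitter by day), then S2 around ``center2`` with
    further excursions.  A fix inside an excursion counts as truly
    exploratory once it is beyond the theoretical 98.5 % displacement radius
    (~2.89 x ``stationary_sd``) of its range centre; the out/back portions
    inside the range core remain stationary, mirroring the envelope
    definition used downstream.

    A ``caught_in_transit`` series starts mid-route: the fox is captured part
    way between the two centres, holds near the release site for ~1.5 days
    (post-capture recovery, eaten by the downstream 24 h trapping-bias
    exclusion), then resumes the transient leg and settles; its transient
    interval is open at the start.  A ``truncated`` series is the full
    trajectory cut at a random time inside the transient leg, so the record
    ends mid-transit and the interval is open at the end.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    c1 = np.asarray(scenario.center1, dtype=float)
    c2 = np.asarray(scenario.center2, dtype=float)
    sd = scenario.stationary_sd
    tau_s = scenario.ou_tau_hours * 3600.0
    edge = RANGE_EDGE_FACTOR * sd
    caught = scenario.disperser_type == "caught_in_transit"

    t = pd.Timestamp(scenario.start_date)
    t_end = t + pd.Timedelta(days=scenario.duration_days)
    s1_days = rng.uniform(*scenario.s1_fraction) * scenario.duration_days
    t_depart = t + pd.Timedelta(days=s1_days)

    ns, ne = scenario.night_hours
    # net outward progress per unit speed of a kappa-tortuous leg
    from scipy.special import i0, i1

    k = scenario.excursion_kappa
    exc_net = float(i1(k) / i0(k)) if math.isfinite(k) else 1.0

    hold_days = 1.5
    if caught:
        pos = c1 + rng.uniform(0.3, 0.6) * (c2 - c1) + rng.normal(0.0, sd, 2)
        hold_center = pos.copy()
        t_hold_end = t + pd.Timedelta(days=hold_days)
        mode = "H"         # post-capture hold, then T -> S2
        # expected settling day, for scheduling S2 excursions
        night_m_per_day = (
            0.95 * scenario.transient_speed_mean * 12.0 * 3600.0
        )
        s1_days = hold_days + float(np.hypot(*(c2 - pos))) / night_m_per_day
    else:
        pos = c1 + rng.normal(0.0, sd, 2)
        hold_center = pos
        t_hold_end = t
        mode = "S1"        # S1 -> T -> S2

    # Excursion schedule: Poisson counts per stationary segment (at least one
    # each, so every segmented individual exhibits the phase), placed at
    # early-night times so an out-and-back loop fits within a single night.
    start0 = pd.Timestamp(scenario.start_date)
    s2_days = max(scenario.duration_days - s1_days - 3.0, 1.5)
    def _n_exc(expected: float) -> int:
        # at least one excursion per stationary segment (capped at two, so
        # envelope contamination stays small); none when the rate is zero
        if scenario.excursion_rate <= 0:
            return 0
        return min(2, max(1, int(rng.poisson(expected))))

    n_exc2 = _n_exc(scenario.excursion_rate * s2_days)
    days_list = [rng.uniform(s1_days + 4.0, scenario.duration_days - 1.0, n_exc2)]
    if not caught:
        n_exc1 = _n_exc(scenario.excursion_rate * s1_days)
        days_list.append(rng.uniform(1.0, max(s1_days - 1.0, 1.5), n_exc1))
    days = np.concatenate(days_list)
    exc_queue = sorted(
        start0 + pd.Timedelta(days=int(d), hours=ns + float(rng.uniform(0.0, 2.0)))
        for d in days
    )
    exc_leg = None         # None | "out" | "loiter" | "back"
    exc_target = 0.0
    exc_bearing = 0.0      # fixed outward direction of the current excursion
    exc_loiter = 0         # remaining loiter fixes at the far point
    exc_base = rng.uniform(0.0, TWO_PI)   # first excursion direction
    exc_count = 0          # golden-angle rotation spreads later directions
    heading = rng.uniform(0.0, TWO_PI)

    times, xs_, ys_, phases = [], [], [], []
    t_arrive = None
    t_depart_actual = None

    while t <= t_end:
        center = c1 if mode == "S1" else c2
        night = _is_night(t, scenario.night_hours)
        times.append(t)
        xs_.append(pos[0])
        ys_.append(pos[1])
        if mode in ("T", "H"):
            phases.append("transient")
        else:
            d = float(np.hypot(*(pos - center)))
            phases.append(
                "exploratory" if exc_leg is not None and d > edge else "stationary"
            )

        dt_min = scenario.active_interval if night else scenario.inactive_interval
        dt_s = dt_min * 60.0
        t_next = t + pd.Timedelta(minutes=dt_min)

        # --- advance position over (t, t_next) ---
        if mode == "H":
            if t >= t_hold_end and night:
                mode = "T"
                heading = math.atan2(*(c2 - pos)[::-1])
            else:
                # post-capture hold: tight reversion around the release site
                a = math.exp(-dt_s / (0.5 * tau_s))
                pos = hold_center + (pos - hold_center) * a + rng.normal(
                    0.0, 0.25 * sd * math.sqrt(1.0 - a * a), 2
                )
        if mode in ("S1", "S2") and exc_leg is None:
            dawn = t.normalize() + pd.Timedelta(hours=ne)
            if t >= dawn:
                dawn += pd.Timedelta(days=1)
            night_left_h = (dawn - t).total_seconds() / 3600.0
            if (
                mode == "S1" and night and t >= t_depart
                and night_left_h >= 6.0
            ):
                # depart: switch to transient from the next fix on
                mode = "T"
                t_depart_actual = t_next
                heading = math.atan2(*(c2 - pos)[::-1])
                # stale S1 excursion slots never fire during/after transit
                exc_queue = [q for q in exc_queue if q > t + pd.Timedelta(days=2)]
            elif exc_queue and night and t >= exc_queue[0]:
                exc_queue.pop(0)
                exc_leg = "out"
                exc_target = scenario.excursion_amplitude * rng.uniform(1.0, 1.1)
                exc_bearing = (
                    exc_base + exc_count * 2.39996 + float(rng.normal(0.0, 0.3))
                )
                exc_count += 1
                exc_loiter = int(rng.integers(6, 13))
            if exc_leg is None and mode != "T":
                a = math.exp(-dt_s / tau_s)
                pos = center + (pos - center) * a + rng.normal(
                    0.0, sd * math.sqrt(1.0 - a * a), 2
                )
        if mode in ("S1", "S2") and exc_leg is not None:
            if not night:
                pos = pos + rng.normal(0.0, scenario.rest_jitter, 2)
            else:
                d = float(np.hypot(*(pos - center)))
                if exc_leg == "out" and d >= exc_target:
                    exc_leg = "loiter"
                if exc_leg == "loiter" and exc_loiter <= 0:
                    exc_leg = "back"
                if exc_leg in ("out", "loiter"):
                    # turn back in time to be home before dawn
                    dawn = t.normalize() + pd.Timedelta(hours=ne)
                    if t >= dawn:
                        dawn += pd.Timedelta(days=1)
                    need_s = d / (exc_net * scenario.exploratory_speed_mean)
                    if (dawn - t).total_seconds() < need_s:
                        exc_leg = "back"
                if exc_leg == "back":
                    base = math.atan2(*(center - pos)[::-1])
                elif exc_leg == "loiter":
                    base = rng.uniform(0.0, TWO_PI)
                    exc_loiter -= 1
                else:
                    base = exc_bearing
                heading = base + _vm(rng, scenario.excursion_kappa)
                speed = rng.gamma(4.0, scenario.exploratory_speed_mean / 4.0)
                pos = pos + speed * dt_s * np.array(
                    [math.cos(heading), math.sin(heading)]
                )
                if exc_leg == "back" and float(np.hypot(*(pos - center))) <= sd:
                    exc_leg = None
        elif mode == "T":
            if not night:
                pos = pos + rng.normal(0.0, scenario.rest_jitter, 2)
            else:
                heading = math.atan2(*(c2 - pos)[::-1]) + _vm(
                    rng, scenario.transient_persistence
                )
                shape = scenario.transient_speed_shape
                speed = rng.gamma(shape, scenario.transient_speed_mean / shape)
                pos = pos + speed * dt_s * np.array(
                    [math.cos(heading), math.sin(heading)]
                )
                if float(np.hypot(*(pos - c2))) <= 2.0 * sd:
                    mode = "S2"
                    t_arrive = t_next
        t = t_next

    if t_arrive is None:
        raise ValueError(
            "duration too short: transient leg did not reach the second range; "
            "increase duration_days or transient_speed_mean"
        )

    fixes = pd.DataFrame({"t": times, "x": xs_, "y": ys_})
    phase = pd.Series(phases, name="true_phase")

    # open-ended transient intervals for partial records
    lo, hi = t_depart_actual, t_arrive
    if caught:
        keep = pd.Series(True, index=fixes.index)
        lo = None
    elif scenario.disperser_type == "truncated":
        cut = lo + (hi - lo) * rng.uniform(0.4, 0.8)
        keep = fixes["t"] <= cut
        hi = None
    else:
        keep = pd.Series(True, index=fixes.index)

    # dropped fixes (collar gaps); always keep the first retained fix
    drop = rng.random(len(fixes)) < scenario.gap_prob
    first = int(np.flatnonzero(keep.to_numpy())[0])
    drop[first] = False
    keep &= ~drop

    fixes = fixes[keep].reset_index(drop=True)
    phase = phase[keep].reset_index(drop=True)
    trap = (float(fixes["x"].iloc[0]), float(fixes["y"].iloc[0]))
    return LabeledFixSeries(
        fixes=fixes,
        true_phase=phase,
        trap_location=trap,
        trap_time=fixes["t"].iloc[0],
        true_transient=(lo, hi),
    )


_TYPE_WEIGHTS = {"full": 8, "caught_in_transit": 3, "truncated": 1}


def _type_mixture(n: int, weights: dict[str, int] | None = None) -> list[str]:
    """Largest-remainder apportionment of disperser types over n individuals."""
    w = weights or _TYPE_WEIGHTS
    total = sum(w.values())
    quotas = {k: v * n / total for k, v in w.items()}
    counts = {k: int(q) for k, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    out: list[str] = []
    for k in ("full", "caught_in_transit", "truncated"):
        out += [k] * counts.get(k, 0)
    return out


def simulate_population(
    scenario: SimScenario,
    landscape: LandscapeStack | None = None,
    extent: tuple[float, float] = (30_000.0, 20_000.0),
    type_weights: dict[str, int] | None = None,
    shared_centers: bool = False,
) -> tuple[list[LabeledFixSeries], LandscapeStack]:
    """Simulate a cohort of individuals plus a shared landscape.

    Per-individual seeds and disperser types are derived deterministically
    from the master seed; the default mixture follows the 8 full : 3
    caught-in-transit : 1 truncated composition of a twelve-fox cohort.
    Unless ``shared_centers`` is set, each individual gets its own pair of
    home-range centres (natal range toward the western side of the extent,
    post-dispersal range toward the eastern side), as real cohorts do; the
    scenario's ``center1``/``center2`` then act as the cohort's west/east
    anchor coordinates.
    """
    scenario.validate()
    ss = np.random.SeedSequence(scenario.seed)
    land_seed, centers_seed, *ind_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in ss.spawn(scenario.n_individuals + 2)
    ]
    if landscape is None:
        landscape = simulate_landscape(
            extent, land_seed, corridor=(scenario.center1, scenario.center2)
        )
    types = _type_mixture(scenario.n_individuals, type_weights)

    crng = np.random.default_rng(centers_seed)
    margin = 1.5 * scenario.excursion_amplitude
    out = []
    for i, (seed_i, type_i) in enumerate(zip(ind_seeds, types)):
        sub = replace(scenario, seed=seed_i, disperser_type=type_i, n_individuals=1)
        if not shared_centers:
            c1 = (
                float(crng.uniform(margin, scenario.center1[0] + 2_000.0)),
                float(crng.uniform(margin, extent[1] - margin)),
            )
            c2 = (
                float(crng.uniform(scenario.center2[0] - 2_000.0, extent[0] - margin)),
                float(crng.uniform(margin, extent[1] - margin)),
            )
            sub = replace(sub, center1=c1, center2=c2)
        series = simulate_individual(sub, landscape)
        series.fixes.insert(0, "individual_id", f"fox{i + 1:02d}")
        out.append(series)
    return out, landscape


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def telemetry_to_csv(
    population: list[LabeledFixSeries],
    path: str | Path,
    crs: str = "EPSG:32632",
    include_truth: bool = False,
) -> pd.DataFrame:
    """Write fixes as Movebank-style delimited text plus a CRS sidecar.

    Columns: ``individual_id, timestamp`` (ISO-8601 UTC), ``x, y`` (m,
    projected).  Ground-truth labels are only included on request (testing).
    """
    frames = []
    for s in population:
        df = s.fixes.copy()
        if "individual_id" not in df.columns:
            df.insert(0, "individual_id", "fox01")
        df["timestamp"] = df.pop("t").dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        cols = ["individual_id", "timestamp", "x", "y"]
        if include_truth:
            df["true_phase"] = s.true_phase.to_numpy()
            cols.append("true_phase")
        frames.append(df[cols])
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    out.to_csv(path, index=False, float_format="%.2f")
    path.with_suffix(".json").write_text(f'{{"crs": "{crs}"}}\n')
    return out
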