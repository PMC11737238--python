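"""Segmentation of tracks into stationary, transient and exploratory phases.

A dispersal record is modelled as a first stationary state (S1, range
residency around the capture area), a one-way transient interval (T), and a
second stationary state (S2).  Within a stationary state, a fix is
*exploratory* when its x coordinate, y coordinate, or displacement from the
state's origin falls outside the state's empirical [1.5 %, 98.5 %] quantile
envelope, provided its out-of-envelope run is bounded on both sides by a
return to the envelope (out-and-back excursion).  Two guard rules anchor S1
to the trapping site: any S1 fix within 1 km of the trap is stationary
regardless of the envelope, and transient-interval fixes whose displacement
from the trap drops below 1 km (a return to the trapping location) are
relabelled stationary.

State detection is a deliberately simple two-cluster procedure (k-means on
x/y with residency and separation checks, plus a robust core-radius
refinement of the run boundaries); externally computed boundaries can be
supplied verbatim instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

PHASES = ("stationary", "transient", "exploratory")


class SegmentationError(ValueError):
    """The record cannot be segmented as requested."""


class NonDisperserError(SegmentationError):
    """No two sufficiently separated stationary clusters: not a disperser."""


class UnclassifiableError(SegmentationError):
    """Neither stationary run satisfies the residency requirement."""


@dataclass
class QuantileEnvelope:
    """Empirical quantile bounds of a stationary state's x, y and displacement."""

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float
    d_lo: float
    d_hi: float
    q_lo: float = 0.015
    q_hi: float = 0.985
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.x_lo <= self.x_hi and self.y_lo <= self.y_hi
                and self.d_lo <= self.d_hi):
            raise ValueError("envelope bounds must satisfy lo <= hi")

    def contains(self, x, y) -> np.ndarray:
        """In-envelope test (closed intervals, OR of exceedances negated)."""
        d = np.hypot(
            np.asarray(x) - self.origin[0], np.asarray(y) - self.origin[1]
        )
        return (
            (self.x_lo <= x) & (x <= self.x_hi)
            & (self.y_lo <= y) & (y <= self.y_hi)
            & (self.d_lo <= d) & (d <= self.d_hi)
        )


@dataclass
class StationaryState:
    label: str                      # "S1" | "S2"
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    center: tuple[float, float]
    envelope: QuantileEnvelope | None = None

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError(f"{self.label}: t_start must precede t_end")


@dataclass
class Excursion:
    state_label: str
    i_start: int          # positional index into the fix frame
    i_end: int            # inclusive
    returned: bool


@dataclass
class PhaseSegmentation:
    """Per-fix phase labels plus the state/transient structure behind them."""

    states: list[StationaryState]
    transient: tuple[pd.Timestamp | None, pd.Timestamp | None]
    labels: pd.DataFrame    # columns: t, x, y, phase, state_label, excursion_id
    excursions: list[Excursion] = field(default_factory=list)

    def to_frame(self, individual_id: str | None = None) -> pd.DataFrame:
        out = self.labels.copy()
        if individual_id is not None:
            out.insert(0, "individual_id", individual_id)
        return out


# ---------------------------------------------------------------------------
# state detection
# ---------------------------------------------------------------------------

def _run_length(
    mask: np.ndarray,
    t: pd.Series,
    from_start: bool,
    tol: pd.Timedelta = pd.Timedelta(hours=36),
) -> int:
    """Length of the maximal True prefix (or suffix) of ``mask``.

    False interruptions shorter than ``tol`` that are followed by a return
    to True are bridged: a one-night excursion that briefly crosses the
    cluster boundary must not terminate a months-long stationary run.  A
    dispersal leg is never bridged because the track does not return.
    """
    n = len(mask)
    idx = range(n) if from_start else range(n - 1, -1, -1)
    idx = list(idx)
    run = 0
    i = 0
    while i < n:
        if mask[idx[i]]:
            run = i + 1
            i += 1
            continue
        j = i
        while j < n and not mask[idx[j]]:
            j += 1
        if j == n:
            break
        a, b = t.iloc[idx[i]], t.iloc[idx[j - 1]]
        if abs(b - a) >= tol:
            break
        i = j  # bridged: interruption short and followed by a return
    return run


def _core_trim(x, y, t, idx, factor):
    """Robust occupancy core of a candidate run: centre (median x/y) and the
    fixes within ``factor`` x median-distance-to-centre."""
    cx = float(np.median(x[idx]))
    cy = float(np.median(y[idx]))
    dist = np.hypot(x[idx] - cx, y[idx] - cy)
    r = factor * float(np.median(dist))
    inside = np.flatnonzero(dist <= r)
    return (cx, cy), idx[inside]


def detect_stationary_states(
    fixes: pd.DataFrame,
    min_residency_days: float = 7.0,
    min_separation: float = 2_000.0,
    core_radius_factor: float = 4.0,
    random_state: int = 0,
) -> tuple[list[StationaryState], tuple[pd.Timestamp | None, pd.Timestamp | None]]:
    """Two-cluster detection of S1/S2 and the transient interval between them.

    k-means with k=2 on (x, y) assigns every fix to a spatial cluster.  The
    maximal initial run in the first fix's cluster and the maximal final run
    in the last fix's cluster are candidate stationary states; each must span
    at least ``min_residency_days`` to count.  Because cluster assignment
    switches at the spatial midpoint between the two centres, raw run ends
    would swallow roughly half of the transient leg into each state, so run
    boundaries are trimmed to the state's occupancy core (fixes within
    ``core_radius_factor`` times the median distance to the run's median
    centre): S1 ends at its last in-core fix, S2 starts at its first.

    Degenerate cases follow the record's shape: no qualifying initial run
    means the animal was caught in transit (T runs from the data start to S2);
    no qualifying final run means the record was truncated in transit (T runs
    from S1 to the data end).

    Raises
    ------
    NonDisperserError
        Cluster centres closer than ``min_separation`` m, or the record
        starts and ends in the same cluster.
    UnclassifiableError
        Neither run satisfies the residency requirement.
    SegmentationError
        Data span below twice the residency requirement.
    """
    t = fixes["t"].reset_index(drop=True)
    x = fixes["x"].to_numpy(float)
    y = fixes["y"].to_numpy(float)
    span = t.iloc[-1] - t.iloc[0]
    residency = pd.Timedelta(days=min_residency_days)
    if span < 2 * residency:
        raise SegmentationError(
            f"record spans {span}, need >= {2 * residency} for two states"
        )

    # Cluster on spatially declustered locations (unique 100 m grid cells) so
    # a long transit path and a months-long home range carry comparable
    # weight, and seed the two centres at the temporal ends of the record
    # (robust medians of the first and last two days): the converged centres
    # then track where the record begins and ends instead of splitting
    # whichever cloud holds the most fixes.
    cells = np.unique(
        np.column_stack([np.floor(x / 100.0), np.floor(y / 100.0)]), axis=0
    )
    head = (t <= t.iloc[0] + pd.Timedelta(hours=12)).to_numpy()
    tail = (t >= t.iloc[-1] - pd.Timedelta(hours=12)).to_numpy()
    init = np.array([
        [np.median(x[head]), np.median(y[head])],
        [np.median(x[tail]), np.median(y[tail])],
    ])
    km = KMeans(n_clusters=2, init=init, n_init=1, random_state=random_state)
    km.fit((cells + 0.5) * 100.0)
    centers = km.cluster_centers_
    if float(np.hypot(*(centers[0] - centers[1]))) < min_separation:
        # A record caught (or truncated) in transit leaves only a thin path
        # next to one large range, and centroid iteration collapses both
        # centres into the range.  When the record's own temporal endpoints
        # are nevertheless far apart, keep the endpoint anchors as centres.
        if float(np.hypot(*(init[0] - init[1]))) >= min_separation:
            centers = init
        else:
            raise NonDisperserError(
                "cluster centres closer than the minimum separation: "
                "no dispersal"
            )
    labels = np.argmin(
        np.hypot(x[:, None] - centers[:, 0], y[:, None] - centers[:, 1]), axis=1
    )

    first_run = _run_length(labels == labels[0], t, from_start=True)
    final_run = _run_length(labels == labels[-1], t, from_start=False)
    has_s1 = t.iloc[first_run - 1] - t.iloc[0] >= residency
    has_s2 = t.iloc[-1] - t.iloc[len(t) - final_run] >= residency
    if has_s1 and has_s2 and labels[0] == labels[-1]:
        raise NonDisperserError("record starts and ends in the same cluster")
    if not has_s1 and not has_s2:
        raise UnclassifiableError("no stationary run satisfies the residency rule")

    states: list[StationaryState] = []
    t_first, t_last = t.iloc[0], t.iloc[-1]
    s1_end = None
    s2_start = None
    if has_s1:
        idx = np.arange(first_run)
        center, core = _core_trim(x, y, t, idx, core_radius_factor)
        s1_end = t.iloc[int(core[-1])]
        states.append(StationaryState("S1", t_first, s1_end, center))
    if has_s2:
        idx = np.arange(len(t) - final_run, len(t))
        center, core = _core_trim(x, y, t, idx, core_radius_factor)
        s2_start = t.iloc[int(core[0])]
        states.append(StationaryState("S2", s2_start, t_last, center))
    transient = (s1_end if has_s1 else None, s2_start if has_s2 else None)
    return states, transient


def accept_external_segmentation(
    fixes: pd.DataFrame,
    boundaries: dict[str, tuple[pd.Timestamp, pd.Timestamp]],
) -> tuple[list[StationaryState], tuple[pd.Timestamp | None, pd.Timestamp | None]]:
    """Build states and transient interval verbatim from supplied boundaries.

    ``boundaries`` maps state labels ("S1", "S2") to (t_start, t_end); either
    state may be absent for records caught or truncated in transit.  The
    transient interval is the span between S1's end and S2's start, falling
    back to the data edges when a state is missing.
    """
    known = set(boundaries) - {"S1", "S2"}
    if known:
        raise SegmentationError(f"unknown boundary labels: {sorted(known)}")
    if not boundaries:
        raise SegmentationError("no boundaries supplied")
    t = fixes["t"]
    t_first, t_last = t.iloc[0], t.iloc[-1]
    for label, (a, b) in boundaries.items():
        if a >= b:
            raise SegmentationError(f"{label}: t_start must precede t_end")
        if a < t_first or b > t_last:
            raise SegmentationError(f"{label}: boundaries outside the data span")
    if "S1" in boundaries and "S2" in boundaries:
        if boundaries["S2"][0] < boundaries["S1"][1]:
            raise SegmentationError("S2 starts before S1 ends")

    states = []
    for label in ("S1", "S2"):
        if label not in boundaries:
            continue
        a, b = boundaries[label]
        sel = (t >= a) & (t <= b)
        if not sel.any():
            raise SegmentationError(f"{label}: no fixes inside the boundaries")
        center = (
            float(fixes.loc[sel, "x"].median()),
            float(fixes.loc[sel, "y"].median()),
        )
        states.append(StationaryState(label, a, b, center))
    s1_end = boundaries["S1"][1] if "S1" in boundaries else None
    s2_start = boundaries["S2"][0] if "S2" in boundaries else None
    return states, (s1_end, s2_start)


# ---------------------------------------------------------------------------
# envelopes and labelling
# ---------------------------------------------------------------------------

def stationary_envelope(
    state_fixes: pd.DataFrame,
    state_label: str,
    origin: tuple[float, float],
    q_lo: float = 0.015,
    q_hi: float = 0.985,
    s2_window_days: float = 28.0,
    min_fixes: int = 50,
) -> QuantileEnvelope:
    """Quantile envelope of a stationary state's x, y and displacement.

    For S2 only the first ``s2_window_days`` of the state contribute, since
    post-settlement records can run for months.  Quantiles are empirical with
    linear interpolation.  ``origin`` is the displacement reference: the trap
    location for S1, the state's first fix for S2.
    """
    g = state_fixes
    if state_label == "S2":
        cutoff = g["t"].iloc[0] + pd.Timedelta(days=s2_window_days)
        g = g[g["t"] <= cutoff]
    if len(g) < min_fixes:
        raise SegmentationError(
            f"state {state_label}: only {len(g)} fixes, need >= {min_fixes} "
            "for a stable envelope"
        )
    x = g["x"].to_numpy(float)
    y = g["y"].to_numpy(float)
    d = np.hypot(x - origin[0], y - origin[1])
    lo_x, hi_x = np.quantile(x, [q_lo, q_hi])
    lo_y, hi_y = np.quantile(y, [q_lo, q_hi])
    lo_d, hi_d = np.quantile(d, [q_lo, q_hi])
    return QuantileEnvelope(lo_x, hi_x, lo_y, hi_y, lo_d, hi_d,
                            q_lo, q_hi, origin)


def label_exploratory(
    fixes: pd.DataFrame,
    states: list[StationaryState],
    transient: tuple[pd.Timestamp | None, pd.Timestamp | None],
    trap_location: tuple[float, float] | None,
    trap_radius: float = 1_000.0,
) -> PhaseSegmentation:
    """Per-fix phase labels from states, envelopes and the trap rules.

    Within a stationary state's timespan, contiguous runs of out-of-envelope
    fixes bounded on both sides by in-envelope fixes of the same state are
    excursions (exploratory); runs touching the state's edge lack the
    required return and stay stationary.  S1 fixes within ``trap_radius`` of
    the trap are stationary regardless of the envelope.  Transient-interval
    fixes whose displacement from the trap is below ``trap_radius`` are
    relabelled stationary (return to the trapping location); the rest are
    transient.
    """
    has_s1 = any(s.label == "S1" for s in states)
    if has_s1 and trap_location is None:
        raise SegmentationError("trap_location is required when S1 is present")
    for s in states:
        if s.envelope is None:
            raise SegmentationError(f"state {s.label} has no envelope")

    t = fixes["t"].reset_index(drop=True)
    x = fixes["x"].to_numpy(float)
    y = fixes["y"].to_numpy(float)
    n = len(fixes)
    phase = np.full(n, "", dtype=object)
    state_label = np.full(n, "", dtype=object)
    excursion_id = np.full(n, -1, dtype=int)
    excursions: list[Excursion] = []

    t_lo, t_hi = transient
    in_T = np.ones(n, dtype=bool)
    if t_lo is not None:
        in_T &= (t > t_lo).to_numpy()
    if t_hi is not None:
        in_T &= (t < t_hi).to_numpy()

    for s in states:
        sel = ((t >= s.t_start) & (t <= s.t_end)).to_numpy()
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            continue
        in_T[sel] = False
        state_label[sel] = s.label
        out = ~s.envelope.contains(x[idx], y[idx])
        if s.label == "S1":
            near_trap = (
                np.hypot(x[idx] - trap_location[0], y[idx] - trap_location[1])
                < trap_radius
            )
            out &= ~near_trap
        phase[idx] = "stationary"
        # contiguous out-of-envelope runs, bounded by in-envelope fixes
        j = 0
        while j < len(idx):
            if not out[j]:
                j += 1
                continue
            k = j
            while k + 1 < len(idx) and out[k + 1]:
                k += 1
            returned = j > 0 and k < len(idx) - 1
            if returned:
                phase[idx[j:k + 1]] = "exploratory"
                excursion_id[idx[j:k + 1]] = len(excursions)
            excursions.append(Excursion(s.label, int(idx[j]), int(idx[k]), returned))
            j = k + 1

    if in_T.any():
        ti = np.flatnonzero(in_T)
        if trap_location is not None:
            d_trap = np.hypot(
                x[ti] - trap_location[0], y[ti] - trap_location[1]
            )
            back = d_trap < trap_radius
        else:
            back = np.zeros(len(ti), dtype=bool)
        phase[ti] = np.where(back, "stationary", "transient")
        state_label[ti] = ""

    labels = pd.DataFrame({
        "t": t, "x": x, "y": y,
        "phase": phase, "state_label": state_label,
        "excursion_id": excursion_id,
    })
    return PhaseSegmentation(states, transient, labels, excursions)


def segment_track(
    fixes: pd.DataFrame,
    trap_location: tuple[float, float],
    min_residency_days: float = 7.0,
    min_separation: float = 2_000.0,
    core_radius_factor: float = 4.0,
    q_lo: float = 0.015,
    q_hi: float = 0.985,
    s2_window_days: float = 28.0,
    min_envelope_fixes: int = 50,
    trap_radius: float = 1_000.0,
    boundaries: dict | None = None,
    random_state: int = 0,
) -> PhaseSegmentation:
    """Detect states (or accept external boundaries), build envelopes, label.

    Convenience orchestration of :func:`detect_stationary_states`,
    :func:`stationary_envelope` and :func:`label_exploratory` for one
    individual's cleaned fixes.
    """
    fixes = fixes.reset_index(drop=True)
    if boundaries is not None:
        states, transient = accept_external_segmentation(fixes, boundaries)
    else:
        states, transient = detect_stationary_states(
            fixes, min_residency_days, min_separation, core_radius_factor,
            random_state,
        )
    t = fixes["t"]
    for s in states:
        g = fixes[(t >= s.t_start) & (t <= s.t_end)]
        origin = trap_location if s.label == "S1" else (
            float(g["x"].iloc[0]), float(g["y"].iloc[0])
        )
        s.envelope = stationary_envelope(
            g, s.label, origin, q_lo, q_hi, s2_window_days, min_envelope_fixes
        )
    return label_exploratory(fixes, states, transient, trap_location, trap_radius)


def segmentation_summary(
    segmentations: dict[str, PhaseSegmentation]
) -> pd.DataFrame:
    """One row per stationary state: interval, centre and envelope bounds."""
    rows = []
    for ind, seg in segmentations.items():
        for s in seg.states:
            e = s.envelope
            rows.append({
                "individual_id": ind,
                "state": s.label,
                "t_start": s.t_start,
                "t_end": s.t_end,
                "center_x": s.center[0],
                "center_y": s.center[1],
                "transient_start": seg.transient[0],
                "transient_end": seg.transient[1],
                **({
                    "x_lo": e.x_lo, "x_hi": e.x_hi,
                    "y_lo": e.y_lo, "y_hi": e.y_hi,
                    "d_lo": e.d_lo, "d_hi": e.d_hi,
                } if e is not None else {}),
            })
    return pd.DataFrame(rows)


def segmentation_to_csv(
    segmentations: dict[str, PhaseSegmentation], path
) -> pd.DataFrame:
    """Per-fix segmentation export: one delimited row per fix."""
    out = pd.concat(
        [seg.to_frame(ind) for ind, seg in segmentations.items()],
        ignore_index=True,
    )
    out.to_csv(path, index=False, float_format="%.2f")
    return out
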