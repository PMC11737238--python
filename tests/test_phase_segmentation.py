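"""Quantile envelopes, excursion labelling (vs a brute-force oracle) and
stationary-state detection against the simulator's ground truth."""

import numpy as np
import pandas as pd
import pytest

from foxphase import phase_segmentation as ps

from .conftest import random_walk_fixes


def make_state_fixes(seed, n=1000, center=(5000.0, 5000.0), spread=500.0,
                     start="2022-01-01"):
    rng = np.random.default_rng(seed)
    t = pd.date_range(start, periods=n, freq="10min")
    return pd.DataFrame({
        "individual_id": "a",
        "t": t,
        "x": rng.uniform(center[0] - spread, center[0] + spread, n),
        "y": rng.uniform(center[1] - spread, center[1] + spread, n),
    })


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

def test_uniform_square_quantiles_match_closed_form():
    g = make_state_fixes(seed=0, n=4000)
    env = ps.stationary_envelope(g, "S1", origin=(5000.0, 5000.0))
    # uniform on [4500, 5500]: q-quantile = 4500 + q * 1000
    assert env.x_lo == pytest.approx(4500 + 0.015 * 1000, abs=25)
    assert env.x_hi == pytest.approx(4500 + 0.985 * 1000, abs=25)
    assert env.y_lo == pytest.approx(4515, abs=25)
    assert env.y_hi == pytest.approx(5485, abs=25)


def test_full_range_envelope_leaves_no_fix_outside():
    g = make_state_fixes(seed=1)
    env = ps.stationary_envelope(g, "S1", origin=(5000.0, 5000.0),
                                 q_lo=0.0, q_hi=1.0)
    assert env.contains(g["x"].to_numpy(), g["y"].to_numpy()).all()


def test_s2_envelope_uses_first_four_weeks_only():
    g = make_state_fixes(seed=2, n=6000)  # ~41 days at 10-min cadence
    origin = (float(g["x"].iloc[0]), float(g["y"].iloc[0]))
    env_full = ps.stationary_envelope(g, "S2", origin=origin)
    cutoff = g["t"].iloc[0] + pd.Timedelta(days=28)
    env_sub = ps.stationary_envelope(g[g["t"] <= cutoff], "S2", origin=origin)
    for f in ("x_lo", "x_hi", "y_lo", "y_hi", "d_lo", "d_hi"):
        assert getattr(env_full, f) == getattr(env_sub, f)


def test_envelope_needs_enough_fixes():
    g = make_state_fixes(seed=3, n=20)
    with pytest.raises(ps.SegmentationError, match="S1"):
        ps.stationary_envelope(g, "S1", origin=(5000.0, 5000.0))


# ---------------------------------------------------------------------------
# labelling
# ---------------------------------------------------------------------------

def _label_setup(seed=0, n=600):
    fixes = make_state_fixes(seed=seed, n=n)
    state = ps.StationaryState(
        "S1", fixes["t"].iloc[0], fixes["t"].iloc[-1], (5000.0, 5000.0)
    )
    state.envelope = ps.stationary_envelope(
        fixes, "S1", origin=(5000.0, 5000.0)
    )
    return fixes, state


def test_fix_on_envelope_bound_is_inside():
    fixes, state = _label_setup()
    e = state.envelope
    assert e.contains(e.x_hi, 5000.0)
    assert e.contains(e.x_lo, 5000.0)
    assert not e.contains(np.nextafter(e.x_hi, np.inf), 5000.0)


def brute_force_labels(fixes, states, transient, trap, trap_radius=1000.0):
    """Independent per-fix re-evaluation of the labelling rule."""
    n = len(fixes)
    phase = []
    for i in range(n):
        t, x, y = fixes["t"].iloc[i], fixes["x"].iloc[i], fixes["y"].iloc[i]
        in_state = None
        for s in states:
            if s.t_start <= t <= s.t_end:
                in_state = s
        if in_state is None:
            d_trap = np.hypot(x - trap[0], y - trap[1]) if trap else np.inf
            phase.append("stationary" if d_trap < trap_radius else "transient")
            continue
        e = in_state.envelope
        out = not bool(e.contains(x, y))
        if in_state.label == "S1" and trap is not None:
            if np.hypot(x - trap[0], y - trap[1]) < trap_radius:
                out = False
        phase.append("OUT" if out else "stationary")
    # resolve OUT runs: exploratory only when bounded by in-state stationary
    phase = np.array(phase, dtype=object)
    i = 0
    while i < n:
        if phase[i] != "OUT":
            i += 1
            continue
        j = i
        while j + 1 < n and phase[j + 1] == "OUT":
            j += 1
        state_of = lambda k: next(
            (s.label for s in states
             if s.t_start <= fixes["t"].iloc[k] <= s.t_end), None
        )
        bounded = (
            i > 0 and j < n - 1
            and phase[i - 1] == "stationary" and phase[j + 1] == "stationary"
            and state_of(i - 1) == state_of(i) == state_of(j + 1)
        )
        phase[i:j + 1] = "exploratory" if bounded else "stationary"
        i = j + 1
    return phase


def test_label_exploratory_matches_per_fix_oracle():
    """On 100 random tracks the vectorized labeller equals the rule applied
    fix by fix."""
    rng = np.random.default_rng(77)
    for rep in range(100):
        n = 160
        fixes = random_walk_fixes(seed=int(rng.integers(1e6)), n=n, sd=150.0)
        mid = n // 2
        states = []
        s1 = ps.StationaryState(
            "S1", fixes["t"].iloc[0], fixes["t"].iloc[mid], (0.0, 0.0)
        )
        # deliberately narrow envelope so excursion runs appear
        gx = fixes.iloc[:mid]
        s1.center = (float(gx["x"].median()), float(gx["y"].median()))
        q_lo, q_hi = 0.10, 0.90
        s1.envelope = ps.stationary_envelope(
            gx, "S1", origin=s1.center, q_lo=q_lo, q_hi=q_hi, min_fixes=5
        )
        states.append(s1)
        trap = (float(fixes["x"].iloc[0]), float(fixes["y"].iloc[0]))
        transient = (fixes["t"].iloc[mid], None)
        seg = ps.label_exploratory(fixes, states, transient, trap,
                                   trap_radius=200.0)
        want = brute_force_labels(fixes, states, transient, trap,
                                  trap_radius=200.0)
        assert list(seg.labels["phase"]) == list(want), f"rep={rep}"


def test_unreturned_terminal_run_stays_stationary():
    fixes, state = _label_setup(seed=5)
    # append a terminal run marching far outside the envelope, no return
    t0 = fixes["t"].iloc[-1]
    tail = pd.DataFrame({
        "individual_id": "a",
        "t": [t0 + pd.Timedelta(minutes=10 * (i + 1)) for i in range(10)],
        "x": np.linspace(7000, 12000, 10),
        "y": 5000.0,
    })
    all_fixes = pd.concat([fixes, tail], ignore_index=True)
    state.t_end = all_fixes["t"].iloc[-1]
    seg = ps.label_exploratory(
        all_fixes, [state], (None, None), trap_location=(5000.0, 5000.0)
    )
    assert (seg.labels["phase"].iloc[-10:] == "stationary").all()
    assert any(not e.returned for e in seg.excursions)


def test_widening_quantiles_never_increases_exploratory_count():
    fixes = random_walk_fixes(seed=13, n=800, sd=120.0)
    counts = []
    for (ql, qh) in [(0.10, 0.90), (0.05, 0.95), (0.015, 0.985), (0.0, 1.0)]:
        state = ps.StationaryState(
            "S1", fixes["t"].iloc[0], fixes["t"].iloc[-1],
            (float(fixes["x"].median()), float(fixes["y"].median())),
        )
        state.envelope = ps.stationary_envelope(
            fixes, "S1", origin=state.center, q_lo=ql, q_hi=qh, min_fixes=5
        )
        seg = ps.label_exploratory(
            fixes, [state], (None, None),
            trap_location=(float(fixes["x"].iloc[0]), float(fixes["y"].iloc[0])),
            trap_radius=0.0,
        )
        counts.append(int((seg.labels["phase"] == "exploratory").sum()))
    assert counts == sorted(counts, reverse=True)
    assert counts[-1] == 0  # full-range envelope flags nothing


def test_labels_partition_and_missing_trap_rejected(default_population):
    s = default_population[0]
    seg = ps.segment_track(
        s.fixes.reset_index(drop=True), trap_location=s.trap_location
    )
    phases = seg.labels["phase"]
    assert set(phases.unique()) <= set(ps.PHASES)
    assert phases.notna().all() and (phases != "").all()
    with pytest.raises(ps.SegmentationError, match="trap"):
        ps.label_exploratory(
            s.fixes, seg.states, seg.transient, trap_location=None
        )


def test_in_state_exploratory_fraction_bounded(default_population):
    """The 1.5/98.5 envelopes flag well under 15% of in-state fixes."""
    for s in default_population[:4]:
        seg = ps.segment_track(
            s.fixes.reset_index(drop=True), trap_location=s.trap_location
        )
        lab = seg.labels
        in_state = lab["state_label"] != ""
        frac = (lab.loc[in_state, "phase"] == "exploratory").mean()
        assert frac < 0.15


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def test_pure_stationary_individual_flagged_non_disperser():
    fixes = make_state_fixes(seed=9, n=4000, spread=400.0)  # ~28 days
    with pytest.raises(ps.NonDisperserError):
        ps.detect_stationary_states(fixes)


def test_too_short_record_rejected():
    fixes = make_state_fixes(seed=10, n=500)  # ~3.5 days
    with pytest.raises(ps.SegmentationError, match="spans"):
        ps.detect_stationary_states(fixes)


def test_caught_in_transit_transient_starts_at_first_fix(default_population):
    caught = [s for s in default_population if s.true_transient[0] is None]
    s = caught[0]
    states, transient = ps.detect_stationary_states(
        s.fixes.reset_index(drop=True)
    )
    assert [st.label for st in states] == ["S2"]
    assert transient[0] is None
    assert transient[1] is not None


def test_transient_interval_recovery_vs_truth(default_population):
    """Temporal Jaccard of the detected vs true transient interval >= 0.8
    for every full disperser in the default cohort."""
    for s in default_population:
        lo, hi = s.true_transient
        if lo is None or hi is None:
            continue
        seg = ps.segment_track(
            s.fixes.reset_index(drop=True), trap_location=s.trap_location
        )
        dlo, dhi = seg.transient
        inter = max(0, min(hi.value, dhi.value) - max(lo.value, dlo.value))
        union = max(hi.value, dhi.value) - min(lo.value, dlo.value)
        assert inter / union >= 0.8


def test_exploratory_sensitivity_vs_truth(default_population):
    """Pooled over the cohort, >= 90% of true-exploratory fixes are labelled
    exploratory by the envelope rule."""
    hits = total = 0
    for s in default_population:
        seg = ps.segment_track(
            s.fixes.reset_index(drop=True), trap_location=s.trap_location
        )
        truth = s.true_phase.to_numpy()
        pred = seg.labels["phase"].to_numpy()
        m = truth == "exploratory"
        hits += int((pred[m] == "exploratory").sum())
        total += int(m.sum())
    assert total > 0
    assert hits / total >= 0.9


# ---------------------------------------------------------------------------
# external boundaries
# ---------------------------------------------------------------------------

def test_external_boundaries_roundtrip(default_population):
    s = default_population[0]
    fixes = s.fixes.reset_index(drop=True)
    states, transient = ps.detect_stationary_states(fixes)
    bounds = {st.label: (st.t_start, st.t_end) for st in states}
    states2, transient2 = ps.accept_external_segmentation(fixes, bounds)
    assert [st.label for st in states2] == [st.label for st in states]
    for a, b in zip(states, states2):
        assert a.t_start == b.t_start and a.t_end == b.t_end
    assert transient2 == transient


def test_external_boundaries_validation():
    fixes = make_state_fixes(seed=11, n=200)
    t0, t1 = fixes["t"].iloc[0], fixes["t"].iloc[-1]
    with pytest.raises(ps.SegmentationError, match="S2 starts before"):
        ps.accept_external_segmentation(fixes, {
            "S1": (t0 + pd.Timedelta(hours=5), t1),
            "S2": (t0, t0 + pd.Timedelta(hours=2)),
        })
    with pytest.raises(ps.SegmentationError, match="outside"):
        ps.accept_external_segmentation(
            fixes, {"S1": (t0 - pd.Timedelta(days=1), t1)}
        )
    with pytest.raises(ps.SegmentationError):
        ps.accept_external_segmentation(fixes, {})


def test_truth_boundaries_reproduce_truth_labels(default_population):
    """With ground-truth boundaries supplied and the trap overrides disabled,
    stationary/transient labels match the simulator's truth exactly outside
    excursions."""
    s = next(
        p for p in default_population
        if None not in p.true_transient
    )
    fixes = s.fixes.reset_index(drop=True)
    lo, hi = s.true_transient
    seg = ps.segment_track(
        fixes,
        trap_location=s.trap_location,
        boundaries={
            # S1 ends just before the first transient fix; S2 starts at the
            # first settled fix
            "S1": (fixes["t"].iloc[0], lo - pd.Timedelta(minutes=1)),
            "S2": (hi, fixes["t"].iloc[-1]),
        },
        trap_radius=0.0,
    )
    truth = s.true_phase.to_numpy()
    pred = seg.labels["phase"].to_numpy()
    keep = (truth != "exploratory") & (pred != "exploratory")
    assert (pred[keep] == truth[keep]).all()
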