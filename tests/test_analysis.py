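import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dnamelt as dm
from dnamelt.analysis import (
    DissociationRecord,
    IncompleteMeltingError,
    at_rich_end,
    classify_opening,
    detect_events,
    interval_series,
    melting_duration,
    opening_fractions,
    order_curve,
    position_curve,
    records_to_frame,
    summarize_ensemble,
)
from dnamelt.fixtures import ScriptedEvent, scripted_trajectory


def make_record(times, n=9):
    classes = ["AT", "GC", "GC", "GC", "AT", "AT", "AT", "GC", "GC"][:n]
    return DissociationRecord(
        times=np.asarray(times, dtype=float),
        positions=np.arange(1, n + 1),
        pair_class=classes,
    )


# ------------------------------------------------------------- detect_events
def test_detect_events_on_scripted_crossings(topo11, params):
    events = [ScriptedEvent(position=1, time=5.0), ScriptedEvent(position=9, time=12.0)]
    traj = scripted_trajectory(topo11, events, dt_frame=0.5)
    rec = detect_events(traj, topo11, params)
    assert rec.times[0] == pytest.approx(5.0, abs=0.5)
    assert rec.times[8] == pytest.approx(12.0, abs=0.5)
    assert np.isnan(rec.times[1:8]).all()
    assert not rec.complete


def test_detect_events_requires_opposite_motion(topo11, params):
    """Separation above threshold while the beads approach is not an event."""
    events = [ScriptedEvent(position=4, time=6.0)]
    traj = scripted_trajectory(topo11, events, dt_frame=0.5)
    traj.velocities = -traj.velocities  # beads now close in at every frame
    rec = detect_events(traj, topo11, params)
    assert np.isnan(rec.times).all()


def test_detect_events_displacement_fallback(topo11, params):
    events = [ScriptedEvent(position=2, time=4.0)]
    traj = scripted_trajectory(topo11, events, dt_frame=0.5)
    traj.velocities = None
    rec = detect_events(traj, topo11, params)
    assert rec.times[1] == pytest.approx(4.0, abs=0.5)

    single = dm.Trajectory(times=traj.times[:1], positions=traj.positions[:1])
    with pytest.raises(ValueError, match="velocities"):
        detect_events(single, topo11, params)


def test_detect_events_debounces_recrossing(topo11, params):
    """A noisy separation trace that dips back below threshold resets the
    persistence window; result must match an exhaustive frame-scan oracle."""
    events = [ScriptedEvent(position=5, time=10.0)]
    traj = scripted_trajectory(topo11, events, dt_frame=0.5, noise_sd=0.08, seed=3)
    persistence = 3
    rec = detect_events(traj, topo11, params, persistence=persistence)

    pairs = topo11.monitored_pairs()
    a = np.array([p[0] for p in pairs]); b = np.array([p[1] for p in pairs])
    thr = np.array([params.dissociation_threshold(c) for _, _, c in pairs])
    d = np.linalg.norm(traj.positions[:, a] - traj.positions[:, b], axis=2)
    rel = traj.positions[:, a] - traj.positions[:, b]
    vr = np.einsum("fmd,fmd->fm", traj.velocities[:, a] - traj.velocities[:, b], rel)
    open_now = (d > thr) & (vr > 0)
    for m in range(9):
        expected = np.nan
        run = 0
        for f in range(traj.n_frames):
            run = run + 1 if open_now[f, m] else 0
            if run >= persistence:
                expected = traj.times[f - persistence + 1]
                break
        if np.isnan(expected):
            assert np.isnan(rec.times[m])
        else:
            assert rec.times[m] == pytest.approx(expected)


# -------------------------------------------------- scalar melting observables
@pytest.mark.parametrize("times, expected", [
    ([0.0, 2.0, 5.0, 9.0, 1.0, 3.0, 4.0, 6.0, 7.0], 9.0),
    ([3.0, 7.0, 15.0, 5.0, 6.0, 8.0, 9.0, 10.0, 11.0], 12.0),  # offset invariance
])
def test_melting_duration(times, expected):
    assert melting_duration(make_record(times)) == expected


def test_melting_duration_degenerate_single_pair():
    rec = DissociationRecord(times=np.array([4.0]), positions=np.array([1]),
                             pair_class=["AT"])
    assert melting_duration(rec) == 0.0


def test_incomplete_record_raises():
    times = [0.0, 2.0, np.nan, 9.0, 1.0, 3.0, 4.0, 6.0, 7.0]
    rec = make_record(times)
    with pytest.raises(IncompleteMeltingError, match="position"):
        melting_duration(rec)
    with pytest.raises(IncompleteMeltingError):
        interval_series(rec)


def test_interval_series_examples():
    rec = make_record([0.0, 4.0, 6.0, 7.0, 9.0, 11.0, 13.0, 15.0, 17.0])
    out = interval_series(rec)
    assert np.allclose(out[:3], [4.0, 2.0, 1.0])
    assert len(out) == rec.n_pairs - 1
    # equally spaced events give a constant series
    rec2 = make_record(np.arange(9) * 2.0)
    assert np.allclose(interval_series(rec2), 2.0)


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(0.0, 1e4), min_size=2, max_size=30))
def test_interval_sum_telescopes_to_duration(times):
    n = len(times)
    rec = DissociationRecord(
        times=np.array(times),
        positions=np.arange(1, n + 1),
        pair_class=["AT"] * n,
    )
    assert np.sum(interval_series(rec)) == pytest.approx(melting_duration(rec), abs=1e-6)


# --------------------------------------------------------------- curve shapes
def test_order_curve_matches_brute_force_and_monotone():
    rng = np.random.default_rng(0)
    records = [make_record(rng.uniform(0, 100, 9)) for _ in range(12)]
    curve = order_curve(records)
    zeroed = np.stack([np.sort(r.times) - r.times.min() for r in records])
    assert np.allclose(curve["mean_time"], zeroed.mean(axis=0))
    assert (np.diff(zeroed, axis=1) >= 0).all()
    one = order_curve(records[:1])
    assert np.allclose(one["mean_time"], np.sort(records[0].times) - records[0].times.min())
    assert np.allclose(order_curve([records[0], records[0]])["sd_time"], 0.0)


def test_position_curve_reveals_opening_end():
    # strict one-end unzipping: monotone position curve
    uni = [make_record(np.arange(9) * 3.0 + r) for r in range(5)]
    curve = position_curve(uni, topo=None if False else _topo9())
    assert (np.diff(curve["mean_time"]) > 0).all()
    # symmetric two-end opening: V shape peaked in the middle
    vtimes = [0.0, 2.0, 4.0, 6.0, 8.0, 6.0, 4.0, 2.0, 0.1]
    sym = [make_record(vtimes) for _ in range(3)]
    vcurve = position_curve(sym, _topo9())
    assert vcurve["mean_time"].idxmax() == 4
    # brute-force mean oracle
    rng = np.random.default_rng(1)
    records = [make_record(rng.uniform(0, 50, 9)) for _ in range(7)]
    got = position_curve(records, _topo9())["mean_time"].to_numpy()
    want = np.stack([r.times - r.times.min() for r in records]).mean(axis=0)
    assert np.allclose(got, want)


def _topo9():
    return dm.build_duplex(dm.study_sequences()["11bp"])


# ------------------------------------------------------------- classification
def test_at_rich_end_of_study_duplex(topo11):
    # terminal A/T windows tie for this sequence; the nearest A-T pair sits
    # right at the 5' terminus, which breaks the tie
    assert at_rich_end(topo11, 3) == "5p"
    with pytest.raises(ValueError):
        at_rich_end(topo11, 5)


def test_classify_opening_windows(topo11):
    at_first = make_record([0.0, 1.0, 2.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0])
    assert classify_opening(at_first, topo11) == "AT_end"
    gc_first = make_record([10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 2.0, 0.0, 1.0])
    assert classify_opening(gc_first, topo11) == "GC_end"
    mixed = make_record([0.0, 2.0, 12.0, 13.0, 14.0, 15.0, 16.0, 17.0, 1.0])
    assert classify_opening(mixed, topo11) == "both"
    with pytest.raises(ValueError):
        classify_opening(at_first, topo11, k_window=5)


def test_opening_fractions_recount_oracle(topo11):
    rng = np.random.default_rng(2)
    records = [make_record(rng.uniform(0, 30, 9)) for _ in range(20)]
    frac = opening_fractions(records, topo11)
    labels = [classify_opening(r, topo11) for r in records]
    for key in ("AT_end", "GC_end", "both"):
        assert frac[key] == pytest.approx(labels.count(key) / len(labels))
    assert sum(frac.values()) == pytest.approx(1.0)
    # invariant to replica order
    shuffled = list(records)
    rng.shuffle(shuffled)
    assert opening_fractions(shuffled, topo11) == frac


# ------------------------------------------------------------------ summaries
def test_summarize_ensemble_identities(topo11):
    rng = np.random.default_rng(3)
    records = [make_record(np.sort(rng.uniform(0, 40, 9))) for _ in range(10)]
    records.append(make_record([0.0] + [np.nan] * 8))  # cap-hit replica
    summary = summarize_ensemble(records, topo11)
    assert summary.n_replicas == 11
    assert summary.n_complete == 10
    durations = [melting_duration(r) for r in records[:10]]
    assert summary.duration_mean == pytest.approx(np.mean(durations))
    # duration equals the last order-curve point; intervals sum to duration
    assert summary.order["mean_time"].iloc[-1] == pytest.approx(summary.duration_mean)
    assert summary.intervals["mean_dt"].sum() == pytest.approx(summary.duration_mean)
    assert sum(summary.opening.values()) == pytest.approx(1.0)


def test_records_to_frame_tidy(topo11):
    records = [make_record(np.arange(9.0)) for _ in range(2)]
    df = records_to_frame(records)
    assert isinstance(df, pd.DataFrame)
    assert len(df) == 18
    assert set(df.columns) == {"replica", "position", "pair_class", "time_ps"}
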