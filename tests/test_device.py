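import dataclasses

import numpy as np
import pytest

from fusionpace import (
    AnatomySpec,
    DeviceConfig,
    DeviceState,
    PatientParams,
    build_heart_graph,
    device_sensed_avi,
    fastest_arrival,
    intrinsic_sources,
    place_leads,
    schedule_mode,
    steady_state_map,
    syncav_offset_for_mode,
    syncav_step,
)
from fusionpace.device import BeatLog, BeatSchedule


def run_machine(config, avi_fn, n_beats, latency=0.0):
    state = DeviceState()
    beats = []
    for _ in range(n_beats):
        state, beat = syncav_step(state, config, avi_fn, atrial_sense_latency_ms=latency)
        beats.append(beat)
    return state, beats


# --- config validation ----------------------------------------------------

def test_offset_range_enforced():
    DeviceConfig(mode=4)  # offset 10, fine
    with pytest.raises(ValueError):
        DeviceConfig(mode=8, syncav_offset_ms=5.0)
    with pytest.raises(ValueError):
        DeviceConfig(mode=8, syncav_offset_ms=121.0)
    with pytest.raises(ValueError):
        DeviceConfig(mode=15)


def test_protocol_offsets():
    assert [syncav_offset_for_mode(m) for m in range(4, 15)] == [
        10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0, 110.0
    ]
    assert DeviceConfig(mode=8).offset_ms == 50.0  # protocol mode 8


# --- AVI measurement ------------------------------------------------------

def test_avi_is_rv_lead_arrival_minus_latency(heart, calibrated_patient):
    amap = fastest_arrival(
        heart,
        intrinsic_sources(heart, calibrated_patient),
        velocity_multiplier=calibrated_patient.velocity_multiplier,
    )
    expected = float(amap.times[heart.rv_lead]) - 30.0
    assert device_sensed_avi(heart, calibrated_patient) == pytest.approx(expected)
    # RV lead away from the breakout: AVI strictly exceeds PR - latency
    assert device_sensed_avi(heart, calibrated_patient) > 189.0 - 30.0


def test_avi_equals_pr_when_lead_is_breakout(chain_graph):
    patient = PatientParams(
        "T", pr_interval_ms=150.0, target_native_vat_ms=140.0,
        atrial_sense_latency_ms=0.0,
    )
    assert device_sensed_avi(chain_graph, patient) == pytest.approx(150.0)


def test_avi_increases_when_fast_layer_slows():
    patient = PatientParams("T", pr_interval_ms=189.0, target_native_vat_ms=181.6)
    fast = place_leads(build_heart_graph(AnatomySpec()))
    slow = place_leads(build_heart_graph(
        AnatomySpec(fast_layer_velocity_mm_per_ms=1.0)
    ))
    assert device_sensed_avi(slow, patient) > device_sensed_avi(fast, patient)


# --- state machine --------------------------------------------------------

def test_syncav_avd_is_avi_minus_offset():
    config = DeviceConfig(mode=8)  # offset 50
    state, beats = run_machine(config, lambda: 189.0, 4)
    assert [b.beat_type for b in beats[:3]] == ["sensed_intrinsic"] * 3
    assert state.last_measured_avi_ms == pytest.approx(189.0)
    assert beats[3].beat_type == "paced"
    assert beats[3].avd_applied_ms == pytest.approx(139.0)
    assert beats[3].firing_leads == ("rv", "lv")


def test_avd_clamped_at_device_floor():
    config = DeviceConfig(mode=14, syncav_offset_ms=120.0)
    _, beats = run_machine(config, lambda: 130.0, 4)
    assert beats[3].avd_applied_ms == pytest.approx(30.0)
    assert beats[3].clamped


def test_t_pace_includes_atrial_latency():
    config = DeviceConfig(mode=8)
    _, beats = run_machine(config, lambda: 189.0, 4, latency=30.0)
    assert beats[3].t_pace_ms == pytest.approx(30.0 + 139.0)


def test_measurement_windows_over_600_beats():
    """Windows at exactly beats {1-3, 257-259, 513-515}; AVD constant elsewhere."""
    config = DeviceConfig(mode=8)
    _, beats = run_machine(config, lambda: 200.0, 600)
    measured = {b.beat_index for b in beats if b.measured_avi_ms is not None}
    assert measured == {1, 2, 3, 257, 258, 259, 513, 514, 515}
    paced_avds = {b.avd_applied_ms for b in beats if b.beat_type == "paced"}
    assert paced_avds == {150.0}
    assert all(
        b.beat_type == "sensed_intrinsic"
        for b in beats
        if b.measured_avi_ms is not None
    )


def test_avd_tracks_avi_drift_exactly():
    """+d drift in AVI between cycles shifts the reprogrammed AVD by +d."""
    config = DeviceConfig(mode=8)
    values = iter([200.0] * 256 + [212.5] * 400)
    _, beats = run_machine(config, lambda: next(values), 600)
    by_index = {b.beat_index: b for b in beats}
    assert by_index[4].avd_applied_ms == pytest.approx(150.0)
    assert by_index[260].avd_applied_ms == pytest.approx(162.5)


def test_inhibition_when_pace_would_trail_intrinsic():
    config = DeviceConfig(mode=4)  # offset 10
    state = DeviceState(beat_counter=3, current_avd_ms=195.0, last_measured_avi_ms=205.0)
    new_state, beat = syncav_step(state, config, lambda: 190.0, 30.0)
    assert beat.beat_type == "sensed_intrinsic"  # AVD 195 >= AVI 190: inhibited
    _, paced = syncav_step(
        DeviceState(beat_counter=3, current_avd_ms=180.0, last_measured_avi_ms=205.0),
        config, lambda: 190.0, 30.0,
    )
    assert paced.beat_type == "paced"
    assert paced.t_pace_ms < 30.0 + 190.0  # never at/after intrinsic RV arrival


def test_syncav_step_rejects_non_syncav_mode():
    with pytest.raises(ValueError):
        syncav_step(DeviceState(), DeviceConfig(mode=3), lambda: 200.0)


def test_beat_log_contracts():
    log = BeatLog()
    log.append(BeatSchedule(beat_index=1, beat_type="sensed_intrinsic"))
    with pytest.raises(ValueError):
        log.append(BeatSchedule(beat_index=3, beat_type="sensed_intrinsic"))
    with pytest.raises(ValueError):
        BeatSchedule(beat_index=1, beat_type="paced")  # no firing leads


# --- schedule_mode and steady-state maps ----------------------------------

def test_mode1_all_sensed(heart, calibrated_patient):
    log = schedule_mode(heart, calibrated_patient, DeviceConfig(mode=1), 10)
    assert len(log) == 10
    assert all(b.beat_type == "sensed_intrinsic" for b in log)


def test_mode3_paces_both_leads_at_sensed_avd(heart, calibrated_patient):
    log = schedule_mode(heart, calibrated_patient, DeviceConfig(mode=3), 5)
    for b in log:
        assert b.beat_type == "paced"
        assert b.firing_leads == ("rv", "lv")
        assert b.avd_applied_ms == 120.0


def test_mode2_paces_rv_only(heart, calibrated_patient):
    log = schedule_mode(heart, calibrated_patient, DeviceConfig(mode=2), 3)
    assert all(b.firing_leads == ("rv",) for b in log)


def test_fixed_mode_inhibits_when_avi_short(chain_graph):
    # AVI = PR = 100 with zero latency; sensed AVD 120 >= AVI: inhibit
    patient = PatientParams(
        "T", pr_interval_ms=100.0, target_native_vat_ms=140.0,
        atrial_sense_latency_ms=0.0,
    )
    log = schedule_mode(chain_graph, patient, DeviceConfig(mode=3), 3)
    assert all(b.beat_type == "sensed_intrinsic" for b in log)


def test_steady_state_mode1_equals_pure_intrinsic(heart, calibrated_patient):
    amap = steady_state_map(heart, calibrated_patient, DeviceConfig(mode=1))
    pure = fastest_arrival(
        heart,
        intrinsic_sources(heart, calibrated_patient),
        velocity_multiplier=calibrated_patient.velocity_multiplier,
    )
    np.testing.assert_array_equal(amap.times, pure.times)


def test_steady_state_syncav_has_three_wavefronts(heart, calibrated_patient):
    amap = steady_state_map(heart, calibrated_patient, DeviceConfig(mode=8))
    kinds = sorted({s.kind for s in amap.sources})
    assert kinds == ["intrinsic", "lv_pace", "rv_pace"]
    assert len([s for s in amap.sources if s.kind == "intrinsic"]) == 3


def test_steady_state_invariant_to_extra_beats(heart, calibrated_patient):
    """The mapped beat is identical once one full re-measurement cycle passed."""
    config = DeviceConfig(mode=8, remeasure_cycle_beats=16)
    short = schedule_mode(heart, calibrated_patient, config, 20)
    long = schedule_mode(heart, calibrated_patient, config, 52)
    last_short = next(b for b in reversed(short.beats) if b.beat_type == "paced")
    last_long = next(b for b in reversed(long.beats) if b.beat_type == "paced")
    assert last_short.avd_applied_ms == last_long.avd_applied_ms
    assert last_short.t_pace_ms == last_long.t_pace_ms


def test_timing_not_mode_label_determines_map(heart, calibrated_patient):
    """A fusion mode whose AVD coincides with the nominal sensed AVD maps
    identically to simultaneous biventricular pacing."""
    avi = device_sensed_avi(heart, calibrated_patient)
    offset = avi - 120.0
    assert 10.0 <= offset <= 120.0
    config = DeviceConfig(mode=4, syncav_offset_ms=offset)
    a = steady_state_map(heart, calibrated_patient, config)
    b = steady_state_map(heart, calibrated_patient, DeviceConfig(mode=3))
    np.testing.assert_allclose(a.times, b.times, atol=1e-9)


def test_beat_log_export_columns(heart, calibrated_patient):
    log = schedule_mode(heart, calibrated_patient, DeviceConfig(mode=8), 6)
    frame = log.to_frame()
    assert list(frame.columns) == [
        "beat_index", "type", "leads", "avd_ms", "t_pace_ms", "measured_avi_ms",
        "clamped",
    ]
    assert list(frame["beat_index"]) == [1, 2, 3, 4, 5, 6]
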