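"""CRT device timing: fixed AV delays and the dynamic AV-delay algorithm.

The dynamic fusion-pacing algorithm (SyncAV-style negative AV hysteresis)
paces both ventricles at a delay derived from the device-measured intrinsic
atrioventricular interval (AVI) minus a programmed offset.  Every
``remeasure_cycle_beats`` (256 by default) the device extends the AV delay
for ``measure_window_beats`` (3) beats so they conduct intrinsically, measures
the AVI on each, and reprograms the paced AV delay to ``AVI - offset``
(clamped to a device floor).  The AVI is the interval from the atrial sensed
event to intrinsic activation at the RV lead — distinct from, and longer
than, the surface PR interval, because the RV lead sits away from the
right-bundle breakout.

All atrial events are sensed (sinus-rhythm cohort), so the sensed AV delay
governs the fixed-delay modes; the paced AV delay is retained in the config
for completeness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

import numpy as np
import pandas as pd

from .cohort import PatientParams
from .heart import HeartGraph
from .wavefront import ActivationMap, fastest_arrival, intrinsic_sources, paced_sources

__all__ = [
    "MODE_LABELS",
    "DeviceConfig",
    "DeviceState",
    "BeatSchedule",
    "BeatLog",
    "mode_label",
    "syncav_offset_for_mode",
    "device_sensed_avi",
    "syncav_step",
    "schedule_mode",
    "steady_state_map",
]

#: study protocol: mode number -> label. Modes 4-14 are fusion pacing with
#: offsets 10-110 ms in 10 ms steps.
MODE_LABELS = {
    1: "native",
    2: "rv_only",
    3: "biv",
    **{m: f"syncav_{10 * (m - 3)}" for m in range(4, 15)},
}


def mode_label(mode: int) -> str:
    if mode not in MODE_LABELS:
        raise ValueError(f"unknown mode {mode} (valid: 1..14)")
    return MODE_LABELS[mode]


def syncav_offset_for_mode(mode: int) -> float:
    """Programmed offset (ms) for fusion-pacing modes 4-14."""
    if not 4 <= mode <= 14:
        raise ValueError(f"mode {mode} is not a fusion-pacing mode (4..14)")
    return 10.0 * (mode - 3)


@dataclass(frozen=True)
class DeviceConfig:
    """Programmed device parameters for one study mode."""

    mode: int = 3
    syncav_offset_ms: Optional[float] = None
    paced_avd_ms: float = 170.0
    sensed_avd_ms: float = 120.0
    remeasure_cycle_beats: int = 256
    measure_window_beats: int = 3
    min_paced_avd_ms: float = 30.0
    #: AV-delay extension applied on measurement beats so they conduct
    avi_extension_ms: float = 100.0
    #: how the per-window AVI observations are summarized: mean|median|last
    avi_summary: str = "mean"

    def __post_init__(self):
        if self.mode not in MODE_LABELS:
            raise ValueError(f"unknown mode {self.mode} (valid: 1..14)")
        if self.is_syncav:
            off = self.offset_ms
            if not 10.0 <= off <= 120.0:
                raise ValueError(
                    f"syncav offset {off} ms outside the programmable 10-120 ms range"
                )
        if self.remeasure_cycle_beats <= self.measure_window_beats:
            raise ValueError("remeasure cycle must exceed the measurement window")
        if self.measure_window_beats < 1:
            raise ValueError("measure_window_beats must be >= 1")
        if self.avi_summary not in ("mean", "median", "last"):
            raise ValueError("avi_summary must be mean, median or last")

    @property
    def is_syncav(self) -> bool:
        return self.mode >= 4

    @property
    def offset_ms(self) -> float:
        """Effective offset: explicit override, else the protocol value."""
        if not self.is_syncav:
            raise ValueError("offset is defined only for fusion-pacing modes")
        if self.syncav_offset_ms is not None:
            return float(self.syncav_offset_ms)
        return syncav_offset_for_mode(self.mode)

    @property
    def label(self) -> str:
        return mode_label(self.mode)


@dataclass(frozen=True)
class DeviceState:
    """Dynamic-AV-delay state between beats."""

    beat_counter: int = 0
    current_avd_ms: Optional[float] = None
    last_measured_avi_ms: Optional[float] = None
    in_measurement_window: bool = False
    pending_measurements: tuple[float, ...] = ()


@dataclass(frozen=True)
class BeatSchedule:
    """What the device did on one beat."""

    beat_index: int
    beat_type: str                      # "sensed_intrinsic" | "paced"
    firing_leads: tuple[str, ...] = ()  # subset of ("rv", "lv")
    t_pace_ms: Optional[float] = None   # ms after atrial onset
    avd_applied_ms: Optional[float] = None
    conduction_intact: bool = True
    clamped: bool = False
    measured_avi_ms: Optional[float] = None

    def __post_init__(self):
        if self.beat_type == "paced" and not self.firing_leads:
            raise ValueError("paced beats must fire at least one lead")


class BeatLog:
    """Ordered per-beat trace of a schedule run."""

    def __init__(self, beats: Optional[list[BeatSchedule]] = None):
        self.beats: list[BeatSchedule] = list(beats or [])

    def append(self, beat: BeatSchedule) -> None:
        if self.beats and beat.beat_index != self.beats[-1].beat_index + 1:
            raise ValueError("beat indices must increase strictly from 1")
        if not self.beats and beat.beat_index != 1:
            raise ValueError("beat indices must start at 1")
        self.beats.append(beat)

    def __len__(self) -> int:
        return len(self.beats)

    def __iter__(self) -> Iterator[BeatSchedule]:
        return iter(self.beats)

    def __getitem__(self, i):
        return self.beats[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "beat_index": b.beat_index,
                    "type": b.beat_type,
                    "leads": "+".join(b.firing_leads),
                    "avd_ms": b.avd_applied_ms,
                    "t_pace_ms": b.t_pace_ms,
                    "measured_avi_ms": b.measured_avi_ms,
                    "clamped": b.clamped,
                }
                for b in self.beats
            ]
        )


def device_sensed_avi(graph: HeartGraph, patient: PatientParams) -> float:
    """Intrinsic AVI as the device measures it.

    Atrial sense to intrinsic ventricular activation at the RV lead:
    ``t_intrinsic(rv_lead) - atrial_sense_latency``.  Exceeds
    ``PR - latency`` whenever the RV lead is not itself a breakout site.
    """
    if graph.rv_lead is None:
        raise ValueError("graph has no RV lead; call place_leads first")
    m = patient.velocity_multiplier if patient.velocity_multiplier is not None else 1.0
    amap = fastest_arrival(
        graph, intrinsic_sources(graph, patient), velocity_multiplier=m
    )
    return float(amap.times[graph.rv_lead]) - patient.atrial_sense_latency_ms


def _summarize(values: tuple[float, ...], how: str) -> float:
    if how == "mean":
        return float(np.mean(values))
    if how == "median":
        return float(np.median(values))
    return float(values[-1])


def syncav_step(
    state: DeviceState,
    config: DeviceConfig,
    observed_avi_fn: Callable[[], float],
    atrial_sense_latency_ms: float = 0.0,
) -> tuple[DeviceState, BeatSchedule]:
    """Advance the dynamic-AV-delay state machine by one beat.

    Beats at positions 1..measure_window_beats of each remeasure cycle are
    measurement beats: the AV delay is extended beyond the expected AVI so
    the beat conducts intrinsically and an AVI observation is recorded; after
    the last one the paced AV delay is reprogrammed to the summarized AVI
    minus the programmed offset, clamped below at the device floor.  All
    other beats pace both ventricles simultaneously at the current AV delay,
    unless intrinsic activation would reach the RV lead first, in which case
    the beat is inhibited (sensed).
    """
    if not config.is_syncav:
        raise ValueError("syncav_step requires a fusion-pacing mode (4..14)")
    idx = state.beat_counter + 1
    pos = (idx - 1) % config.remeasure_cycle_beats + 1
    avi_now = float(observed_avi_fn())

    if pos <= config.measure_window_beats:
        # measurement beat: extend AVD so intrinsic conduction wins
        reference = (
            state.last_measured_avi_ms
            if state.last_measured_avi_ms is not None
            else config.sensed_avd_ms
        )
        extended_avd = max(reference, avi_now) + config.avi_extension_ms
        pending = state.pending_measurements + (avi_now,)
        if pos == config.measure_window_beats:
            summary = _summarize(pending, config.avi_summary)
            raw_avd = summary - config.offset_ms
            new_avd = max(config.min_paced_avd_ms, raw_avd)
            new_state = DeviceState(
                beat_counter=idx,
                current_avd_ms=new_avd,
                last_measured_avi_ms=summary,
                in_measurement_window=False,
                pending_measurements=(),
            )
        else:
            new_state = dataclasses.replace(
                state,
                beat_counter=idx,
                in_measurement_window=True,
                pending_measurements=pending,
            )
        beat = BeatSchedule(
            beat_index=idx,
            beat_type="sensed_intrinsic",
            avd_applied_ms=extended_avd,
            measured_avi_ms=avi_now,
        )
        return new_state, beat

    avd = state.current_avd_ms
    if avd is None:  # unreachable under normal cycling (window opens the cycle)
        raise RuntimeError("pacing requested before any AVI measurement")
    clamped = bool(
        avd == config.min_paced_avd_ms
        and state.last_measured_avi_ms is not None
        and state.last_measured_avi_ms - config.offset_ms < config.min_paced_avd_ms
    )
    if avd >= avi_now:
        # pace would land after intrinsic RV activation: inhibit
        beat = BeatSchedule(
            beat_index=idx, beat_type="sensed_intrinsic", avd_applied_ms=avd
        )
    else:
        beat = BeatSchedule(
            beat_index=idx,
            beat_type="paced",
            firing_leads=("rv", "lv"),
            t_pace_ms=atrial_sense_latency_ms + avd,
            avd_applied_ms=avd,
            clamped=clamped,
        )
    return dataclasses.replace(state, beat_counter=idx, in_measurement_window=False), beat


def schedule_mode(
    graph: HeartGraph,
    patient: PatientParams,
    config: DeviceConfig,
    n_beats: int,
    observed_avi_fn: Optional[Callable[[], float]] = None,
) -> BeatLog:
    """Run one study mode for ``n_beats`` and return the per-beat trace.

    Mode 1: intrinsic conduction, all beats sensed.  Mode 2: RV-only pacing
    at the sensed AV delay.  Mode 3: simultaneous biventricular pacing at the
    sensed AV delay.  Modes 4-14: the dynamic-AV-delay loop with the
    protocol offset.  ``observed_avi_fn`` may inject AVI drift for testing;
    by default the device re-measures the (stationary) model AVI each window.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    latency = patient.atrial_sense_latency_ms
    log = BeatLog()

    if config.mode == 1:
        for i in range(1, n_beats + 1):
            log.append(BeatSchedule(beat_index=i, beat_type="sensed_intrinsic"))
        return log

    if config.mode in (2, 3):
        leads = ("rv",) if config.mode == 2 else ("rv", "lv")
        avi = device_sensed_avi(graph, patient)
        for i in range(1, n_beats + 1):
            if config.sensed_avd_ms >= avi:  # intrinsic beats the pace: inhibit
                log.append(
                    BeatSchedule(
                        beat_index=i,
                        beat_type="sensed_intrinsic",
                        avd_applied_ms=config.sensed_avd_ms,
                    )
                )
            else:
                log.append(
                    BeatSchedule(
                        beat_index=i,
                        beat_type="paced",
                        firing_leads=leads,
                        t_pace_ms=latency + config.sensed_avd_ms,
                        avd_applied_ms=config.sensed_avd_ms,
                    )
                )
        return log

    if observed_avi_fn is None:
        avi_value = device_sensed_avi(graph, patient)
        observed_avi_fn = lambda: avi_value  # noqa: E731 - stationary model AVI
    state = DeviceState()
    for _ in range(n_beats):
        state, beat = syncav_step(
            state, config, observed_avi_fn, atrial_sense_latency_ms=latency
        )
        log.append(beat)
    return log


def steady_state_map(
    graph: HeartGraph, patient: PatientParams, config: DeviceConfig
) -> ActivationMap:
    """Activation map of the representative steady-state beat of a mode.

    Runs the schedule past one full re-measurement cycle and maps the last
    non-measurement beat: its paced sources (if any) plus the intrinsic
    breakout sources whenever AV conduction is intact.
    """
    n_beats = config.remeasure_cycle_beats + config.measure_window_beats + 1
    log = schedule_mode(graph, patient, config, n_beats)
    beat = next(
        b for b in reversed(log.beats) if b.measured_avi_ms is None
    )
    m = patient.velocity_multiplier if patient.velocity_multiplier is not None else 1.0
    if beat.beat_type == "paced":
        sources = paced_sources(graph, patient, beat)
    else:
        sources = intrinsic_sources(graph, patient)
    return fastest_arrival(
        graph,
        sources,
        velocity_multiplier=m,
        patient_id=patient.patient_id,
        mode=config.label,
    )
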