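"""Takeover-onset detection and windowed feature extraction.

Takeover onset is operationalized the way reaction times are commonly scored
in driving-simulator work: the earliest post-TOR moment at which the driver
turns the steering wheel more than 2 degrees away from its position at the
TOR, or presses the brake pedal more than 10% (the same threshold is applied
to the accelerator pedal, which is not covered by the convention and is a
configurable package default).

Analysis windows start at 0, 2, 4, ..., 12 s after takeover onset and are
half-open [start, start + length); with a 2 s length the seven windows tile
the first 14 s without overlap, with a 5 s length they overlap.

Per window the seven variables are:

====================  =====================================================
winding               sample SD of the steering angle (deg, n-1 denominator)
speed                 mean speed (km/h)
deceleration          mean braking deceleration (m/s^2, positive), over
                      samples with negative longitudinal acceleration while
                      the brake pedal is pressed; missing when none
eoff                  fraction of gaze samples directed off the road
pd                    mean pupil diameter after subtracting the value at
                      takeover onset (mm)
hr                    mean heart rate over unmasked samples (bpm)
sc                    mean phasic skin conductance (uS)
====================  =====================================================

A window with no eligible samples for a variable is missing, never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eda import EdaDecomposition, decompose_recording
from .errors import ConfigError, SchemaError
from .recording import MultiChannelRecording
from .synthetic import VARIABLES

logger = logging.getLogger("tostab.features")

#: stable column order of the long-form feature table
FEATURE_COLUMNS = (
    "event_id", "driver_id", "variable", "window_start_s", "window_len_s",
    "value", "is_missing",
)


@dataclass(frozen=True)
class TakeoverOnset:
    """Detected takeover onset for one event.

    ``time`` is seconds after the TOR; exactly one of ``time``/``missed`` is
    meaningful.  ``abs_time`` is the onset on the recording clock.
    """

    event_id: str
    time: float | None
    abs_time: float | None
    action: str | None          # "steering" | "brake" | "accelerator"
    missed: bool = False


@dataclass(frozen=True)
class WindowGrid:
    """Half-open analysis windows [start, start + length)."""

    length: float
    step: float = 2.0
    horizon: float = 12.0

    @property
    def starts(self) -> np.ndarray:
        return np.arange(0.0, self.horizon + 0.5 * self.step, self.step)

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def overlapping(self) -> bool:
        return self.length > self.step


def build_window_grid(length: float, step: float = 2.0,
                      horizon: float = 12.0) -> WindowGrid:
    if length <= 0 or step <= 0:
        raise ConfigError("window length and step must be > 0")
    if horizon < 0:
        raise ConfigError("horizon must be >= 0")
    return WindowGrid(length=float(length), step=float(step), horizon=float(horizon))


def detect_takeover_onset(
    recording: MultiChannelRecording,
    tor_time: float | None = None,
    steering_threshold: float = 2.0,
    brake_threshold: float = 10.0,
    accel_threshold: float = 10.0,
) -> TakeoverOnset:
    """Earliest threshold crossing of steering, brake or accelerator after
    the TOR; ``missed`` when nothing crosses before automation availability
    ends."""
    tor = recording.tor_time if tor_time is None else tor_time
    end = recording.availability_end
    for name in ("steering_deg", "brake_pct", "accpedal_pct"):
        if name not in recording.channels:
            raise ConfigError(f"onset detection requires channel '{name}'")

    candidates: list[tuple[float, str]] = []

    steer = recording["steering_deg"]
    t, v = steer.present()
    before = t <= tor
    if before.any():
        ref = v[before][-1]
        sel = (t > tor) & (t <= end) & (np.abs(v - ref) > steering_threshold)
        if sel.any():
            candidates.append((float(t[sel][0]), "steering"))

    for name, thr, label in (
        ("brake_pct", brake_threshold, "brake"),
        ("accpedal_pct", accel_threshold, "accelerator"),
    ):
        t, v = recording[name].present()
        sel = (t > tor) & (t <= end) & (v > thr)
        if sel.any():
            candidates.append((float(t[sel][0]), label))

    if not candidates:
        return TakeoverOnset(recording.event_id, None, None, None, missed=True)
    abs_time, action = min(candidates)
    return TakeoverOnset(recording.event_id, abs_time - tor, abs_time, action)


def _window_slice(ch_time: np.ndarray, origin: float, start: float,
                  length: float) -> np.ndarray:
    """Boolean mask of samples in [start, start+length) seconds after origin."""
    rel = ch_time - origin
    return (rel >= start) & (rel < start + length)


def compute_window_features(
    recording: MultiChannelRecording,
    onset: TakeoverOnset,
    grid: WindowGrid,
    phasic: EdaDecomposition | None = None,
    variables: tuple[str, ...] = VARIABLES,
    driver_id: str = "",
    pd_baseline: float | None = None,
) -> pd.DataFrame:
    """Long-form window-feature table for one takeover attempt.

    The time base is re-anchored so t = 0 at the detected onset.  ``phasic``
    is the decomposition of the attempt's full GSR record (run once per
    record, not per window, so the tonic model has context); when omitted it
    is computed here.  ``pd_baseline`` overrides the per-attempt pupil
    baseline (first unmasked sample at or after onset) to support per-driver
    anchoring.
    """
    if onset.missed:
        raise ConfigError(f"event {onset.event_id}: missed takeover has no features")
    unknown = set(variables) - set(VARIABLES)
    if unknown:
        raise ConfigError(f"unknown variables {sorted(unknown)}")
    origin = onset.abs_time
    rows: list[tuple] = []

    def add(variable: str, start: float, value: float) -> None:
        missing = not np.isfinite(value)
        rows.append((recording.event_id, driver_id, variable, start,
                     grid.length, np.nan if missing else value, missing))

    need = {v: (v in variables) for v in VARIABLES}

    if need["pd"]:
        t_pd, v_pd = recording["pd_mm"].present()
        if pd_baseline is None:
            after = t_pd >= origin
            pd_base = float(v_pd[after][0]) if after.any() else np.nan
        else:
            pd_base = pd_baseline
    if need["sc"] and phasic is None:
        phasic = decompose_recording(recording["gsr_us"])

    for start in grid.starts:
        if need["winding"]:
            t, v = recording["steering_deg"].present()
            sel = _window_slice(t, origin, start, grid.length)
            add("winding", start,
                float(np.std(v[sel], ddof=1)) if sel.sum() >= 2 else np.nan)
        if need["speed"]:
            t, v = recording["speed_kmh"].present()
            sel = _window_slice(t, origin, start, grid.length)
            add("speed", start, float(v[sel].mean()) if sel.any() else np.nan)
        if need["deceleration"]:
            t, a = recording["accel_ms2"].present()
            tb, b = recording["brake_pct"].present()
            brake = np.interp(t, tb, b) if len(tb) != len(t) else b
            sel = _window_slice(t, origin, start, grid.length) & (a < 0) & (brake > 0)
            add("deceleration", start, float(-a[sel].mean()) if sel.any() else np.nan)
        if need["eoff"]:
            t, g = recording["gaze_onroad"].present()
            sel = _window_slice(t, origin, start, grid.length)
            add("eoff", start, float(1.0 - g[sel].mean()) if sel.any() else np.nan)
        if need["pd"]:
            sel = _window_slice(t_pd, origin, start, grid.length)
            add("pd", start,
                float((v_pd[sel] - pd_base).mean()) if sel.any() else np.nan)
        if need["hr"]:
            t, v = recording["hr_bpm"].present()
            sel = _window_slice(t, origin, start, grid.length)
            add("hr", start, float(v[sel].mean()) if sel.any() else np.nan)
        if need["sc"]:
            rel_start = origin + start
            val = phasic.window_mean_phasic(rel_start, rel_start + grid.length)
            add("sc", start, val)

    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def extract_features(
    recordings,
    events,
    grid: WindowGrid,
    variables: tuple[str, ...] = VARIABLES,
    decompositions: dict[str, EdaDecomposition] | None = None,
) -> pd.DataFrame:
    """Feature table over many events; missed takeovers are excluded with a
    logged reason."""
    tables = []
    n_missed = 0
    for event, rec in zip(events, recordings):
        onset = detect_takeover_onset(rec)
        if onset.missed:
            n_missed += 1
            logger.info("event %s excluded: missed takeover", rec.event_id)
            continue
        phasic = (decompositions or {}).get(rec.event_id)
        driver_id = f"s{event.study}-d{event.driver:03d}"
        tables.append(
            compute_window_features(rec, onset, grid, phasic=phasic,
                                    variables=variables, driver_id=driver_id)
        )
    if n_missed:
        logger.info("%d of %d events excluded as missed takeovers",
                    n_missed, len(list(events)))
    if not tables:
        return pd.DataFrame(columns=list(FEATURE_COLUMNS))
    return pd.concat(tables, ignore_index=True)
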