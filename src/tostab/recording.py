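"""In-memory containers for takeover episodes.

Time convention: analysis timestamps are seconds relative to takeover (TO)
onset, t = 0 at the moment the driver starts driving manually.  Raw
recordings produced by the generator use the same clock; the TOR time and the
automation-availability end are carried in the recording metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, SchemaError

#: Mandatory channel set for one takeover episode.
CHANNEL_NAMES = (
    "steering_deg",
    "speed_kmh",
    "accel_ms2",
    "brake_pct",
    "accpedal_pct",
    "gaze_onroad",
    "pd_mm",
    "hr_bpm",
    "gsr_us",
)


@dataclass
class Channel:
    """One uniformly or non-uniformly sampled signal.

    ``missing`` marks samples whose value is unavailable; masked values are
    kept in place (never dropped) so sample counts are preserved.
    """

    time: np.ndarray
    values: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.time.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        if not (self.time.shape == self.values.shape == self.missing.shape):
            raise SchemaError("channel time/values/missing must have equal length")
        if self.time.size > 1:
            bad = np.flatnonzero(np.diff(self.time) <= 0)
            if bad.size:
                raise DataError(
                    f"non-monotone timestamps (first offending row {int(bad[0]) + 1})"
                )

    def __len__(self) -> int:
        return int(self.time.size)

    def present(self) -> tuple[np.ndarray, np.ndarray]:
        """Timestamps and values of the unmasked samples."""
        keep = ~self.missing
        return self.time[keep], self.values[keep]

    def __eq__(self, other) -> bool:  # value equality incl. masks
        if not isinstance(other, Channel):
            return NotImplemented
        return (
            np.array_equal(self.time, other.time)
            and np.array_equal(self.values, other.values, equal_nan=True)
            and np.array_equal(self.missing, other.missing)
        )


@dataclass
class TakeoverEvent:
    """Identity and event-log entries of one takeover attempt."""

    event_id: str
    study: int
    driver: int
    trial: int
    index: int          # takeover number within the trial (0-based)
    tor_time: float     # s, relative to TO onset (negative: TOR precedes TO)
    availability_end: float  # s, tor_time + TOR lead time


@dataclass
class MultiChannelRecording:
    """Time-aligned driving and physiological channels for one episode."""

    event_id: str
    tor_time: float
    availability_end: float
    channels: dict[str, Channel] = field(default_factory=dict)

    def validate(self, required: tuple[str, ...] = CHANNEL_NAMES) -> None:
        for name in required:
            if name not in self.channels:
                raise SchemaError(f"mandatory channel '{name}' is missing")
        for name, ch in self.channels.items():
            vals = ch.values[~ch.missing]
            if name in ("brake_pct", "accpedal_pct") and vals.size:
                if vals.min() < 0 or vals.max() > 100:
                    raise DataError(f"{name} outside [0, 100]")
            if name == "gaze_onroad" and vals.size:
                if not np.isin(vals, (0.0, 1.0)).all():
                    raise DataError("gaze_onroad must be binary")
            if name == "gsr_us" and vals.size and vals.min() < 0:
                raise DataError("gsr_us must be non-negative")

    def __getitem__(self, name: str) -> Channel:
        return self.channels[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, MultiChannelRecording):
            return NotImplemented
        return (
            self.event_id == other.event_id
            and self.tor_time == other.tor_time
            and self.availability_end == other.availability_end
            and set(self.channels) == set(other.channels)
            and all(self.channels[k] == other.channels[k] for k in self.channels)
        )
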