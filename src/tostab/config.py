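"""Study design and signal-model configuration.

The default study design mirrors two driving-simulator experiments run on the
same rig: study 1 with 30 drivers x 4 trials x 4 takeovers (480 takeover
attempts) and study 2 with 28 drivers x 2 trials x 4 takeovers (224 attempts),
704 attempts in total.  The takeover request (TOR) precedes the end of
automation availability by 5 s; eye tracking runs at 50 Hz, skin conductance
at 4 Hz and heart rate at 1 Hz.  Driving channels are logged at 50 Hz (the
logging rate is a package default, aligned with the eye tracker).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .errors import ConfigError


@dataclass(frozen=True)
class StudyBlock:
    """One experiment: every driver completes ``n_trials`` trials with
    ``n_takeovers`` takeover attempts each."""

    n_drivers: int
    n_trials: int
    n_takeovers: int

    def n_events(self) -> int:
        return self.n_drivers * self.n_trials * self.n_takeovers


@dataclass(frozen=True)
class StudyConfig:
    """Design of the synthetic data collection.

    Times are in seconds, rates in Hz.  ``episode_duration`` is the recorded
    time after takeover onset; it must cover the last analysis window
    (start 12 s + length 5 s = 17 s).
    """

    studies: tuple[StudyBlock, ...] = (StudyBlock(30, 4, 4), StudyBlock(28, 2, 4))
    tor_lead_time: float = 5.0
    rate_drive: float = 50.0
    rate_eye: float = 50.0
    rate_gsr: float = 4.0
    rate_hr: float = 1.0
    episode_duration: float = 20.0
    pre_tor_duration: float = 5.0
    seed: int = 0

    def n_events(self) -> int:
        return sum(s.n_events() for s in self.studies)

    def validate(self) -> None:
        for s in self.studies:
            if min(s.n_drivers, s.n_trials, s.n_takeovers) < 0:
                raise ConfigError("study counts must be non-negative")
        if self.tor_lead_time <= 0:
            raise ConfigError("tor_lead_time must be > 0")
        for name in ("rate_drive", "rate_eye", "rate_gsr", "rate_hr"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.episode_duration < 17.0:
            raise ConfigError(
                "episode_duration must be >= 17 s to cover the 5 s window starting at 12 s"
            )
        if self.pre_tor_duration < 0:
            raise ConfigError("pre_tor_duration must be >= 0")


def default_study_config() -> StudyConfig:
    """The two-study design: 480 + 224 = 704 takeover attempts."""
    cfg = StudyConfig()
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Signal-model parameters.
#
# The source studies report no numeric signal magnitudes, so the defaults
# below are plausible values for an urban scenario at a 50 km/h limit, chosen
# once by a forward power calculation (see docs/methods.md) so that the
# default dataset reproduces the qualitative stabilization ordering:
# deceleration / eyes-off-road early, pupil diameter mid, winding / speed at
# 8-10 s, heart rate late, phasic skin conductance not stabilized within the
# analysis horizon.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteeringParams:
    """Steering angle is a zero-mean coloured-noise process whose standard
    deviation decays from ``base_sd + excursion_sd`` at takeover to
    ``base_sd``; winding (the windowed SD) is defined on this SD profile."""

    base_sd: float = 1.0          # deg, settled manual steering variability
    excursion_sd: float = 5.0     # deg, extra variability right after takeover
    tau: float = 1.74             # s, decay time constant of the SD profile
    noise_corr_time: float = 0.3  # s, correlation time of the angle process
    pre_to_sd: float = 0.3        # deg, automation keeps the wheel nearly still


@dataclass(frozen=True)
class SpeedParams:
    """Speed dips under braking and recovers toward the baseline.

    Most attempts brake briefly (duration ``brief_min + Exp(brief_mean)``
    capped at ``brief_max``) and then accelerate back with time constant
    ``tau_recover``.  A fraction ``long_braker_prob`` of attempts keeps a
    light foot on the brake through the whole horizon (duration
    ``long_min + Exp(long_mean)``); these attempts supply deceleration data in
    the late windows and do not recover speed, emulating the minority of
    drivers who decelerate gradually toward the hazard.
    """

    baseline: float = 50.0        # km/h
    baseline_sd: float = 2.0      # km/h, between-attempt variation
    dip_depth: float = 6.0        # km/h, asymptotic speed loss while braking
    tau_dip: float = 0.5          # s
    tau_recover: float = 1.2      # s
    noise_sd: float = 1.5         # km/h
    noise_corr_time: float = 2.0  # s, vehicle inertia
    accel_noise_sd: float = 0.3   # m/s^2, white noise on the accelerometer
    long_braker_prob: float = 0.12
    brief_min: float = 1.0        # s
    brief_mean: float = 1.2       # s
    brief_max: float = 5.0        # s
    long_min: float = 14.0        # s
    long_mean: float = 3.0        # s
    brake_floor: float = 15.0     # %, pedal position at steady braking
    brake_peak: float = 60.0      # %, extra pedal travel at brake onset


@dataclass(frozen=True)
class GazeParams:
    """Binary on-road gaze; the off-road probability relaxes exponentially
    from ``p_off_asymptote + p_off_excursion`` at takeover."""

    p_off_pre: float = 0.85       # secondary task before the takeover
    p_off_asymptote: float = 0.12
    p_off_excursion: float = 0.33
    tau: float = 0.45             # s


@dataclass(frozen=True)
class PupilParams:
    """Pupil diameter: step increase at takeover with exponential decay."""

    baseline: float = 3.5         # mm
    baseline_sd: float = 0.3      # mm, between-attempt variation
    excursion: float = 1.0        # mm
    tau: float = 1.0              # s
    noise_sd: float = 0.33        # mm, per 50 Hz sample


@dataclass(frozen=True)
class HeartRateParams:
    """Heart rate at 1 Hz with i.i.d. dropout emulating wristband motion
    artifacts around the takeover."""

    baseline: float = 76.0        # bpm
    baseline_sd: float = 8.0      # bpm, between-attempt variation
    excursion: float = 12.0       # bpm
    tau: float = 8.0              # s, slow autonomic recovery
    noise_sd: float = 3.0         # bpm
    missing_prob: float = 0.35


@dataclass(frozen=True)
class ScParams:
    """Skin conductance: tonic level + drift plus a Poisson train of skin
    conductance responses (SCRs) whose rate decays slowly after takeover;
    each SCR is a biexponential (Bateman) kernel scaled by a lognormal
    amplitude."""

    tonic_level: float = 2.0      # uS
    tonic_level_sd: float = 0.5   # uS, between-attempt variation
    tonic_drift: float = 0.01     # uS/s
    scr_rate_base: float = 0.05   # events/s, settled
    scr_rate_excursion: float = 0.8   # events/s, extra rate at takeover
    scr_rate_tau: float = 10.0    # s, arousal outlasts the analysis horizon
    scr_amp_mean: float = 0.35    # uS, median SCR peak amplitude
    scr_amp_sigma: float = 0.4    # lognormal sigma of SCR amplitudes
    tau_rise: float = 0.7         # s, SCR kernel rise
    tau_decay: float = 2.0        # s, SCR kernel decay
    noise_sd: float = 0.01        # uS


@dataclass(frozen=True)
class SignalParams:
    """All per-variable dynamics plus attempt-level behaviour.

    ``amp_jitter_rel`` is the lognormal sigma of a per-attempt multiplicative
    jitter applied to the post-takeover excursion amplitudes (individual
    response magnitude differences).  Reaction times (TOR to takeover onset)
    are lognormal, truncated below the TOR lead time so that every attempt
    succeeds unless ``missed_prob`` > 0.
    """

    steering: SteeringParams = field(default_factory=SteeringParams)
    speed: SpeedParams = field(default_factory=SpeedParams)
    gaze: GazeParams = field(default_factory=GazeParams)
    pupil: PupilParams = field(default_factory=PupilParams)
    heart_rate: HeartRateParams = field(default_factory=HeartRateParams)
    skin_conductance: ScParams = field(default_factory=ScParams)
    amp_jitter_rel: float = 0.2
    reaction_time_median: float = 1.5   # s
    reaction_time_sigma: float = 0.35   # lognormal sigma
    missed_prob: float = 0.0

    def validate(self) -> None:
        st, sp, gz, pd_, hr, sc = (
            self.steering, self.speed, self.gaze, self.pupil,
            self.heart_rate, self.skin_conductance,
        )
        taus = [st.tau, sp.tau_dip, sp.tau_recover, gz.tau, pd_.tau, hr.tau,
                sc.scr_rate_tau]
        if any(t < 0 for t in taus):
            raise ConfigError("decay time constants must be >= 0")
        sds = [st.base_sd, st.excursion_sd, st.pre_to_sd, sp.noise_sd,
               sp.accel_noise_sd, pd_.noise_sd, hr.noise_sd, sc.noise_sd]
        if any(s < 0 for s in sds):
            raise ConfigError("noise standard deviations must be >= 0")
        probs = [gz.p_off_pre, gz.p_off_asymptote,
                 gz.p_off_asymptote + gz.p_off_excursion,
                 hr.missing_prob, sp.long_braker_prob, self.missed_prob]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if sc.tonic_level < 0 or sc.scr_rate_base < 0 or sc.scr_rate_excursion < 0:
            raise ConfigError("skin conductance levels and rates must be >= 0")
        if not (1.0 <= pd_.baseline <= 9.0):
            raise ConfigError("pupil baseline must be in the plausible 1-9 mm range")
        if not (0 < sc.tau_rise < sc.tau_decay):
            raise ConfigError("SCR kernel requires 0 < tau_rise < tau_decay")


def default_signal_params() -> SignalParams:
    params = SignalParams()
    params.validate()
    return params


def _update_dataclass(obj, updates: dict, path: str):
    """Recursively apply a mapping onto a (frozen) dataclass tree."""
    if not dataclasses.is_dataclass(obj):
        raise ConfigError(f"'{path}' does not accept a table")
    names = {f.name for f in dataclasses.fields(obj)}
    changes = {}
    for key, value in updates.items():
        if key not in names:
            raise ConfigError(f"unknown config key '{path}.{key}'")
        current = getattr(obj, key)
        if isinstance(value, dict):
            changes[key] = _update_dataclass(current, value, f"{path}.{key}")
        elif key == "studies":
            changes[key] = tuple(
                StudyBlock(int(b["n_drivers"]), int(b["n_trials"]), int(b["n_takeovers"]))
                for b in value
            )
        else:
            changes[key] = type(current)(value) if current is not None else value
    return dataclasses.replace(obj, **changes)
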