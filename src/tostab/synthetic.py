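"""Synthetic takeover-episode generator with known ground truth.

The raw recordings of the two source studies are not publicly deposited, so
this module emulates their design: 704 takeover attempts (480 + 224), a 5 s
TOR lead time, eye tracking at 50 Hz, skin conductance at 4 Hz, heart rate at
1 Hz with dropout, and per-variable post-takeover decay dynamics whose
stabilization times are known analytically from the noise-free mean profiles.

Per-event randomness is drawn from independent substreams keyed by
(study, driver, trial, takeover index), so datasets are reproducible under
partial regeneration and bitwise identical for identical seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import SignalParams, StudyConfig, default_study_config
from .errors import ConfigError
from .recording import Channel, MultiChannelRecording, TakeoverEvent

#: Canonical names of the seven variables of interest.
VARIABLES = ("winding", "speed", "deceleration", "eoff", "pd", "hr", "sc")


# ---------------------------------------------------------------------------
# latent per-attempt behaviour
# ---------------------------------------------------------------------------


@dataclass
class EventLatents:
    """Per-attempt draws that shape the deterministic mean profiles."""

    missed: bool
    reaction_time: float     # s, TOR to takeover onset
    long_braker: bool
    brake_duration: float    # s
    jitter_steering: float   # multiplicative excursion jitters
    jitter_speed: float
    jitter_pd: float
    jitter_hr: float
    speed_baseline: float
    pd_baseline: float
    hr_baseline: float
    sc_tonic_level: float


def neutral_latents(params: SignalParams, lead_time: float = 5.0) -> EventLatents:
    """Latents with all jitters at 1 and baselines at their central values."""
    sp = params.speed
    return EventLatents(
        missed=False,
        reaction_time=min(params.reaction_time_median, lead_time - 0.3),
        long_braker=False,
        brake_duration=sp.brief_min + sp.brief_mean,
        jitter_steering=1.0,
        jitter_speed=1.0,
        jitter_pd=1.0,
        jitter_hr=1.0,
        speed_baseline=sp.baseline,
        pd_baseline=params.pupil.baseline,
        hr_baseline=params.heart_rate.baseline,
        sc_tonic_level=params.skin_conductance.tonic_level,
    )


def draw_event_latents(
    params: SignalParams, rng: np.random.Generator, lead_time: float = 5.0
) -> EventLatents:
    sp = params.speed
    missed = bool(rng.random() < params.missed_prob)
    rt = params.reaction_time_median * np.exp(
        params.reaction_time_sigma * rng.standard_normal()
    )
    rt = float(np.clip(rt, 0.3, lead_time - 0.3))
    long_braker = bool(rng.random() < sp.long_braker_prob)
    if long_braker:
        duration = sp.long_min + rng.exponential(sp.long_mean)
    else:
        duration = min(sp.brief_min + rng.exponential(sp.brief_mean), sp.brief_max)
    jit = lambda: float(np.exp(params.amp_jitter_rel * rng.standard_normal()))
    return EventLatents(
        missed=missed,
        reaction_time=rt,
        long_braker=long_braker,
        brake_duration=float(duration),
        jitter_steering=jit(),
        jitter_speed=jit(),
        jitter_pd=jit(),
        jitter_hr=jit(),
        speed_baseline=float(sp.baseline + sp.baseline_sd * rng.standard_normal()),
        pd_baseline=float(
            np.clip(params.pupil.baseline
                    + params.pupil.baseline_sd * rng.standard_normal(), 1.5, 8.0)
        ),
        hr_baseline=float(params.heart_rate.baseline
                          + params.heart_rate.baseline_sd * rng.standard_normal()),
        sc_tonic_level=float(
            max(0.2, params.skin_conductance.tonic_level
                + params.skin_conductance.tonic_level_sd * rng.standard_normal())
        ),
    )


# ---------------------------------------------------------------------------
# deterministic mean profiles (t in seconds since takeover onset)
# ---------------------------------------------------------------------------


def _decay(t: np.ndarray, tau: float) -> np.ndarray:
    """exp(-t/tau) for t >= 0 (0 for t < 0); identically 0 when tau == 0,
    i.e. a zero time constant means an instantaneous return to baseline."""
    t = np.asarray(t, dtype=float)
    if tau <= 0:
        return np.zeros_like(t)
    out = np.exp(-np.clip(t, 0.0, None) / tau)
    out[t < 0] = 0.0
    return out


def steering_sd_profile(t, params: SignalParams, lat: EventLatents) -> np.ndarray:
    """SD of the steering-angle process; winding ground truth lives here."""
    t = np.asarray(t, dtype=float)
    st = params.steering
    if lat.missed:
        return np.full_like(t, st.pre_to_sd)
    post = st.base_sd + lat.jitter_steering * st.excursion_sd * _decay(t, st.tau)
    return np.where(t < 0, st.pre_to_sd, post)


def speed_profile(t, params: SignalParams, lat: EventLatents) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    sp = params.speed
    v0 = lat.speed_baseline
    if lat.missed:
        return np.full_like(t, v0)
    depth = lat.jitter_speed * sp.dip_depth
    d = lat.brake_duration
    v = np.full_like(t, v0)
    braking = (t >= 0) & (t < d)
    v[braking] = v0 - depth * (1.0 - _decay(t[braking], sp.tau_dip))
    after = t >= d
    if after.any() and not lat.long_braker:
        v_d = v0 - depth * (1.0 - float(_decay(np.array([d]), sp.tau_dip)[0]))
        v[after] = v0 - (v0 - v_d) * _decay(t[after] - d, sp.tau_recover)
    elif after.any():
        v[after] = v0 - depth * (1.0 - _decay(t[after], sp.tau_dip))
    return v


def accel_profile(t, params: SignalParams, lat: EventLatents) -> np.ndarray:
    """Longitudinal acceleration (m/s^2) = d(speed)/dt / 3.6."""
    t = np.asarray(t, dtype=float)
    sp = params.speed
    if lat.missed:
        return np.zeros_like(t)
    depth = lat.jitter_speed * sp.dip_depth
    d = lat.brake_duration
    a = np.zeros_like(t)
    braking = (t >= 0) & (t < d)
    if sp.tau_dip > 0:
        a[braking] = -(depth / sp.tau_dip) * _decay(t[braking], sp.tau_dip) / 3.6
    after = t >= d
    if after.any() and not lat.long_braker and sp.tau_recover > 0:
        v_d_gap = depth * (1.0 - float(_decay(np.array([d]), sp.tau_dip)[0]))
        a[after] = (v_d_gap / sp.tau_recover) * _decay(t[after] - d, sp.tau_recover) / 3.6
    elif after.any() and lat.long_braker and sp.tau_dip > 0:
        a[after] = -(depth / sp.tau_dip) * _decay(t[after], sp.tau_dip) / 3.6
    return a


def brake_profile(t, params: SignalParams, lat: EventLatents) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    sp = params.speed
    if lat.missed:
        return np.zeros_like(t)
    on = (t >= 0) & (t < lat.brake_duration)
    out = np.zeros_like(t)
    out[on] = np.clip(sp.brake_floor + sp.brake_peak * _decay(t[on], sp.tau_dip), 0, 100)
    return out


def off_road_probability(t, params: SignalParams, lat: EventLatents) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    gz = params.gaze
    if lat.missed:
        return np.full_like(t, gz.p_off_pre)
    post = gz.p_off_asymptote + gz.p_off_excursion * _decay(t, gz.tau)
    return np.clip(np.where(t < 0, gz.p_off_pre, post), 0.0, 1.0)


def pupil_profile(t, params: SignalParams, lat: EventLatents) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if lat.missed:
        return np.full_like(t, lat.pd_baseline)
    exc = lat.jitter_pd * params.pupil.excursion
    return lat.pd_baseline + exc * _decay(t, params.pupil.tau)


def heart_rate_profile(t, params: SignalParams, lat: EventLatents) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if lat.missed:
        return np.full_like(t, lat.hr_baseline)
    exc = lat.jitter_hr * params.heart_rate.excursion
    return lat.hr_baseline + exc * _decay(t, params.heart_rate.tau)


def scr_rate_profile(t, params: SignalParams, lat: EventLatents) -> np.ndarray:
    """SCR event rate (events/s)."""
    t = np.asarray(t, dtype=float)
    sc = params.skin_conductance
    if lat.missed:
        return np.full_like(t, sc.scr_rate_base)
    return sc.scr_rate_base + sc.scr_rate_excursion * _decay(t, sc.scr_rate_tau)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableGroundTruth:
    """Earliest time after which the noise-free mean profile stays inside the
    tolerance band around its asymptote; ``math.inf`` if never."""

    time: float
    stabilized_within_horizon: bool


@dataclass(frozen=True)
class GroundTruth:
    tolerance: float
    horizon: float
    variables: dict[str, VariableGroundTruth]

    def __getitem__(self, name: str) -> VariableGroundTruth:
        return self.variables[name]


def settle_time(t: np.ndarray, profile: np.ndarray, asymptote: float,
                tolerance: float) -> float:
    """Earliest t from which |profile - asymptote| <= tolerance * amplitude
    holds for all later t, where amplitude = max deviation over t >= 0.
    Brute-force reverse scan; returns inf if the profile never settles."""
    dev = np.abs(np.asarray(profile, float) - asymptote)
    amp = dev.max()
    if amp <= 1e-9 * max(abs(asymptote), 1.0):  # numerically flat profile
        return 0.0
    band = tolerance * amp
    # running maximum of future deviations
    future_max = np.maximum.accumulate(dev[::-1])[::-1]
    inside = future_max <= band
    if not inside.any():
        return float("inf")
    return float(t[np.argmax(inside)])


def _expected_speed_profiles(t, params, n_quantiles=101):
    """Population expectation of the speed / deceleration-magnitude profiles,
    integrating over the brake-duration mixture by quantile quadrature."""
    sp = params.speed
    base = neutral_latents(params)
    q = (np.arange(n_quantiles) + 0.5) / n_quantiles
    v = np.zeros(len(t))
    a_mag = np.zeros(len(t))
    specs = [
        (1.0 - sp.long_braker_prob, False,
         np.minimum(sp.brief_min - sp.brief_mean * np.log1p(-q), sp.brief_max)),
        (sp.long_braker_prob, True, sp.long_min - sp.long_mean * np.log1p(-q)),
    ]
    for weight, long_flag, durations in specs:
        if weight <= 0:
            continue
        for d in durations:
            lat = EventLatents(**{**base.__dict__,
                                  "long_braker": long_flag,
                                  "brake_duration": float(d)})
            v += weight / n_quantiles * speed_profile(t, params, lat)
            a = accel_profile(t, params, lat)
            a_mag += weight / n_quantiles * np.where(a < 0, -a, 0.0)
    return v, a_mag


def _expected_phasic_profile(t, params, rate=20.0):
    """Expected phasic skin conductance: mean SCR amplitude times the SCR
    rate profile convolved with the Bateman kernel (dense numeric grid)."""
    from .eda import BatemanParams, bateman_kernel

    sc = params.skin_conductance
    lat = neutral_latents(params)
    kern = bateman_kernel(BatemanParams(sc.tau_rise, sc.tau_decay), rate)
    pad = kern.size / rate + 5.0  # pre-history longer than the kernel support
    grid = np.arange(-pad, t[-1] + 1.0 / rate, 1.0 / rate)
    amp_mean = sc.scr_amp_mean * np.exp(0.5 * sc.scr_amp_sigma**2)
    driver = scr_rate_profile(grid, params, lat) * amp_mean / rate
    phasic = np.convolve(driver, kern)[: len(grid)]
    asymptote = sc.scr_rate_base * amp_mean / rate * kern.sum()
    return np.interp(t, grid, phasic), asymptote


def ground_truth_for(
    params: SignalParams,
    tolerance: float = 0.05,
    horizon: float = 14.0,
    scan_duration: float = 120.0,
    dt: float = 0.01,
) -> GroundTruth:
    """Per-variable ground-truth stabilization time of the mean profiles.

    A variable is flagged stabilized within the horizon when its settle time
    does not exceed ``horizon`` (last window start + window length).
    """
    if tolerance <= 0:
        raise ConfigError("tolerance must be > 0")
    t = np.arange(0.0, scan_duration, dt)
    lat = neutral_latents(params)
    st = params.steering
    profiles: dict[str, tuple[np.ndarray, float]] = {}
    profiles["winding"] = (steering_sd_profile(t, params, lat), st.base_sd)
    v, a_mag = _expected_speed_profiles(t, params)
    profiles["speed"] = (v, v[-1])
    profiles["deceleration"] = (a_mag, a_mag[-1])
    profiles["eoff"] = (off_road_probability(t, params, lat),
                        params.gaze.p_off_asymptote)
    profiles["pd"] = (pupil_profile(t, params, lat), lat.pd_baseline)
    profiles["hr"] = (heart_rate_profile(t, params, lat), lat.hr_baseline)
    phasic, asym = _expected_phasic_profile(t, params)
    profiles["sc"] = (phasic, asym)

    out = {}
    for name, (profile, asymptote) in profiles.items():
        ts = settle_time(t, profile, asymptote, tolerance)
        out[name] = VariableGroundTruth(ts, ts <= horizon)
    return GroundTruth(tolerance=tolerance, horizon=horizon, variables=out)


# ---------------------------------------------------------------------------
# channel synthesis
# ---------------------------------------------------------------------------


def _time_grid(t_start: float, t_end: float, rate: float) -> np.ndarray:
    idx = np.arange(np.ceil(t_start * rate), np.floor(t_end * rate) + 1)
    return idx / rate


def _ou_noise(sd_profile: np.ndarray, rate: float, corr_time: float,
              rng: np.random.Generator) -> np.ndarray:
    """Coloured (Ornstein-Uhlenbeck) noise with slowly varying target SD."""
    n = len(sd_profile)
    if n == 0:
        return np.zeros(0)
    rho = float(np.exp(-1.0 / (rate * corr_time))) if corr_time > 0 else 0.0
    innov = rng.standard_normal(n) * sd_profile * np.sqrt(1.0 - rho**2)
    # start the recursion in the stationary regime of the first sample
    innov[0] = rng.standard_normal() * sd_profile[0]
    return lfilter([1.0], [1.0, -rho], innov)


def simulate_event_channels(
    event: TakeoverEvent,
    params: SignalParams,
    seed,
    config: StudyConfig | None = None,
    latents: EventLatents | None = None,
) -> MultiChannelRecording:
    """Synthesize all nine channels of one takeover episode.

    ``seed`` may be an integer, a ``SeedSequence`` or a ``Generator``.  The
    recording clock has t = 0 at the takeover onset implied by the event's
    TOR time; it covers ``[tor_time - pre_tor_duration, episode_duration]``.
    """
    params.validate()
    cfg = config or default_study_config()
    rng = np.random.default_rng(seed)
    if latents is None:
        latents = draw_event_latents(params, rng, cfg.tor_lead_time)
        latents.reaction_time = -event.tor_time
    lat = latents
    t0 = event.tor_time - cfg.pre_tor_duration
    t1 = cfg.episode_duration

    ch: dict[str, Channel] = {}

    td = _time_grid(t0, t1, cfg.rate_drive)
    st = params.steering
    ch["steering_deg"] = Channel(
        td, _ou_noise(steering_sd_profile(td, params, lat),
                      cfg.rate_drive, st.noise_corr_time, rng))
    sp = params.speed
    ch["speed_kmh"] = Channel(
        td, speed_profile(td, params, lat)
        + _ou_noise(np.full(len(td), sp.noise_sd), cfg.rate_drive,
                    sp.noise_corr_time, rng))
    ch["accel_ms2"] = Channel(
        td, accel_profile(td, params, lat)
        + sp.accel_noise_sd * rng.standard_normal(len(td)))
    ch["brake_pct"] = Channel(td, brake_profile(td, params, lat))
    ch["accpedal_pct"] = Channel(td, np.zeros(len(td)))

    te = _time_grid(t0, t1, cfg.rate_eye)
    p_off = off_road_probability(te, params, lat)
    ch["gaze_onroad"] = Channel(te, (rng.random(len(te)) >= p_off).astype(float))
    ch["pd_mm"] = Channel(
        te, pupil_profile(te, params, lat)
        + params.pupil.noise_sd * rng.standard_normal(len(te)))

    th = _time_grid(t0, t1, cfg.rate_hr)
    hr = params.heart_rate
    hr_vals = heart_rate_profile(th, params, lat) \
        + hr.noise_sd * rng.standard_normal(len(th))
    hr_missing = rng.random(len(th)) < hr.missing_prob
    hr_vals = hr_vals.copy()
    hr_vals[hr_missing] = np.nan
    ch["hr_bpm"] = Channel(th, hr_vals, hr_missing)

    tg = _time_grid(t0, t1, cfg.rate_gsr)
    sc = params.skin_conductance
    tonic = lat.sc_tonic_level + sc.tonic_drift * (tg - tg[0])
    rate_per_bin = scr_rate_profile(tg, params, lat) / cfg.rate_gsr
    counts = rng.poisson(rate_per_bin)
    driver = np.zeros(len(tg))
    total = int(counts.sum())
    if total:
        amps = sc.scr_amp_mean * np.exp(sc.scr_amp_sigma * rng.standard_normal(total))
        np.add.at(driver, np.repeat(np.arange(len(tg)), counts), amps)
    from .eda import BatemanParams, bateman_kernel

    kern = bateman_kernel(BatemanParams(sc.tau_rise, sc.tau_decay), cfg.rate_gsr)
    phasic = np.convolve(driver, kern)[: len(tg)]
    gsr = np.clip(tonic + phasic + sc.noise_sd * rng.standard_normal(len(tg)), 0, None)
    ch["gsr_us"] = Channel(tg, gsr)

    rec = MultiChannelRecording(
        event_id=event.event_id,
        tor_time=event.tor_time,
        availability_end=event.availability_end,
        channels=ch,
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Events, recordings and the ground truth of one generated study.

    Ground truth describes the noise-free mean profiles shared by all events
    of the dataset (per-attempt jitters average out), so it is stored once at
    dataset level.
    """

    config: StudyConfig
    params: SignalParams
    seed: int
    events: list[TakeoverEvent] = field(default_factory=list)
    recordings: list[MultiChannelRecording] = field(default_factory=list)
    ground_truth: GroundTruth | None = None

    def event_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "event_id": e.event_id,
                    "study": e.study,
                    "driver": e.driver,
                    "trial": e.trial,
                    "index": e.index,
                    "tor_time_s": e.tor_time,
                    "availability_end_s": e.availability_end,
                }
                for e in self.events
            ],
            columns=["event_id", "study", "driver", "trial", "index",
                     "tor_time_s", "availability_end_s"],
        )


def generate_study(
    config: StudyConfig | None = None,
    params: SignalParams | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Generate the configured number of takeover episodes.

    Deterministic given (config, params, seed): every event draws from a
    substream keyed by its (study, driver, trial, takeover) coordinates.
    """
    cfg = config or default_study_config()
    cfg.validate()
    par = params or SignalParams()
    par.validate()
    root = cfg.seed if seed is None else seed

    ds = SyntheticDataset(config=cfg, params=par, seed=root)
    for si, block in enumerate(cfg.studies):
        for di in range(block.n_drivers):
            for ti in range(block.n_trials):
                for ei in range(block.n_takeovers):
                    ss = np.random.SeedSequence(root, spawn_key=(si, di, ti, ei))
                    rng = np.random.default_rng(ss)
                    lat = draw_event_latents(par, rng, cfg.tor_lead_time)
                    event = TakeoverEvent(
                        event_id=f"s{si + 1}-d{di:03d}-t{ti}-e{ei}",
                        study=si + 1,
                        driver=di,
                        trial=ti,
                        index=ei,
                        tor_time=-lat.reaction_time,
                        availability_end=-lat.reaction_time + cfg.tor_lead_time,
                    )
                    rec = simulate_event_channels(event, par, rng, cfg, lat)
                    ds.events.append(event)
                    ds.recordings.append(rec)
    if not ds.events:
        warnings.warn("configuration yields zero takeover events", stacklevel=2)
    ds.ground_truth = ground_truth_for(par)
    return ds
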