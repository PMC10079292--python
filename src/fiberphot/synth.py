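"""Synthetic-data generators with known ground truth for every pipeline input.

Emulates the structure of the real recordings so that every downstream stage is
testable without external data:

* multiplexed two-wavelength photometry frame streams — event-locked calcium
  transients riding on exponential bleaching, a motion/noise artifact shared
  sample-for-sample by the 405 and 473 nm channels, and laser-power drift
  visible in the control-fluorophore fiber;
* fixed-ratio operant sessions with the stated trial timing (3 s inter-trial
  interval, lever extension, ratio presses, pellet delivery, head entry,
  8 s consumption period) and pseudo-random light delivery on a fixed fraction
  of trials;
* lick trains organized in bouts; open-field trajectories alternating rest and
  movement; current-clamp sweeps with template action potentials on an Ohmic
  membrane response; Poisson tract-tracing count tables.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .behavior import EventLog, Schedule
from .ephys import CurrentClampSweep
from .photometry import RawPhotometrySession, VALID_RATES
from .tracing import TracingCounts

DEFAULT_KERNEL_RISE_S = 0.2    # GCaMP6s-like rise
DEFAULT_KERNEL_DECAY_S = 1.5   # GCaMP6s-like decay
DEFAULT_BLEACH_TAU_S = 600.0


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

@dataclass
class PhotometrySimConfig:
    """Parameters of a simulated multiplexed photometry session.

    ``artifact`` and ``laser_drift`` may be None, an array on the per-pair
    (473-frame) timebase, or a callable of the pair time vector. The artifact
    is added identically to both excitation channels (motion is wavelength
    independent); the drift multiplies all laser-driven fluorescence and the
    control fiber (laser power is shared).
    """

    duration_s: float
    multiplex_rate_per_channel_hz: int = 15
    transient_amplitude: float = 5.0
    kernel_rise_s: float = DEFAULT_KERNEL_RISE_S
    kernel_decay_s: float = DEFAULT_KERNEL_DECAY_S
    artifact: object = None
    laser_drift: object = None
    bleach_tau_s: float = DEFAULT_BLEACH_TAU_S
    noise_sd: float = 0.0
    background_level: float = 10.0
    base_fluorescence: float = 100.0
    control_fluorescence: float = 50.0
    background_duration_s: float = 1.0
    seed: int = 0

    def to_json(self, path) -> None:
        d = {k: v for k, v in asdict(self).items() if k not in ("artifact", "laser_drift")}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PhotometrySimConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GroundTruth:
    """What the generator actually injected, on the demultiplexed 473 timebase."""

    t_s: np.ndarray
    clean_transient_trace: np.ndarray  # unit-amplitude kernel-convolved series
    artifact_trace: np.ndarray
    laser_drift_trace: np.ndarray
    event_times_s: np.ndarray          # absolute session time (laser-on offset applied)
    laser_on_s: float = 0.0            # time of the first laser-on frame


def calcium_kernel(tau: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials transient kernel, normalized to unit peak."""
    if rise_s <= 0 or decay_s <= rise_s:
        raise ValueError("require 0 < rise < decay")
    tau = np.asarray(tau, dtype=float)
    k = np.where(tau >= 0, np.exp(-np.maximum(tau, 0) / decay_s)
                 - np.exp(-np.maximum(tau, 0) / rise_s), 0.0)
    t_peak = np.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return k / peak


def _series_on_pairs(spec, t_pair: np.ndarray, default: float) -> np.ndarray:
    if spec is None:
        return np.full(t_pair.size, default)
    if callable(spec):
        return np.asarray(spec(t_pair), dtype=float)
    arr = np.asarray(spec, dtype=float)
    if arr.size != t_pair.size:
        raise ValueError(
            f"series length {arr.size} does not match the {t_pair.size} frame pairs"
        )
    return arr


def simulate_photometry_session(
    cfg: PhotometrySimConfig,
    events_s,
) -> tuple[RawPhotometrySession, GroundTruth]:
    """Generate an interleaved 405/473 frame stream with known ground truth.

    Event times are given relative to laser onset, within [0, duration]. The
    473 frames carry the kernel-convolved transient plus bleach, artifact and
    noise; the 405 frames carry everything except the transient (isosbestic
    assumption); the control-fiber column carries laser drift and noise only.
    A leading block of laser-off background frames (>= 1 s) is emitted first.
    """
    if cfg.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if cfg.multiplex_rate_per_channel_hz not in VALID_RATES:
        raise ValueError(f"multiplex rate must be one of {VALID_RATES}")
    events = np.sort(np.asarray(list(events_s), dtype=float))
    if events.size and (events.min() < 0 or events.max() > cfg.duration_s):
        raise ValueError("event times must lie within [0, duration_s]")

    rng = np.random.default_rng(cfg.seed)
    fs = cfg.multiplex_rate_per_channel_hz
    frame_dt = 1.0 / (2 * fs)
    n_bg = int(np.ceil(max(cfg.background_duration_s, 1.0) * 2 * fs))
    n_pairs = int(round(cfg.duration_s * fs))
    if n_pairs < 2:
        raise ValueError("session too short for the requested rate")

    t_on = n_bg * frame_dt                      # first laser frame time
    idx = np.arange(n_bg + 2 * n_pairs)
    t_frames = idx * frame_dt
    t405 = t_frames[n_bg::2]
    t473 = t_frames[n_bg + 1::2]
    t_rel = t473 - t_on                          # pair timebase, 0 at laser onset

    clean = np.zeros(n_pairs)
    for te in events:
        clean += calcium_kernel(t_rel - te, cfg.kernel_rise_s, cfg.kernel_decay_s)
    artifact = _series_on_pairs(cfg.artifact, t_rel, 0.0)
    drift = _series_on_pairs(cfg.laser_drift, t_rel, 1.0)
    bleach = cfg.base_fluorescence * np.exp(-t_rel / cfg.bleach_tau_s)

    # bleach/artifact/drift are evaluated once per frame pair so the two
    # excitation channels share them sample-for-sample
    s473 = cfg.background_level + drift * (bleach + cfg.transient_amplitude * clean) + artifact
    s405 = cfg.background_level + drift * bleach + artifact
    ctrl = cfg.background_level + drift * cfg.control_fluorescence

    def noisy(x, n):
        return x + (rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0)

    frames = pd.DataFrame({
        "frame_index": idx,
        "t_s": t_frames,
        "channel": np.concatenate((
            np.full(n_bg, "off"),
            np.tile(["405", "473"], n_pairs),
        )),
        "roi_signal": np.concatenate((
            noisy(np.full(n_bg, cfg.background_level), n_bg),
            np.column_stack((noisy(s405, n_pairs), noisy(s473, n_pairs))).ravel(),
        )),
        "roi_control": np.concatenate((
            noisy(np.full(n_bg, cfg.background_level), n_bg),
            np.column_stack((noisy(ctrl, n_pairs), noisy(ctrl, n_pairs))).ravel(),
        )),
    })
    session = RawPhotometrySession(frames, fs)
    truth = GroundTruth(
        t_s=t473, clean_transient_trace=clean, artifact_trace=artifact,
        laser_drift_trace=drift, event_times_s=events + t_on, laser_on_s=t_on,
    )
    return session, truth


def default_artifact(n: int, fs_hz: float, rng: np.random.Generator,
                     sine_amplitude: float = 2.0, sine_freq_hz: float = 0.1,
                     walk_step_sd: float = 0.05) -> np.ndarray:
    """Shared-channel artifact: slow sinusoid plus a Gaussian random walk."""
    t = np.arange(n) / fs_hz
    phase = rng.uniform(0, 2 * np.pi)
    return (sine_amplitude * np.sin(2 * np.pi * sine_freq_hz * t + phase)
            + np.cumsum(rng.normal(0.0, walk_step_sd, n)))


def default_laser_drift(n: int, fs_hz: float, rng: np.random.Generator,
                        amplitude: float = 0.02, freq_hz: float = 0.02) -> np.ndarray:
    """Slow multiplicative laser-power fluctuation around 1."""
    t = np.arange(n) / fs_hz
    phase = rng.uniform(0, 2 * np.pi)
    return 1.0 + amplitude * np.sin(2 * np.pi * freq_hz * t + phase)


def make_default_session(
    seed: int,
    duration_s: float = 1800.0,
    n_events: int = 100,
    rate_hz: int = 15,
    noise_sd: float = 0.3,
    event_times_s=None,
) -> tuple[RawPhotometrySession, GroundTruth]:
    """A standard test session: transients at the default SNR over a shared
    sinusoid + random-walk artifact and slow laser drift.

    The default duration matches a 30 min recording session with roughly one
    rewarded trial's worth of transients every 18 s. Session length matters:
    the isosbestic-regression slope is estimated from the data, and its
    finite-sample bias (chance covariance between the calcium signal and the
    artifact) shrinks with the number of independent artifact fluctuations.
    """
    rng = np.random.default_rng(seed)
    if event_times_s is None:
        lo, hi = 5.0, duration_s - 10.0
        event_times_s = np.sort(rng.uniform(lo, hi, n_events))
    n_pairs = int(round(duration_s * rate_hz))
    cfg = PhotometrySimConfig(
        duration_s=duration_s,
        multiplex_rate_per_channel_hz=rate_hz,
        noise_sd=noise_sd,
        artifact=default_artifact(n_pairs, rate_hz, rng),
        laser_drift=default_laser_drift(n_pairs, rate_hz, rng),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return simulate_photometry_session(cfg, event_times_s)


# ---------------------------------------------------------------------------
# operant behavior
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSimConfig:
    """Parameters of a simulated fixed-ratio operant session.

    ``schedule`` names the ratio and response time limit (e.g. ``FR5-5s``;
    ``NTL`` = no time limit). ``p_engage`` is the probability a trial has any
    pressing; on light trials it is shifted by ``light_effect`` (clipped to
    [0, 1]). Light trials are an exactly ``light_fraction`` proportion,
    pseudo-randomly ordered by seeded shuffling.
    """

    schedule: str = "FR5-5s"
    n_trials: int = 50
    iti_s: float = 3.0
    consumption_s: float = 8.0
    press_rate_hz: float = 2.0
    p_engage: float = 0.9
    light_fraction: float = 0.0
    light_effect: float = 0.0
    retrieval_mean_s: float = 1.0
    ntl_omission_cap_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_engage", "light_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        Schedule.from_name(self.schedule)  # validates the name

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BehaviorSimConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_fr_session(cfg: BehaviorSimConfig) -> EventLog:
    """Generate an operant event log for one fixed-ratio session.

    Each trial: inter-trial interval, lever extension, exponential-interval
    presses while the animal is engaged, pellet delivery at the ratio-th press
    (if within the time limit), head entry after delivery, lever retraction at
    retrieval or at limit expiry, then the consumption period. The returned
    EventLog carries a ``truth`` DataFrame attribute with the per-trial
    ground-truth outcome for oracle tests.
    """
    sched = Schedule.from_name(cfg.schedule)
    rng = np.random.default_rng(cfg.seed)

    n_light = int(round(cfg.light_fraction * cfg.n_trials))
    light = np.zeros(cfg.n_trials, dtype=bool)
    light[:n_light] = True
    rng.shuffle(light)

    rows = []
    truth_rows = []
    t = 0.0

    def emit(t_s, label, k, lf):
        rows.append({"t_s": t_s, "label": label, "trial_index": k, "light_flag": lf})

    for k in range(cfg.n_trials):
        lf = bool(light[k])
        t += cfg.iti_s
        if lf:
            emit(t - 0.5, "light_on", k, lf)
        t_ext = t
        emit(t_ext, "lever_extension", k, lf)

        p = cfg.p_engage + (cfg.light_effect if lf else 0.0)
        p = min(1.0, max(0.0, p))
        engaged = rng.random() < p

        presses: list[float] = []
        if engaged and cfg.press_rate_hz > 0:
            tp = t_ext
            while len(presses) < sched.ratio:
                tp += rng.exponential(1.0 / cfg.press_rate_hz)
                if sched.time_limit_s is not None and tp - t_ext > sched.time_limit_s:
                    break
                presses.append(tp)

        completed = len(presses) >= sched.ratio
        if completed:
            t_del = presses[-1] + 0.05
            t_entry = t_del + rng.exponential(cfg.retrieval_mean_s)
            t_ret = t_entry  # lever retracts once the pellet is retrieved
            for tp in presses:
                emit(tp, "press", k, lf)
            emit(t_del, "pellet_delivery", k, lf)
            emit(t_ret, "lever_retraction", k, lf)
            emit(t_entry, "head_entry", k, lf)
            t = t_ret + cfg.consumption_s
        else:
            if sched.time_limit_s is not None:
                t_ret = t_ext + sched.time_limit_s
            elif presses:
                t_ret = presses[-1] + 1.0  # NTL trial abandoned mid-sequence
            else:
                t_ret = t_ext + cfg.ntl_omission_cap_s
            for tp in presses:
                emit(tp, "press", k, lf)
            emit(t_ret, "lever_retraction", k, lf)
            t = t_ret
        if lf:
            emit(t_ret, "light_off", k, lf)

        outcome = ("completed" if completed
                   else "incomplete" if presses else "omission")
        truth_rows.append({
            "trial_index": k, "light_flag": lf, "n_presses": len(presses),
            "outcome": outcome, "t_extension_s": t_ext,
        })

    df = pd.DataFrame(rows).sort_values("t_s", kind="stable").reset_index(drop=True)
    log = EventLog(df)
    log.truth = pd.DataFrame(truth_rows)
    return log


def simulate_lick_train(
    n_bouts: int,
    licks_per_bout: int,
    intra_ili_s: float,
    inter_bout_gap_s: float,
    start_s: float = 0.0,
) -> list[float]:
    """Deterministic lick train forming exactly ``n_bouts`` bouts.

    Requires intra-bout interval < 2 s < inter-bout gap so the bout rule
    (two or more licks, every inter-lick interval under 2 s) segments the
    train as constructed. ``licks_per_bout == 1`` yields isolated licks that
    form no bout.
    """
    if n_bouts < 0 or licks_per_bout < 0:
        raise ValueError("counts must be nonnegative")
    if n_bouts == 0 or licks_per_bout == 0:
        return []
    if not (intra_ili_s < 2.0 < inter_bout_gap_s):
        raise ValueError("require intra_ili_s < 2 s < inter_bout_gap_s")
    t = start_s
    licks: list[float] = []
    for _ in range(n_bouts):
        for j in range(licks_per_bout):
            licks.append(t + j * intra_ili_s)
        t = licks[-1] + inter_bout_gap_s
    return licks


# ---------------------------------------------------------------------------
# open-field trajectory
# ---------------------------------------------------------------------------

def simulate_trajectory(
    duration_s: float = 60.0,
    rate_hz: float = 30.0,
    arena_cm: tuple[float, float] = (70.0, 30.0),
    move_speed_cm_s: float = 8.0,
    bout_dur_s: float = 2.0,
    rest_dur_s: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[float, float]]]:
    """Random-walk trajectory alternating rest and movement bouts.

    Returns the (t, x, y) DataFrame and the ground-truth list of
    (onset_s, offset_s) movement intervals.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    dt = 1.0 / rate_hz
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = arena_cm[0] / 2, arena_cm[1] / 2
    moving = False
    t_switch = rest_dur_s
    heading = rng.uniform(0, 2 * np.pi)
    intervals: list[tuple[float, float]] = []
    t_on = 0.0
    for i in range(1, n):
        if t[i] >= t_switch:
            moving = not moving
            if moving:
                t_on = t[i]
                heading = rng.uniform(0, 2 * np.pi)
                t_switch = t[i] + bout_dur_s
            else:
                intervals.append((t_on, t[i]))
                t_switch = t[i] + rest_dur_s
        if moving:
            heading += rng.normal(0, 0.2)
            step = move_speed_cm_s * dt
        else:
            step = 0.0
        x[i] = np.clip(x[i - 1] + step * np.cos(heading), 0, arena_cm[0])
        y[i] = np.clip(y[i - 1] + step * np.sin(heading), 0, arena_cm[1])
    if moving:
        intervals.append((t_on, t[-1]))
    return pd.DataFrame({"t_s": t, "x_cm": x, "y_cm": y}), intervals


# ---------------------------------------------------------------------------
# current clamp
# ---------------------------------------------------------------------------

#: template AP geometry (relative to the local baseline, times in ms)
_AP_FOOT_MS = 2.0      # slow depolarizing foot up to the kink
_AP_FOOT_MV = 15.0     # kink sits this far above baseline
_AP_RISE_MS = 0.3      # fast upstroke
_AP_PEAK_MV = 90.0     # peak above baseline
_AP_FALL_MS = 0.5      # downstroke to the AHP
_AP_AHP_MV = -5.0      # AHP below baseline
_AP_AHP_TAU_MS = 2.0   # AHP recovery


def _ap_template(fs_hz: float) -> tuple[np.ndarray, int]:
    """Sampled AP waveform (additive, baseline 0) and the index of its peak."""
    dt_ms = 1000.0 / fs_hz
    foot = np.linspace(0.0, _AP_FOOT_MV, int(round(_AP_FOOT_MS / dt_ms)),
                       endpoint=False)
    rise = np.linspace(_AP_FOOT_MV, _AP_PEAK_MV, int(round(_AP_RISE_MS / dt_ms)) + 1)
    fall = np.linspace(_AP_PEAK_MV, _AP_AHP_MV,
                       int(round(_AP_FALL_MS / dt_ms)) + 1)[1:]
    t_rec = np.arange(1, int(round(5 * _AP_AHP_TAU_MS / dt_ms)) + 1) * dt_ms
    rec = _AP_AHP_MV * np.exp(-t_rec / _AP_AHP_TAU_MS)
    wave = np.concatenate((foot, rise, fall, rec))
    i_peak = foot.size + rise.size - 1
    return wave, i_peak


def simulate_current_clamp(
    spike_times_s,
    step_onset_s: float = 0.2,
    step_offset_s: float = 0.7,
    step_pa: float = 0.0,
    rin_mohm: float = 100.0,
    seed: int = 0,
    fs_hz: float = 10_000.0,
    duration_s: float | None = None,
    v_rest_mv: float = -60.0,
    membrane_tau_s: float = 0.02,
    noise_sd_mv: float = 0.0,
) -> CurrentClampSweep:
    """Current-clamp sweep: template APs on an exponential membrane response.

    The step drives an Ohmic deflection with steady state ``step_pa * rin_mohm``
    (in microvolts, i.e. pA x MOhm / 1000 mV) reached exponentially with the
    membrane time constant. Spike times mark template-AP peaks; spikes closer
    than 2 ms raise.
    """
    spikes = np.sort(np.asarray(list(spike_times_s), dtype=float))
    if spikes.size > 1 and np.min(np.diff(spikes)) < 0.002:
        raise ValueError("overlapping spikes: < 2 ms apart")
    if duration_s is None:
        duration_s = step_offset_s + 0.5
    if spikes.size and (spikes.min() < 0 or spikes.max() > duration_s):
        raise ValueError("spike times must lie inside the sweep")
    if not step_onset_s < step_offset_s <= duration_s:
        raise ValueError("require step_onset < step_offset <= duration")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz)) + 1
    t = np.arange(n) / fs_hz
    dv_ss = step_pa * rin_mohm / 1000.0  # mV
    vm = np.full(n, v_rest_mv)
    during = (t >= step_onset_s) & (t < step_offset_s)
    vm[during] += dv_ss * (1.0 - np.exp(-(t[during] - step_onset_s) / membrane_tau_s))
    after = t >= step_offset_s
    dv_off = dv_ss * (1.0 - np.exp(-(step_offset_s - step_onset_s) / membrane_tau_s))
    vm[after] += dv_off * np.exp(-(t[after] - step_offset_s) / membrane_tau_s)

    wave, i_peak = _ap_template(fs_hz)
    for ts in spikes:
        j = int(round(ts * fs_hz)) - i_peak
        lo, hi = max(0, j), min(n, j + wave.size)
        vm[lo:hi] += wave[lo - j:hi - j]
    if noise_sd_mv > 0:
        vm = vm + rng.normal(0.0, noise_sd_mv, n)

    i_pa = np.where(during, step_pa, 0.0)
    return CurrentClampSweep(t, vm, i_pa, step_onset_s, step_offset_s, step_pa)


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------

def simulate_tracing_counts(
    ratios: dict,
    base_count: int,
    n_slices: int = 4,
    seed: int = 0,
    case_id: str = "case1",
    afferent: str = "afferent",
    area_range_mm2: tuple[float, float] = (0.8, 1.2),
) -> TracingCounts:
    """Poisson cell-count table around ``base_count x ratio`` per compartment.

    Each slice draws an area per region and a Poisson count with mean
    ``base_count * ratio * area``, so the density ratio concentrates on the
    requested value.
    """
    if base_count <= 0:
        raise ValueError("base_count must be positive")
    if any(r <= 0 for r in ratios.values()):
        raise ValueError("ratios must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_slices):
        for region, ratio in ratios.items():
            area = rng.uniform(*area_range_mm2)
            rows.append({
                "case_id": case_id, "afferent": afferent, "slice_index": s,
                "region": region,
                "count": int(rng.poisson(base_count * ratio * area)),
                "area_mm2": area,
            })
    return TracingCounts(pd.DataFrame(rows))
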