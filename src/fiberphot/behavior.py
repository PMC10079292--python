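"""Operant and consummatory behavior parsing.

Covers fixed-ratio (FR) lever-press sessions, lick-bout microstructure,
open-field movement epochs and target-approach detection.

FR trial structure: after an inter-trial interval the lever extends; on an FR-N
schedule the N-th press triggers sucrose-pellet delivery, the animal retrieves
the pellet at the receptacle (head entry), and the lever retracts. Timed
schedules (e.g. FR5-5s) retract the lever when the response time limit — clocked
from lever extension — expires first. Trial outcomes:

* completed  — the full ratio pressed within the time limit
* incomplete — at least one press but fewer than the ratio (one to four on FR5)
* omission   — no press during lever availability
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

EVENT_LABELS = (
    "lever_extension", "lever_retraction", "press", "pellet_delivery",
    "head_entry", "lick", "tone_on", "tone_off", "light_on", "light_off",
)

OUTCOMES = ("completed", "incomplete", "omission")

#: maximal inter-lick interval (s) inside a bout: >=2 licks with every ILI < 2 s
BOUT_ILI_S = 2.0


@dataclass(frozen=True)
class Schedule:
    """Fixed-ratio schedule: press ``ratio`` times within ``time_limit_s`` (None = no limit)."""

    name: str
    ratio: int
    time_limit_s: float | None

    @classmethod
    def from_name(cls, name: str) -> "Schedule":
        """Parse names like ``FR5-NTL``, ``FR5-7.5s``, ``FR1-NTL``."""
        m = re.fullmatch(r"FR(\d+)-(NTL|[\d.]+s)", name)
        if not m:
            raise ValueError(f"unrecognized schedule name: {name!r}")
        ratio = int(m.group(1))
        limit = None if m.group(2) == "NTL" else float(m.group(2)[:-1])
        return cls(name, ratio, limit)


@dataclass
class EventLog:
    """Timestamped labeled behavioral events.

    ``records`` columns: ``t_s``, ``label``, ``trial_index`` (nullable),
    ``light_flag`` (bool). Timestamps must be nondecreasing.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"t_s", "label"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"event log missing columns: {sorted(missing)}")
        if "trial_index" not in self.records.columns:
            self.records["trial_index"] = pd.NA
        if "light_flag" not in self.records.columns:
            self.records["light_flag"] = False
        t = self.records["t_s"].to_numpy(float)
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("event timestamps must be nondecreasing")

    def times(self, label: str) -> np.ndarray:
        return self.records.loc[self.records["label"] == label, "t_s"].to_numpy(float)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventLog":
        return cls(pd.read_csv(path))


@dataclass
class Trial:
    schedule: Schedule
    t_extension_s: float
    t_retraction_s: float
    press_times_s: list[float]
    outcome: str
    initiation_latency_s: float  # first press - extension; NaN if no press
    retrieval_latency_s: float   # first head entry after delivery - delivery; NaN if n/a
    t_delivery_s: float          # NaN if not reinforced
    light_flag: bool
    reinforced_flag: bool
    trial_index: int


@dataclass
class Bout:
    """Lick bout: two or more licks, every inter-lick interval < 2 s."""

    start_s: float
    end_s: float
    n_licks: int
    lick_times_s: list[float]


@dataclass
class MovementEpoch:
    onset_s: float
    offset_s: float
    peak_speed_cm_s: float
    t_peak_s: float


@dataclass
class ApproachEvent:
    t_entry_s: float
    target_id: int


def parse_trials(log: EventLog, schedule: Schedule | str) -> list[Trial]:
    """Segment an event log into trials and classify each outcome.

    Trials are bounded by lever_extension/lever_retraction pairs. Outcome follows
    the press count relative to the schedule ratio; initiation latency is first
    press minus extension, retrieval latency is first head entry after pellet
    delivery minus the delivery time. A press outside any trial raises.
    """
    if isinstance(schedule, str):
        schedule = Schedule.from_name(schedule)
    df = log.records
    ext = df[df["label"] == "lever_extension"]
    ret_t = log.times("lever_retraction")
    press_t = log.times("press")
    deliv_t = log.times("pellet_delivery")
    entry_t = log.times("head_entry")

    trials: list[Trial] = []
    claimed = np.zeros(press_t.size, dtype=bool)
    for k, (_, row) in enumerate(ext.iterrows()):
        t0 = float(row["t_s"])
        later = ret_t[ret_t > t0]
        if later.size == 0:
            raise ValueError(f"lever extension at t={t0:g} s has no matching retraction")
        t1 = float(later[0])
        in_trial = (press_t >= t0) & (press_t <= t1)
        claimed |= in_trial
        presses = press_t[in_trial].tolist()
        n = len(presses)
        if n == 0:
            outcome = "omission"
        elif n >= schedule.ratio:
            outcome = "completed"
        else:
            outcome = "incomplete"
        init = presses[0] - t0 if presses else math.nan
        deliv = deliv_t[(deliv_t >= t0) & (deliv_t <= t1)]
        t_del = float(deliv[0]) if deliv.size else math.nan
        retrieval = math.nan
        if deliv.size:
            after = entry_t[entry_t >= t_del]
            if after.size:
                retrieval = float(after[0]) - t_del
        light = bool(row.get("light_flag", False))
        trials.append(Trial(
            schedule=schedule, t_extension_s=t0, t_retraction_s=t1,
            press_times_s=presses, outcome=outcome,
            initiation_latency_s=init, retrieval_latency_s=retrieval,
            t_delivery_s=t_del, light_flag=light,
            reinforced_flag=bool(deliv.size), trial_index=k,
        ))
    stray = press_t[~claimed]
    if stray.size:
        raise ValueError(f"press at t={stray[0]:g} s falls outside every trial")
    return trials


def trials_to_frame(trials: list[Trial]) -> pd.DataFrame:
    """One row per trial, suitable for trials.csv export or group statistics."""
    return pd.DataFrame([
        {
            "trial_index": tr.trial_index,
            "schedule": tr.schedule.name,
            "t_extension_s": tr.t_extension_s,
            "t_retraction_s": tr.t_retraction_s,
            "n_presses": len(tr.press_times_s),
            "outcome": tr.outcome,
            "initiation_latency_s": tr.initiation_latency_s,
            "retrieval_latency_s": tr.retrieval_latency_s,
            "light_flag": tr.light_flag,
            "reinforced_flag": tr.reinforced_flag,
        }
        for tr in trials
    ])


def session_performance(trials: list[Trial]) -> pd.DataFrame:
    """Percentage of completed / incomplete / omission trials, split by light flag.

    Returns one row per stratum (``all``, and ``light``/``no_light`` where both
    occur); percentages in each row sum to 100.
    """
    if not trials:
        raise ValueError("no trials to summarize")
    df = trials_to_frame(trials)

    def rates(sub: pd.DataFrame) -> dict:
        n = len(sub)
        row = {"n_trials": n}
        for oc in OUTCOMES:
            row[f"pct_{oc}"] = 100.0 * (sub["outcome"] == oc).sum() / n
        return row

    rows = {"all": rates(df)}
    for flag, name in ((True, "light"), (False, "no_light")):
        sub = df[df["light_flag"] == flag]
        if len(sub):
            rows[name] = rates(sub)
    return pd.DataFrame.from_dict(rows, orient="index")


def detect_bouts(lick_times_s) -> list[Bout]:
    """Segment a sorted lick train into bouts.

    A bout is a maximal run of licks whose successive inter-lick intervals are
    all strictly less than 2 s; runs of a single lick are discarded. An interval
    of exactly 2.0 s splits the run.
    """
    t = np.asarray(lick_times_s, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("lick times must be sorted")
    bouts: list[Bout] = []
    if t.size == 0:
        return bouts
    breaks = np.flatnonzero(np.diff(t) >= BOUT_ILI_S)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [t.size - 1]))
    for s, e in zip(starts, ends):
        if e - s + 1 >= 2:
            bouts.append(Bout(float(t[s]), float(t[e]), int(e - s + 1), t[s:e + 1].tolist()))
    return bouts


def bouts_to_frame(bouts: list[Bout]) -> pd.DataFrame:
    return pd.DataFrame([
        {"start_s": b.start_s, "end_s": b.end_s, "n_licks": b.n_licks} for b in bouts
    ])


def _speed(t: np.ndarray, x: np.ndarray, y: np.ndarray, smooth_s: float) -> np.ndarray:
    dt = float(np.median(np.diff(t)))
    v = np.hypot(np.diff(x), np.diff(y)) / dt
    v = np.concatenate(([v[0]], v))  # same length as t
    w = max(1, int(round(smooth_s / dt)))
    if w > 1:
        kernel = np.ones(w) / w
        v = np.convolve(v, kernel, mode="same")
    return v


def detect_movement_epochs(
    trajectory: pd.DataFrame,
    speed_on_cm_s: float = 2.0,
    speed_off_cm_s: float = 1.0,
    min_dur_s: float = 0.5,
    smooth_s: float = 0.25,
) -> list[MovementEpoch]:
    """Find movement epochs by hysteresis thresholding of smoothed speed.

    An epoch opens when smoothed speed rises to ``speed_on_cm_s`` and closes when
    it falls below ``speed_off_cm_s``; epochs shorter than ``min_dur_s`` are
    dropped. Requires a uniformly sampled (t, x, y) trajectory in cm.
    """
    t = trajectory["t_s"].to_numpy(float)
    if t.size < 3:
        raise ValueError("trajectory too short")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6 * np.median(dt) + 1e-9:
        raise ValueError("trajectory timestamps are not uniformly sampled")
    v = _speed(t, trajectory["x_cm"].to_numpy(float),
               trajectory["y_cm"].to_numpy(float), smooth_s)
    epochs: list[MovementEpoch] = []
    moving = False
    onset_i = 0
    for i, vi in enumerate(v):
        if not moving and vi >= speed_on_cm_s:
            moving, onset_i = True, i
        elif moving and vi < speed_off_cm_s:
            _close_epoch(epochs, t, v, onset_i, i, min_dur_s)
            moving = False
    if moving:
        _close_epoch(epochs, t, v, onset_i, len(v), min_dur_s)
    return epochs


def _close_epoch(epochs, t, v, i0, i1, min_dur_s) -> None:
    if t[min(i1, len(t) - 1)] - t[i0] < min_dur_s:
        return
    seg = v[i0:i1]
    k = int(np.argmax(seg))
    epochs.append(MovementEpoch(
        onset_s=float(t[i0]),
        offset_s=float(t[min(i1, len(t) - 1)]),
        peak_speed_cm_s=float(seg[k]),
        t_peak_s=float(t[i0 + k]),
    ))


def detect_approaches(
    trajectory: pd.DataFrame,
    targets: list[tuple[float, float]],
    radius_cm: float = 5.0,
) -> list[ApproachEvent]:
    """Detect outside-to-inside crossings of a radius around each target.

    One event per crossing; dwelling inside produces a single event and
    re-entry requires a prior exit. The default 5 cm radius matches the
    convention of scoring an approach when the body center passes within
    5 cm of the target.
    """
    t = trajectory["t_s"].to_numpy(float)
    x = trajectory["x_cm"].to_numpy(float)
    y = trajectory["y_cm"].to_numpy(float)
    events: list[ApproachEvent] = []
    for tid, (tx, ty) in enumerate(targets):
        inside = np.hypot(x - tx, y - ty) <= radius_cm
        crossings = np.flatnonzero(inside[1:] & ~inside[:-1]) + 1
        events.extend(ApproachEvent(float(t[i]), tid) for i in crossings)
    events.sort(key=lambda e: e.t_entry_s)
    return events


def premature_head_entries(trials: list[Trial], log: EventLog) -> list[float]:
    """Head entries between lever extension and the final press of completed trials.

    These receptacle checks precede reward availability; entries after pellet
    delivery (the retrieval entry) are excluded.
    """
    entry_t = log.times("head_entry")
    out: list[float] = []
    for tr in trials:
        if tr.outcome != "completed" or not tr.press_times_s:
            continue
        last_press = tr.press_times_s[-1]
        sel = (entry_t >= tr.t_extension_s) & (entry_t < last_press)
        out.extend(entry_t[sel].tolist())
    return sorted(out)


def meets_advancement_criterion(
    completed_per_session: list[int],
    min_completed: int = 30,
    n_consecutive: int = 2,
) -> bool:
    """Whether a run of sessions satisfies the schedule-advancement criterion.

    Advancement requires at least ``min_completed`` completed fixed-ratio trials
    in each of ``n_consecutive`` consecutive sessions.
    """
    c = [n >= min_completed for n in completed_per_session]
    run = 0
    for ok in c:
        run = run + 1 if ok else 0
        if run >= n_consecutive:
            return True
    return False
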