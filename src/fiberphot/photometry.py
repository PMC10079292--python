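"""Fiber-photometry signal processing: from raw interleaved frames to a z-scored trace.

The recording scheme multiplexes two excitation lasers — 473 nm (calcium-dependent
GCaMP fluorescence) and 405 nm (the isosbestic wavelength, at which GCaMP emission
is calcium-independent) — at 10 or 15 Hz per channel, i.e. a 20 or 30 Hz frame
train. A second fiber sits in a dye tube and reports laser-power fluctuation only.

Processing proceeds in four steps:

1.  demultiplex: split the interleaved frame stream into paired 473/405 samples.
2.  subtract_background: remove the mean camera signal measured with the lasers off.
3.  regress_out_control: regress each channel (473 and 405) on its control-fiber
    series and keep the residuals, removing laser-power fluctuation.
4.  regress_out_isosbestic: regress the 473 residuals on the 405 residuals and keep
    the residuals, removing motion and other calcium-independent artifacts shared
    by the two excitation wavelengths.

The final residual series is standardized over the whole session (z-score); that
z-scored trace is the fully processed signal consumed by peri-event analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_RATES = (10, 15)


@dataclass
class RawPhotometrySession:
    """Interleaved per-frame scalar intensities from the signal and control fibers.

    ``frames`` columns: ``frame_index``, ``t_s``, ``channel`` (one of ``"405"``,
    ``"473"``, ``"off"``), ``roi_signal``, ``roi_control``. Laser-on frames must
    strictly alternate 405/473; at least one ``"off"`` (background) frame must be
    present for background subtraction.
    """

    frames: pd.DataFrame
    multiplex_rate_per_channel_hz: int

    def __post_init__(self) -> None:
        if self.multiplex_rate_per_channel_hz not in VALID_RATES:
            raise ValueError(
                f"multiplex rate must be one of {VALID_RATES}, "
                f"got {self.multiplex_rate_per_channel_hz}"
            )
        required = {"t_s", "channel", "roi_signal", "roi_control"}
        missing = required - set(self.frames.columns)
        if missing:
            raise ValueError(f"frames missing columns: {sorted(missing)}")
        t = np.asarray(self.frames["t_s"], dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame timestamps must be strictly increasing")

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, multiplex_rate_per_channel_hz: int) -> "RawPhotometrySession":
        df = pd.read_csv(path, dtype={"channel": str})
        return cls(df, multiplex_rate_per_channel_hz)


@dataclass
class ChannelPair:
    """Demultiplexed, time-aligned 473/405 samples on the 473-frame timebase.

    ``s473``/``s405`` are the signal-fiber series and ``c473``/``c405`` the
    control-fiber series at the corresponding frames. After the regression
    stages the ``s`` series hold residuals.
    """

    t_s: np.ndarray
    s473: np.ndarray
    s405: np.ndarray
    c473: np.ndarray
    c405: np.ndarray
    n_dropped_frames: int = 0
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        n = len(self.t_s)
        for name in ("s473", "s405", "c473", "c405"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from t_s")


@dataclass
class ProcessedTrace:
    """Session-level z-scored residual signal: the fully processed photometry trace."""

    t_s: np.ndarray
    z: np.ndarray
    sample_rate_hz: float
    diagnostics: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t_s, "z": self.z}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sample_rate_hz: float) -> "ProcessedTrace":
        df = pd.read_csv(path)
        return cls(df["t_s"].to_numpy(), df["z"].to_numpy(), sample_rate_hz)


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Residuals of the OLS fit y ~ a + b*x, plus the fit R^2."""
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    return resid, float(res.rvalue**2)


def demultiplex(session: RawPhotometrySession) -> ChannelPair:
    """Split interleaved frames into paired 405/473 samples.

    Each 473 frame is paired with the immediately preceding 405 frame; the pair
    is stamped with the 473 frame's time. Unpaired leading/trailing laser-on
    frames are dropped (count logged). Two consecutive laser-on frames of the
    same channel raise, naming the offending frame index.
    """
    df = session.frames
    on = df[df["channel"].astype(str) != "off"].reset_index(drop=True)
    if on.empty:
        raise ValueError("session contains no laser-on frames")
    ch = on["channel"].astype(str).to_numpy()
    same = np.flatnonzero(ch[1:] == ch[:-1])
    if same.size:
        i = int(same[0]) + 1
        raise ValueError(
            f"two consecutive {ch[i]} frames at laser-on frame index {i}; "
            "multiplexing alternation violated"
        )
    is405 = ch == "405"
    # pair indices: every 473 frame whose predecessor is a 405 frame
    idx473 = np.flatnonzero(~is405)
    idx473 = idx473[idx473 > 0]
    n_dropped = len(on) - 2 * len(idx473)
    if n_dropped:
        logger.warning("demultiplex: dropped %d unpaired frame(s)", n_dropped)
    if len(idx473) == 0:
        raise ValueError("no complete 405/473 frame pairs in session")
    i405 = idx473 - 1
    return ChannelPair(
        t_s=on["t_s"].to_numpy(float)[idx473],
        s473=on["roi_signal"].to_numpy(float)[idx473],
        s405=on["roi_signal"].to_numpy(float)[i405],
        c473=on["roi_control"].to_numpy(float)[idx473],
        c405=on["roi_control"].to_numpy(float)[i405],
        n_dropped_frames=int(n_dropped),
    )


def subtract_background(pair: ChannelPair, session: RawPhotometrySession) -> ChannelPair:
    """Subtract the mean laser-off (background) intensity from every series.

    The signal-fiber background mean is removed from s473/s405 and the
    control-fiber background mean from c473/c405. Negative values are permitted
    (a warning is issued if the background exceeds the signal anywhere).
    """
    off = session.frames[session.frames["channel"].astype(str) == "off"]
    if off.empty:
        raise ValueError("no laser-off background frames in session")
    bg_sig = float(off["roi_signal"].mean())
    bg_ctl = float(off["roi_control"].mean())
    s473 = pair.s473 - bg_sig
    s405 = pair.s405 - bg_sig
    c473 = pair.c473 - bg_ctl
    c405 = pair.c405 - bg_ctl
    if min(s473.min(), s405.min(), c473.min(), c405.min()) < 0:
        warnings.warn(
            "background exceeds signal in places; negative intensities retained",
            stacklevel=2,
        )
    out = ChannelPair(
        pair.t_s, s473, s405, c473, c405,
        n_dropped_frames=pair.n_dropped_frames, background_subtracted=True,
    )
    out.background_means = (bg_sig, bg_ctl)  # diagnostics, attached ad hoc
    return out


def regress_out_control(pair: ChannelPair, allow_constant_control: bool = False) -> ChannelPair:
    """Regress each excitation channel on its own control-fiber series.

    Ordinary least squares with intercept; the series are replaced by the
    regression residuals, removing the component explained by laser-power
    fluctuation recorded on the control fiber.
    """
    out_s = {}
    r2 = {}
    for name, y, x in (("473", pair.s473, pair.c473), ("405", pair.s405, pair.c405)):
        if np.ptp(x) == 0:
            if allow_constant_control:
                out_s[name] = y - y.mean()
                r2[name] = 0.0
                continue
            raise ValueError(
                f"control series for the {name} channel has zero variance; "
                "pass allow_constant_control=True to fall back to mean-subtraction"
            )
        out_s[name], r2[name] = _ols_residuals(y, x)
    out = ChannelPair(
        pair.t_s, out_s["473"], out_s["405"], pair.c473, pair.c405,
        n_dropped_frames=pair.n_dropped_frames,
        background_subtracted=pair.background_subtracted,
    )
    out.stage1_r2 = r2
    return out


def regress_out_isosbestic(pair: ChannelPair, return_r2: bool = False):
    """Regress the 473 nm residuals on the 405 nm residuals; return the residuals.

    The 405 nm (isosbestic) channel carries motion and other calcium-independent
    artifacts but no calcium transient, so the residual of this regression is the
    artifact-corrected calcium signal. With ``return_r2=True`` returns
    ``(residuals, r_squared)``.
    """
    if np.ptp(pair.s405) == 0:
        raise ValueError("405 nm residual series has zero variance; cannot regress")
    resid, r2 = _ols_residuals(pair.s473, pair.s405)
    return (resid, r2) if return_r2 else resid


def zscore_session(
    residuals: np.ndarray,
    t_s: np.ndarray | None = None,
    sample_rate_hz: float = float("nan"),
) -> ProcessedTrace:
    """Standardize the residual series over the whole session: (x - mean) / sd."""
    x = np.asarray(residuals, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to z-score")
    sd = x.std()
    if sd == 0:
        raise ValueError("constant residual series: zero variance, cannot z-score")
    z = (x - x.mean()) / sd
    if t_s is None:
        t_s = np.arange(x.size, dtype=float)
    return ProcessedTrace(np.asarray(t_s, dtype=float), z, sample_rate_hz)


def _detrend_exponential(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Remove a single-exponential bleaching trend (optional pre-processing)."""
    from scipy.optimize import curve_fit

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    t0 = t - t[0]
    span = max(t0[-1], 1.0)
    try:
        p, _ = curve_fit(
            model, t0, y,
            p0=(max(y[0] - y[-1], 1e-6), span / 2.0, y[-1]),
            maxfev=5000,
        )
        return y - model(t0, *p)
    except RuntimeError:  # fit failed: leave series for the regressions to handle
        return y


def process_session(
    session: RawPhotometrySession,
    detrend: bool = False,
    allow_constant_control: bool = False,
) -> ProcessedTrace:
    """Run the full chain: demultiplex, background-subtract, the two regressions, z-score.

    Bleaching is absorbed by the two intercept-bearing regressions; ``detrend=True``
    additionally removes a fitted single exponential from each channel first
    (off by default — the standard chain does not include it).
    """
    pair = demultiplex(session)
    pair = subtract_background(pair, session)
    if detrend:
        pair = ChannelPair(
            pair.t_s,
            _detrend_exponential(pair.s473, pair.t_s),
            _detrend_exponential(pair.s405, pair.t_s),
            pair.c473, pair.c405,
            n_dropped_frames=pair.n_dropped_frames,
            background_subtracted=True,
        )
    stage1 = regress_out_control(pair, allow_constant_control=allow_constant_control)
    resid, stage2_r2 = regress_out_isosbestic(stage1, return_r2=True)
    trace = zscore_session(resid, t_s=pair.t_s,
                           sample_rate_hz=session.multiplex_rate_per_channel_hz)
    trace.diagnostics = {
        "n_dropped_frames": pair.n_dropped_frames,
        "stage1_r2": getattr(stage1, "stage1_r2", {}),
        "stage2_r2": stage2_r2,
        "background_means": getattr(pair, "background_means", None),
    }
    logger.info("processed session: %s", trace.diagnostics)
    return trace
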