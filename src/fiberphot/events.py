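"""Peri-event alignment and summary statistics on processed photometry traces.

Builds peri-event matrices (trials x lag) of the z-scored signal around
behavioral events, and computes the summary quantities used to compare them:
three-sample window means, window-mean differences, trapezoidal AUC,
trial-count standardization across compared categories, and Pearson
correlations with Fisher-z 95% confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .photometry import ProcessedTrace

logger = logging.getLogger(__name__)


@dataclass
class PeriEventMatrix:
    """Event-aligned z-score rows over a common lag window.

    ``rows[i, j]`` is the z-score of event ``event_ids[i]`` at lag
    ``lags_s[j]``; lag 0 is the sample the event time snapped to.
    """

    lags_s: np.ndarray
    rows: np.ndarray
    event_ids: list
    window: tuple[float, float]
    sample_rate_hz: float
    n_dropped_events: int = 0

    def row_mean(self) -> np.ndarray:
        return self.rows.mean(axis=0)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.rows, columns=[f"{l:.6g}" for l in self.lags_s])
        df.insert(0, "event_id", self.event_ids)
        df.to_csv(path, index=False)


@dataclass
class WindowStat:
    """Mean z over three consecutive samples centered on a target lag."""

    t_center_s: float
    mean_z: float
    n_samples: int = 3


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    p: float


def _snap(times: np.ndarray, target: float) -> int:
    """Index of the sample nearest ``target``; ties break toward the earlier sample."""
    return int(np.argmin(np.abs(np.asarray(times) - target)))


def align(
    trace: ProcessedTrace,
    event_times_s,
    window: tuple[float, float],
) -> PeriEventMatrix:
    """Extract z-score rows around each event over a (pre, post) window.

    Event times are snapped to the nearest trace sample. Events whose window
    would extend beyond the session are dropped and counted; if every event is
    out of bounds an error is raised.
    """
    pre_s, post_s = window
    if pre_s < 0 or post_s < 0 or (pre_s == 0 and post_s == 0):
        raise ValueError("window extents must be positive")
    events = np.asarray(list(event_times_s), dtype=float)
    if events.size == 0:
        raise ValueError("no events to align")
    if np.any(np.diff(events) < 0):
        raise ValueError("event times must be sorted")
    fs = trace.sample_rate_hz
    if not np.isfinite(fs) or fs <= 0:
        fs = 1.0 / float(np.median(np.diff(trace.t_s)))
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    n = trace.z.size
    rows, ids = [], []
    dropped = 0
    for k, te in enumerate(events):
        i = _snap(trace.t_s, te)
        if i - n_pre < 0 or i + n_post >= n:
            dropped += 1
            continue
        rows.append(trace.z[i - n_pre: i + n_post + 1])
        ids.append(k)
    if not rows:
        raise ValueError("every event window falls outside the session")
    if dropped:
        logger.warning("align: dropped %d event(s) with out-of-bounds windows", dropped)
    lags = np.arange(-n_pre, n_post + 1) / fs
    return PeriEventMatrix(lags, np.vstack(rows), ids, (pre_s, post_s), fs, dropped)


def _window_rows(matrix: PeriEventMatrix, t_center_s: float,
                 placement: str = "center") -> tuple[np.ndarray, float]:
    """Per-row three-sample means around the snapped center lag."""
    lags = matrix.lags_s
    i = _snap(lags, t_center_s)
    if placement == "center":
        lo, hi = i - 1, i + 1
    elif placement == "leading":
        lo, hi = i, i + 2
    elif placement == "trailing":
        lo, hi = i - 2, i
    else:
        raise ValueError(f"unknown placement {placement!r}")
    if lo < 0 or hi >= lags.size:
        raise ValueError(
            f"window center {t_center_s:g} s is within one sample of the matrix edge"
        )
    return matrix.rows[:, lo:hi + 1].mean(axis=1), float(lags[i])


def window_mean(matrix: PeriEventMatrix, t_center_s: float,
                placement: str = "center") -> WindowStat:
    """Mean z over three consecutive samples at a target lag, averaged across rows.

    The center snaps to the nearest lag sample (ties toward the earlier lag);
    ``placement`` selects whether the three samples are centered on, start at,
    or end at that sample.
    """
    per_row, t_snap = _window_rows(matrix, t_center_s, placement)
    return WindowStat(t_center_s=t_snap, mean_z=float(per_row.mean()))


def delta_z(matrix: PeriEventMatrix, t0_s: float, t1_s: float,
            placement: str = "center") -> tuple[np.ndarray, float]:
    """Change in the three-sample window mean from t0 to t1, per row and averaged."""
    r0, _ = _window_rows(matrix, t0_s, placement)
    r1, _ = _window_rows(matrix, t1_s, placement)
    d = r1 - r0
    return d, float(d.mean())


def auc(trace: ProcessedTrace, t0_s: float, t1_s: float) -> float:
    """Trapezoidal area under z between the samples nearest t0 and t1 (z*seconds)."""
    if t1_s <= t0_s:
        raise ValueError("AUC bounds reversed: require t0 < t1")
    i0 = _snap(trace.t_s, t0_s)
    i1 = _snap(trace.t_s, t1_s)
    if i1 <= i0:
        raise ValueError("AUC bounds snap to fewer than two samples")
    return float(np.trapezoid(trace.z[i0:i1 + 1], trace.t_s[i0:i1 + 1]))


def standardize_counts(groups: dict, seed: int) -> dict:
    """Equalize the number of rows across compared categories by seeded subsampling.

    Each group is subsampled without replacement down to the smallest group's
    size, so category comparisons average the same number of events or trials.
    Deterministic under a fixed seed.
    """
    if not groups:
        raise ValueError("no groups given")
    sizes = {k: len(v) for k, v in groups.items()}
    if min(sizes.values()) == 0:
        empty = [k for k, n in sizes.items() if n == 0]
        raise ValueError(f"empty group(s): {empty}")
    n_min = min(sizes.values())
    rng = np.random.default_rng(seed)
    out = {}
    for key in groups:
        items = list(groups[key])
        if len(items) == n_min:
            out[key] = items
        else:
            idx = np.sort(rng.choice(len(items), size=n_min, replace=False))
            out[key] = [items[i] for i in idx]
    return out


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided p and Fisher-z 95% confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 4:
        raise ValueError("need at least 4 observations for the Fisher-z interval")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    n = x.size
    if abs(r) >= 1.0:  # degenerate perfect correlation: interval collapses
        lo = hi = r
    else:
        zr = math.atanh(r)
        half = stats.norm.ppf(0.975) / math.sqrt(n - 3)
        lo, hi = math.tanh(zr - half), math.tanh(zr + half)
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, n=n, p=p)
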