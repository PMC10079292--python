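"""Intrinsic electrophysiology features from current-clamp sweeps.

Extracts the standard current-step battery: spike detection, action-potential
(AP) threshold at the dV/dt kink, maximum firing rate from the first six APs of
a 0.5 s step, the accommodation index over the step that elicited maximum
firing, input resistance from a -140 pA hyperpolarizing step, and
post-hyperpolarization rebound bursting. Cells that fall into depolarization
block (firing not sustained through the step) are excluded from accommodation
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

#: dV/dt criterion (mV/ms) defining the AP threshold kink; configurable per call
DVDT_THRESHOLD_MV_PER_MS = 20.0

#: minimum inter-spike separation enforced during detection
REFRACTORY_S = 0.002


@dataclass
class CurrentClampSweep:
    """Uniformly sampled membrane-potential record with a square current step."""

    t_s: np.ndarray
    vm_mv: np.ndarray
    i_pa: np.ndarray
    step_onset_s: float
    step_offset_s: float
    step_amplitude_pa: float

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.vm_mv = np.asarray(self.vm_mv, dtype=float)
        self.i_pa = np.asarray(self.i_pa, dtype=float)
        dt = np.diff(self.t_s)
        if dt.size and np.ptp(dt) > 1e-9 + 1e-6 * float(np.median(dt)):
            raise ValueError("sweep must be uniformly sampled")

    @property
    def fs_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t_s)))

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t_s, "vm_mv": self.vm_mv, "i_pa": self.i_pa}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, step_onset_s, step_offset_s, step_amplitude_pa):
        df = pd.read_csv(path)
        return cls(df["t_s"].to_numpy(), df["vm_mv"].to_numpy(), df["i_pa"].to_numpy(),
                   step_onset_s, step_offset_s, step_amplitude_pa)


@dataclass
class SpikeFeatures:
    """Per-cell intrinsic-property summary row."""

    spike_times_s: list[float]
    ap_threshold_mv: float
    max_rate_hz: float          # NaN when undefined (< 6 APs in every step)
    max_rate_defined: bool
    accommodation_index: float  # NaN when undefined or excluded
    rebound_n_aps: int
    rebound_mean_isi_s: float   # NaN when < 2 rebound APs
    input_resistance_mohm: float
    excluded_depol_block: bool


def detect_spikes(
    sweep: CurrentClampSweep,
    peak_height_mv: float = -10.0,
    dvdt_mv_per_ms: float = DVDT_THRESHOLD_MV_PER_MS,
) -> np.ndarray:
    """Detect action-potential peak times.

    Candidate peaks must exceed ``peak_height_mv``, be separated by at least the
    2 ms refractory period, and be preceded (within 3 ms) by a depolarization
    rate of at least ``dvdt_mv_per_ms`` — rejecting sub-threshold bumps.
    """
    fs = sweep.fs_hz
    distance = max(1, int(round(REFRACTORY_S * fs)))
    idx, _ = find_peaks(sweep.vm_mv, height=peak_height_mv, distance=distance)
    if idx.size == 0:
        return np.array([])
    dvdt = np.gradient(sweep.vm_mv, sweep.t_s) / 1000.0  # mV/ms
    look = max(1, int(round(0.003 * fs)))
    keep = [i for i in idx if np.max(dvdt[max(0, i - look): i + 1]) >= dvdt_mv_per_ms]
    return sweep.t_s[np.asarray(keep, dtype=int)] if keep else np.array([])


def ap_threshold(
    sweep: CurrentClampSweep,
    spike_time_s: float,
    dvdt_mv_per_ms: float = DVDT_THRESHOLD_MV_PER_MS,
    search_window_s: float = 0.005,
) -> float:
    """Membrane potential at the first sample where dV/dt reaches the kink criterion.

    Searches backward from the AP peak within ``search_window_s`` for the first
    sample (in forward time) at which dV/dt >= ``dvdt_mv_per_ms``.
    """
    fs = sweep.fs_hz
    i_peak = int(np.argmin(np.abs(sweep.t_s - spike_time_s)))
    i0 = max(0, i_peak - int(round(search_window_s * fs)))
    dvdt = np.gradient(sweep.vm_mv, sweep.t_s) / 1000.0
    above = np.flatnonzero(dvdt[i0:i_peak + 1] >= dvdt_mv_per_ms)
    if above.size == 0:
        raise ValueError(
            f"dV/dt never reaches {dvdt_mv_per_ms} mV/ms before the peak at "
            f"{spike_time_s:g} s"
        )
    return float(sweep.vm_mv[i0 + above[0]])


def max_firing_rate(step_spike_times_s) -> tuple[float, bool]:
    """Maximum firing rate from the first six APs of a current step.

    Returns ``(rate_hz, defined)``: five inter-spike intervals spanned by the
    first six APs give ``5 / (t6 - t1)`` Hz. With fewer than six APs the rate is
    undefined and ``(nan, False)`` is returned.
    """
    t = np.sort(np.asarray(step_spike_times_s, dtype=float))
    if t.size < 6:
        return math.nan, False
    return float(5.0 / (t[5] - t[0])), True


def max_rate_across_steps(spike_times_per_step: list) -> tuple[float, bool]:
    """Max firing rate computed on the step with the most APs."""
    if not spike_times_per_step:
        return math.nan, False
    best = max(spike_times_per_step, key=len)
    return max_firing_rate(best)


def accommodation_index(isis_s, excluded_depol_block: bool = False) -> float:
    """Spike-frequency accommodation as the mean local contrast of successive ISIs.

    For ISIs (I_1 .. I_N), A = (1/(N-1)) * sum_{i=2..N} (I_i - I_{i-1}) / (I_i + I_{i-1}).
    Positive A means lengthening intervals (adaptation). Requires >= 3 ISIs and a
    sweep not excluded for depolarization block.
    """
    if excluded_depol_block:
        raise ValueError(
            "sweep excluded: depolarization block (firing not sustained through the step)"
        )
    isis = np.asarray(isis_s, dtype=float)
    if isis.size < 3:
        raise ValueError("accommodation index requires at least 3 inter-spike intervals")
    contrasts = (isis[1:] - isis[:-1]) / (isis[1:] + isis[:-1])
    return float(contrasts.mean())


def is_depolarization_block(
    sweep: CurrentClampSweep,
    spike_times_s,
    tail_fraction: float = 0.25,
    vm_block_mv: float = -45.0,
) -> bool:
    """Heuristic flag for sweeps where firing collapses before the step ends.

    Flags a sweep whose spikes stop during the first part of the step while the
    membrane stays depolarized above ``vm_block_mv`` through the final
    ``tail_fraction`` of the step.
    """
    t = np.asarray(spike_times_s, dtype=float)
    on, off = sweep.step_onset_s, sweep.step_offset_s
    in_step = t[(t >= on) & (t <= off)]
    if in_step.size == 0:
        return False
    tail_start = off - tail_fraction * (off - on)
    if in_step.max() >= tail_start:
        return False
    sel = (sweep.t_s >= tail_start) & (sweep.t_s <= off)
    return bool(np.mean(sweep.vm_mv[sel]) > vm_block_mv)


def input_resistance(
    sweep: CurrentClampSweep,
    expected_step_pa: float = -140.0,
    baseline_s: float = 0.1,
    steady_fraction: float = 0.2,
) -> float:
    """Input resistance (MOhm) from the steady-state deflection of a -140 pA step.

    Delta-V is the mean Vm over the last ``steady_fraction`` of the step minus the
    mean over ``baseline_s`` preceding the step onset; Rin = |Delta-V| / |I|.
    """
    if not math.isclose(sweep.step_amplitude_pa, expected_step_pa, rel_tol=1e-6):
        raise ValueError(
            f"expected a {expected_step_pa:g} pA step, sweep has "
            f"{sweep.step_amplitude_pa:g} pA"
        )
    on, off = sweep.step_onset_s, sweep.step_offset_s
    base = (sweep.t_s >= on - baseline_s) & (sweep.t_s < on)
    steady = (sweep.t_s >= off - steady_fraction * (off - on)) & (sweep.t_s < off)
    if not base.any() or not steady.any():
        raise ValueError("sweep lacks baseline or steady-state samples around the step")
    dv_mv = float(np.mean(sweep.vm_mv[steady]) - np.mean(sweep.vm_mv[base]))
    # pA * MOhm = uV, so Rin[MOhm] = dV[mV] / (I[pA] / 1000)
    return abs(dv_mv) / (abs(sweep.step_amplitude_pa) / 1000.0)


def rebound_burst(
    sweep: CurrentClampSweep,
    spike_times_s=None,
    window_s: float = 0.3,
) -> tuple[int, float]:
    """Count post-hyperpolarization rebound APs and their mean inter-spike interval.

    APs within ``window_s`` after step offset (inclusive) are counted; with
    fewer than two APs the mean ISI is NaN. Returns ``(n_aps, mean_isi_s)``.
    """
    if spike_times_s is None:
        spike_times_s = detect_spikes(sweep)
    t = np.asarray(spike_times_s, dtype=float)
    off = sweep.step_offset_s
    sel = t[(t > off) & (t <= off + window_s)]
    if sel.size < 2:
        return int(sel.size), math.nan
    return int(sel.size), float(np.mean(np.diff(sel)))


def extract_features(
    step_sweeps: list[CurrentClampSweep],
    rin_sweep: CurrentClampSweep,
    rebound_sweep: CurrentClampSweep | None = None,
) -> SpikeFeatures:
    """Full per-cell feature battery from a family of depolarizing steps plus a
    -140 pA sweep (and optionally a dedicated rebound sweep, else the Rin sweep).
    """
    spikes_per_step = []
    for sw in step_sweeps:
        st = detect_spikes(sw)
        spikes_per_step.append(st[(st >= sw.step_onset_s) & (st <= sw.step_offset_s)])
    k_best = int(np.argmax([len(s) for s in spikes_per_step])) if spikes_per_step else -1
    best_sweep = step_sweeps[k_best] if k_best >= 0 else None
    best_spikes = spikes_per_step[k_best] if k_best >= 0 else np.array([])

    rate, defined = max_firing_rate(best_spikes) if best_spikes.size else (math.nan, False)
    blocked = (
        is_depolarization_block(best_sweep, best_spikes) if best_sweep is not None else False
    )
    acc = math.nan
    if not blocked and best_spikes.size >= 4:
        acc = accommodation_index(np.diff(best_spikes))
    thr = math.nan
    if best_spikes.size:
        thr = float(np.mean([ap_threshold(best_sweep, t) for t in best_spikes[:3]]))
    reb = rebound_sweep if rebound_sweep is not None else rin_sweep
    n_reb, isi_reb = rebound_burst(reb)
    return SpikeFeatures(
        spike_times_s=best_spikes.tolist(),
        ap_threshold_mv=thr,
        max_rate_hz=rate,
        max_rate_defined=defined,
        accommodation_index=acc,
        rebound_n_aps=n_reb,
        rebound_mean_isi_s=isi_reb,
        input_resistance_mohm=input_resistance(rin_sweep),
        excluded_depol_block=blocked,
    )


def features_to_frame(features: dict) -> pd.DataFrame:
    """Assemble a features.csv table: one row per cell id."""
    rows = []
    for cell_id, f in features.items():
        d = {"cell_id": cell_id, **{k: v for k, v in f.__dict__.items()
                                    if k != "spike_times_s"}}
        d["n_spikes"] = len(f.spike_times_s)
        rows.append(d)
    return pd.DataFrame(rows)
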