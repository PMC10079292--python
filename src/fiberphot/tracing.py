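"""Tract-tracing quantification: area-corrected cell-count ratios across nuclei.

Labeled cells are counted per coronal slice in three thalamic compartments —
CM (central medial), ipsilateral CL (central lateral) and contralateral CL —
and converted to densities (count / area). Two ratios are formed per slice,
CM : ipsilateral CL and ipsilateral CL : contralateral CL, then averaged
across slices within a case and across cases per afferent. A comparison is
flagged "strong" when the two compartments differ by at least 40% of the
larger count, i.e. smaller/larger density <= 0.6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGIONS = ("CM", "CL_ipsi", "CL_contra")

#: smaller/larger density at or below this flags a strong (>=40%) difference
STRONG_DIFFERENCE_MAX_RATIO = 0.6

_RATIO_DEFS = {
    "ratio_cm_ipsicl": ("CM", "CL_ipsi"),
    "ratio_ipsicl_contracl": ("CL_ipsi", "CL_contra"),
}


@dataclass
class TracingCounts:
    """Per-slice labeled-cell counts with section areas.

    ``table`` columns: ``case_id``, ``afferent``, ``slice_index``, ``region``
    (one of CM, CL_ipsi, CL_contra), ``count``, ``area_mm2``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"case_id", "afferent", "slice_index", "region", "count", "area_mm2"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"counts table missing columns: {sorted(missing)}")
        if (self.table["count"] < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.table["area_mm2"] <= 0).any():
            raise ValueError("areas must be positive")
        unknown = set(self.table["region"]) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown regions: {sorted(unknown)}")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TracingCounts":
        return cls(pd.read_csv(path))


@dataclass
class ConnectivitySummary:
    """Case-level mean density ratios and strong-difference flags."""

    case_id: str
    afferent: str
    ratio_cm_ipsicl: float
    ratio_ipsicl_contracl: float
    strong_difference_flags: dict = field(default_factory=dict)
    n_slices: int = 0


def strength_flag(ratio: float) -> bool:
    """Whether a density ratio marks a >=40% difference between compartments.

    Direction-agnostic and boundary-inclusive: true iff min(r, 1/r) <= 0.6,
    equivalently r >= 5/3 or r <= 0.6.
    """
    if not np.isfinite(ratio) or ratio <= 0:
        raise ValueError(f"ratio must be finite and positive, got {ratio!r}")
    return min(ratio, 1.0 / ratio) <= STRONG_DIFFERENCE_MAX_RATIO + 1e-12


def density_ratios(counts: TracingCounts) -> list[ConnectivitySummary]:
    """Per-case mean density ratios, averaged slice-then-case within each afferent.

    Within each slice the density (count/area) ratio is formed for
    CM:ipsilateral CL and ipsilateral CL:contralateral CL; slices with a zero
    denominator density are excluded with a warning. Slice ratios are averaged
    per case; the strong-difference flag is evaluated on the case mean.
    """
    out: list[ConnectivitySummary] = []
    for (case_id, afferent), case_df in counts.table.groupby(["case_id", "afferent"]):
        per_slice: dict[str, list[float]] = {k: [] for k in _RATIO_DEFS}
        n_slices = case_df["slice_index"].nunique()
        for _, sl in case_df.groupby("slice_index"):
            dens = {
                r: sl.loc[sl["region"] == r, "count"].sum()
                / sl.loc[sl["region"] == r, "area_mm2"].sum()
                for r in set(sl["region"])
            }
            for name, (num, den) in _RATIO_DEFS.items():
                if num not in dens or den not in dens:
                    continue
                if dens[den] == 0:
                    warnings.warn(
                        f"case {case_id}: zero {den} density in a slice; "
                        f"slice excluded from {name}",
                        stacklevel=2,
                    )
                    continue
                per_slice[name].append(dens[num] / dens[den])
        if all(len(v) == 0 for v in per_slice.values()):
            raise ValueError(f"case {case_id}: every slice excluded, no ratios computable")
        means = {
            name: float(np.mean(v)) if v else float("nan")
            for name, v in per_slice.items()
        }
        flags = {
            name: strength_flag(m) if np.isfinite(m) else False
            for name, m in means.items()
        }
        out.append(ConnectivitySummary(
            case_id=str(case_id), afferent=str(afferent),
            ratio_cm_ipsicl=means["ratio_cm_ipsicl"],
            ratio_ipsicl_contracl=means["ratio_ipsicl_contracl"],
            strong_difference_flags=flags,
            n_slices=int(n_slices),
        ))
    return out


def summarize_afferent(cases: list[ConnectivitySummary]) -> pd.DataFrame:
    """Per-afferent table of case-mean ratios, strong-difference flags, and case counts.

    Case means are averaged across cases per afferent; the flag is re-evaluated
    on the across-case mean ratio (line-thickness convention of the summary
    diagrams, typically based on two to four cases per afferent).
    """
    if not cases:
        raise ValueError("no cases to summarize")
    rows = []
    df = pd.DataFrame([{
        "afferent": c.afferent,
        "ratio_cm_ipsicl": c.ratio_cm_ipsicl,
        "ratio_ipsicl_contracl": c.ratio_ipsicl_contracl,
    } for c in cases])
    for afferent, sub in df.groupby("afferent"):
        row = {"afferent": afferent, "n_cases": len(sub)}
        for name in _RATIO_DEFS:
            vals = sub[name].dropna()
            m = float(vals.mean()) if len(vals) else float("nan")
            row[name] = m
            row[f"strong_{name}"] = strength_flag(m) if np.isfinite(m) else False
        rows.append(row)
    return pd.DataFrame(rows)
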