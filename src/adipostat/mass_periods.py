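"""Segmentation of seasonal body-mass trajectories.

Morning body mass is smoothed (default smoothing parameter 0.35) and its
first derivative taken on the calendar-day axis.  A bird-specific cut-off
slope — 75% of the maximum derivative — defines the fattening period:
days before it are "breeding", days after are "migration".  Candidate
above-cutoff runs are bridged across short dips (derivative still above half
the cutoff) and the chosen run is extended outward to plateau contact
(derivative back below a quarter of the cutoff), so that the reported
magnitude spans the full ramp rather than just its steepest core.  Birds
whose best candidate gains less than a configurable floor are
"non-fatteners".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import PeriodConfig
from .smoothing import smooth_series

__all__ = [
    "MassTrajectory",
    "PeriodAssignment",
    "FatteningSummary",
    "classify_periods",
    "fattening_summary",
    "apply_manual_adjustment",
]


@dataclass
class MassTrajectory:
    """One bird's morning body-mass series on a calendar-day axis."""

    bird_id: str
    day: np.ndarray
    mass: np.ndarray
    mass_smooth: np.ndarray | None = None
    dmass: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if np.any(np.diff(self.day) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.mass <= 0):
            raise ValueError("mass must be positive")


@dataclass
class PeriodAssignment:
    """Per-day period labels and the fattening window for one bird."""

    bird_id: str
    day: np.ndarray
    labels: np.ndarray                 # breeding | fattening | migration
    cutoff_slope: float
    fattener: bool
    fattening_start: float | None = None
    fattening_end: float | None = None
    mass_smooth: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)
    audit: list[dict] = field(default_factory=list)

    @property
    def magnitude(self) -> float | None:
        if not self.fattener:
            return None
        i0 = int(np.searchsorted(self.day, self.fattening_start))
        i1 = int(np.searchsorted(self.day, self.fattening_end))
        return float(self.mass_smooth[i1] - self.mass_smooth[i0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bird_id": self.bird_id, "day": self.day,
                             "period": self.labels,
                             "mass_smooth": self.mass_smooth})


@dataclass
class FatteningSummary:
    magnitude_g: float
    relative_gain_pct: float
    duration_days: float


def _candidate_runs(dmass: np.ndarray, cutoff: float,
                    cfg: PeriodConfig) -> list[tuple[int, int]]:
    idx = np.flatnonzero(dmass >= cutoff)
    if len(idx) == 0:
        return []
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[brk + 1]].tolist()
    ends = np.r_[idx[brk], idx[-1]].tolist()
    # bridge gaps where the slope never falls below bridge_frac · cutoff
    merged_s, merged_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if np.all(dmass[merged_e[-1]:s] > cfg.bridge_frac * cutoff):
            merged_e[-1] = e
        else:
            merged_s.append(s)
            merged_e.append(e)
    # extend to plateau contact
    out = []
    n = len(dmass)
    for s, e in zip(merged_s, merged_e):
        while s > 0 and dmass[s - 1] > cfg.contact_frac * cutoff:
            s -= 1
        while e < n - 1 and dmass[e + 1] > cfg.contact_frac * cutoff:
            e += 1
        out.append((s, e))
    return out


def classify_periods(traj: MassTrajectory,
                     cfg: PeriodConfig | None = None) -> PeriodAssignment:
    """Label each observed day breeding / fattening / migration."""
    cfg = cfg or PeriodConfig()
    if len(traj.day) < cfg.min_days:
        raise ValueError(f"need at least {cfg.min_days} days of morning masses")
    ms = smooth_series(traj.mass, cfg.span, x=traj.day)
    dm = np.gradient(ms, traj.day)
    traj.mass_smooth, traj.dmass = ms, dm

    labels = np.array(["breeding"] * len(traj.day), dtype=object)
    cutoff = cfg.cutoff_frac * float(dm.max())
    base = dict(bird_id=traj.bird_id, day=traj.day, labels=labels,
                cutoff_slope=cutoff, mass_smooth=ms)

    if dm.max() < cfg.slope_floor:
        return PeriodAssignment(fattener=False, flags=["non_fattener"], **base)

    runs = _candidate_runs(dm, cutoff, cfg)
    gains = [ms[e] - ms[s] for s, e in runs]
    k = int(np.argmax(gains))
    s, e = runs[k]
    flags = []
    if len(runs) > 1:
        flags.append("non_contiguous_candidates")
    if gains[k] < cfg.magnitude_floor:
        return PeriodAssignment(fattener=False,
                                flags=flags + ["non_fattener"], **base)
    labels[s:e + 1] = "fattening"
    labels[e + 1:] = "migration"
    return PeriodAssignment(
        fattener=True, fattening_start=float(traj.day[s]),
        fattening_end=float(traj.day[e]), flags=flags, **base)


def fattening_summary(assign: PeriodAssignment) -> FatteningSummary:
    """Magnitude (g), relative gain (%) and duration (days) of fattening,
    measured on the smoothed trace used for the segmentation."""
    if not assign.fattener:
        raise ValueError("bird is a non-fattener; no fattening summary")
    i0 = int(np.searchsorted(assign.day, assign.fattening_start))
    i1 = int(np.searchsorted(assign.day, assign.fattening_end))
    m0, m1 = assign.mass_smooth[i0], assign.mass_smooth[i1]
    return FatteningSummary(
        magnitude_g=float(m1 - m0),
        relative_gain_pct=100.0 * float(m1 - m0) / float(m0),
        duration_days=float(assign.fattening_end - assign.fattening_start))


def apply_manual_adjustment(assign: PeriodAssignment,
                            bounds: tuple[float, float],
                            note: str) -> PeriodAssignment:
    """Replace the fattening bounds, keeping the originals in an audit trail."""
    start, end = bounds
    if end < start:
        raise ValueError("inverted fattening interval")
    if start < assign.day[0] or end > assign.day[-1]:
        raise ValueError("bounds outside observed days")
    out = replace(assign)
    out.audit = assign.audit + [{
        "original_start": assign.fattening_start,
        "original_end": assign.fattening_end,
        "new_start": float(start), "new_end": float(end), "note": note}]
    out.fattener = True
    out.fattening_start, out.fattening_end = float(start), float(end)
    labels = np.array(["breeding"] * len(assign.day), dtype=object)
    in_run = (assign.day >= start) & (assign.day <= end)
    labels[in_run] = "fattening"
    labels[assign.day > end] = "migration"
    out.labels = labels
    return out
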