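"""Metabolic-state annotation by smoothed-derivative thresholds.

Each minute of an overnight V̇O2 trace is labelled normo-pre / entry /
torpor / arousal / normo-post.  The procedure:

1. Smooth the whole night and locate a *preliminary* arousal point: the first
   minute after the trace's global minimum whose slope exceeds the arousal
   cut-off (default 0.005 mL·min⁻¹·min⁻¹).  This point only needs to fall
   between the end of entry and the arousal peak; it splits the night into a
   pre-arousal and a post-arousal segment that are smoothed separately.
2. On the preliminary slope, find the start of the dominant sustained decline
   below the entry demarcation (−0.003): everything before it is the
   normothermic reference window ("normo-pre").
3. Entry is the contiguous run of pre-segment minutes whose decline magnitude
   exceeds mean + 2·SD of the normo-pre slope magnitudes (the run achieving
   the largest smoothed drop).
4. The stable minutes between entry end and arousal start are torpor; a bout
   is only accepted if this stable level is below half the normothermic
   level (depth gate — protects against false bouts on torpor-free nights).
5. Arousal is the post-segment run whose rise exceeds mean + 5·SD of the
   torpid-phase slope magnitudes, ending at peak V̇O2 (the end of the rise
   run, i.e. the first maximum when the peak plateaus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnnotationConfig
from .smoothing import smooth_with_derivative

__all__ = [
    "StateAnnotation",
    "BoutMetrics",
    "preliminary_arousal_point",
    "annotate_states",
    "torpor_bout_metrics",
    "STATES",
]

STATES = ("normo-pre", "entry", "torpor", "arousal", "normo-post", "none")


@dataclass
class StateAnnotation:
    """Per-minute labels and bout boundaries (minutes since lights-off)."""

    labels: np.ndarray
    torpid: bool
    entry_start: int | None = None
    torpor_start: int | None = None
    arousal_start: int | None = None
    arousal_end: int | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.torpid:
            if not (self.entry_start < self.torpor_start
                    <= self.arousal_start < self.arousal_end):
                raise ValueError("bout boundaries out of order")


@dataclass
class BoutMetrics:
    entry_time_h: float
    entry_fraction: float
    duration_h: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of contiguous True runs."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[brk + 1]]
    ends = np.r_[idx[brk], idx[-1]]
    return list(zip(starts.tolist(), ends.tolist()))


def preliminary_arousal_point(vo2: np.ndarray,
                              cfg: AnnotationConfig | None = None) -> int | None:
    """First minute after the smoothed global minimum whose slope exceeds
    the arousal cut-off; ``None`` if the trace never rises that fast."""
    cfg = cfg or AnnotationConfig()
    y = np.asarray(vo2, dtype=float)
    fit, slope = smooth_with_derivative(y, cfg.span_preliminary)
    gmin = int(np.argmin(fit))
    after = np.arange(gmin + 1, len(y))
    hits = after[slope[after] > cfg.arousal_cutoff]
    return int(hits[0]) if len(hits) else None


def annotate_states(vo2: np.ndarray,
                    cfg: AnnotationConfig | None = None) -> StateAnnotation:
    """Annotate each minute of a night of minute-binned V̇O2.

    Nights with no detectable bout come back with ``torpid=False``, all
    minutes normothermic, and a flag naming the first check that failed.
    """
    cfg = cfg or AnnotationConfig()
    y = np.asarray(vo2, dtype=float)
    n = len(y)
    if n < cfg.min_night_minutes:
        raise ValueError(f"night of {n} min is shorter than the "
                         f"{cfg.min_night_minutes} min minimum")
    if np.any(~np.isfinite(y)):
        raise ValueError("vo2 contains non-finite values; interpolate first")

    labels = np.array(["normo-pre"] * n, dtype=object)

    def no_bout(flag: str) -> StateAnnotation:
        return StateAnnotation(labels=labels, torpid=False, flags=[flag])

    # -- 1. preliminary whole-night smooth and arousal point
    fit0, slope0 = smooth_with_derivative(y, cfg.span_preliminary)
    gmin = int(np.argmin(fit0))
    after = np.arange(gmin + 1, n)
    hits = after[slope0[after] > cfg.arousal_cutoff]
    if len(hits) == 0:
        return no_bout("no_arousal_candidate")
    prelim = int(hits[0])

    # -- 2. entry demarcation: start of the dominant preliminary decline
    dem_runs = _runs(slope0[:prelim] < cfg.entry_demarcation)
    if not dem_runs:
        return no_bout("no_entry_demarcation")
    drops0 = [fit0[s] - fit0[e] for s, e in dem_runs]
    dem0 = dem_runs[int(np.argmax(drops0))][0]
    if dem0 < cfg.min_normo_minutes:
        return no_bout("no_normothermic_reference")

    # -- 3. pre-arousal segment smooth; entry threshold from normo-pre slopes
    fit_a, slope_a = smooth_with_derivative(y[:prelim], cfg.span_segment)
    ref = np.abs(slope_a[:dem0])
    entry_thr = ref.mean() + cfg.entry_k * ref.std()
    entry_runs = _runs((slope_a < 0) & (np.abs(slope_a) > entry_thr))
    entry_runs = [r for r in entry_runs if r[1] >= dem0 - 5]
    if not entry_runs:
        return no_bout("no_entry_run")
    drops = [fit_a[s] - fit_a[e] for s, e in entry_runs]
    entry_start, entry_end = entry_runs[int(np.argmax(drops))]
    torpor_start = entry_end + 1

    # -- 4. depth gate
    normo_level = float(fit_a[:dem0].mean())
    if torpor_start < prelim:
        torpid_level = float(fit_a[torpor_start:prelim].mean())
    else:
        torpid_level = float(fit_a[entry_end])
    if torpid_level > cfg.depth_frac * normo_level:
        return no_bout("shallow_depth")

    # -- 5. post-arousal segment; arousal threshold from torpid slopes
    fit_b, slope_b = smooth_with_derivative(y[prelim:], cfg.span_segment)
    ref_t = np.abs(slope_a[min(torpor_start + 5, prelim):prelim])
    if len(ref_t) < 10:
        ref_t = np.r_[ref_t, np.abs(slope_b[:max(10 - len(ref_t), 5)])]
    arousal_thr = ref_t.mean() + cfg.arousal_k * ref_t.std()
    rise_runs = _runs(slope_b > arousal_thr)
    if not rise_runs:
        return no_bout("no_arousal_run")
    rises = [fit_b[e] - fit_b[s] for s, e in rise_runs]
    sb, eb = rise_runs[int(np.argmax(rises))]
    arousal_start = prelim + sb
    arousal_end = prelim + eb
    if arousal_start <= torpor_start:
        return no_bout("state_order_unresolvable")

    labels[:entry_start] = "normo-pre"
    labels[entry_start:torpor_start] = "entry"
    labels[torpor_start:arousal_start] = "torpor"
    labels[arousal_start:arousal_end + 1] = "arousal"
    labels[arousal_end + 1:] = "normo-post"

    flags: list[str] = []
    # multi-bout check: a second large decline after arousal end
    post_sl = slope_b[eb + 1:]
    post_fit = fit_b[eb + 1:]
    for s2, e2 in _runs((post_sl < 0) & (np.abs(post_sl) > entry_thr)):
        if post_fit[s2] - post_fit[e2] > 0.5 * max(drops):
            flags.append("multi_bout")
            break

    return StateAnnotation(
        labels=labels, torpid=True,
        entry_start=int(entry_start), torpor_start=int(torpor_start),
        arousal_start=int(arousal_start), arousal_end=int(arousal_end),
        flags=flags)


def torpor_bout_metrics(ann: StateAnnotation, night_length_h: float) -> BoutMetrics:
    """Entry time (h), entry fraction of night, and torpor duration (h).

    Duration runs from the start of entry to the start of arousal: the entry
    phase is included, arousal is excluded.
    """
    if not ann.torpid:
        raise ValueError("night has no torpor bout")
    if night_length_h <= 0:
        raise ValueError("night_length_h must be positive")
    entry_h = ann.entry_start / 60.0
    return BoutMetrics(
        entry_time_h=entry_h,
        entry_fraction=entry_h / night_length_h,
        duration_h=(ann.arousal_start - ann.entry_start) / 60.0)
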