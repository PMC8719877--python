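"""Per-night records: composition + annotation + energetics, and the
torpor-use statistics built on them (propensity, adipostat compliance)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import KJ_PER_G_FAT, ComplianceConfig
from .energetics import EnergyLedger, fat_content_at_entry
from .state_annotation import StateAnnotation, torpor_bout_metrics

__all__ = [
    "BodyComposition",
    "NightRecord",
    "build_night_record",
    "records_to_frame",
    "torpor_propensity",
    "adipostat_compliance",
]


@dataclass
class BodyComposition:
    """Evening and morning QMR scans for one bird-night (replicate means)."""

    evening_mass: float
    evening_fat: float
    evening_lean: float
    morning_mass: float
    morning_fat: float
    morning_lean: float
    n_scans: int = 3

    def __post_init__(self) -> None:
        for tag in ("evening", "morning"):
            mass = getattr(self, f"{tag}_mass")
            fat = getattr(self, f"{tag}_fat")
            lean = getattr(self, f"{tag}_lean")
            if fat + lean > mass * 1.02:  # small scan-noise allowance
                raise ValueError(f"{tag} fat + lean exceeds body mass")

    @property
    def evening_fat_content(self) -> float:
        return 100.0 * self.evening_fat / self.evening_mass

    @property
    def morning_fat_content(self) -> float:
        return 100.0 * self.morning_fat / self.morning_mass


@dataclass
class NightRecord:
    """One bird-night, the tidy unit consumed by the statistical models."""

    bird_id: str
    date: str
    period: str
    night_length_h: float
    evening_fat_content: float
    torpid: bool
    total_energy_kj: float
    overnight_fat_loss_mg: float
    food_consumed_day_kj: float | None = None
    entry_time_h: float | None = None
    entry_fraction: float | None = None
    torpor_duration_h: float | None = None
    fat_at_entry_pct: float | None = None
    pre_torpor_energy_kj: float | None = None
    #: per-minute instantaneous fat content (% morning mass), optional
    fat_content_series: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


def build_night_record(comp: BodyComposition, ann: StateAnnotation,
                       ledger: EnergyLedger, meta: dict) -> NightRecord:
    """Assemble a night record; ``meta`` needs bird_id, date, night_length_h
    and optionally period and food_consumed_day_kj."""
    bird_id = meta["bird_id"]
    if "bird_id" in getattr(ledger, "meta", {}):  # pragma: no cover
        if ledger.meta["bird_id"] != bird_id:
            raise ValueError("bird id mismatch between ledger and metadata")
    night_h = float(meta["night_length_h"])
    total_kj = float(ledger.e_cum[-1])
    rec = NightRecord(
        bird_id=bird_id, date=meta.get("date", ""),
        period=meta.get("period", ""), night_length_h=night_h,
        evening_fat_content=comp.evening_fat_content,
        torpid=ann.torpid, total_energy_kj=total_kj,
        overnight_fat_loss_mg=total_kj / KJ_PER_G_FAT * 1000.0,
        food_consumed_day_kj=meta.get("food_consumed_day_kj"),
        fat_content_series=ledger.fat_content_inst,
        flags=list(ann.flags) + list(ledger.flags))
    if ann.torpid:
        bm = torpor_bout_metrics(ann, night_h)
        pre_kj = float(np.interp(ann.entry_start, ledger.t_min, ledger.e_cum))
        rec.entry_time_h = bm.entry_time_h
        rec.entry_fraction = bm.entry_fraction
        rec.torpor_duration_h = bm.duration_h
        rec.pre_torpor_energy_kj = pre_kj
        rec.fat_at_entry_pct = fat_content_at_entry(
            ledger.evening_fat, pre_kj, ledger.morning_mass)
    return rec


_FRAME_COLS = [
    "bird_id", "date", "period", "night_length_h", "evening_fat_content",
    "torpid", "entry_time_h", "entry_fraction", "torpor_duration_h",
    "fat_at_entry_pct", "pre_torpor_energy_kj", "total_energy_kj",
    "overnight_fat_loss_mg", "food_consumed_day_kj",
]


def records_to_frame(records: list[NightRecord]) -> pd.DataFrame:
    """Tidy NightRecord table (one row per bird-night)."""
    return pd.DataFrame([{c: getattr(r, c) for c in _FRAME_COLS}
                         for r in records])


def torpor_propensity(records: list[NightRecord] | pd.DataFrame) -> pd.DataFrame:
    """Percent of focal nights with torpor, per bird × period, plus the
    cohort mean ± SE across birds within each period."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        warnings.warn("no nights; propensity undefined", stacklevel=2)
        return pd.DataFrame(columns=["period", "bird_id", "propensity_pct",
                                     "n_nights"])
    per_bird = (df.groupby(["period", "bird_id"], as_index=False)
                  .agg(n_nights=("torpid", "size"),
                       propensity_pct=("torpid", lambda s: 100.0 * s.mean())))
    cohort = (per_bird.groupby("period")["propensity_pct"]
              .agg(mean="mean",
                   se=lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1
                   else np.nan,
                   n_birds="size").reset_index())
    per_bird.attrs["cohort"] = cohort
    return per_bird


def adipostat_compliance(records: list[NightRecord],
                         cfg: ComplianceConfig | None = None) -> pd.DataFrame:
    """Classify each night against the two-clause adipostat rule.

    A torpid night complies when its fat content at entry lies within the
    tolerance band of the threshold.  A normothermic night complies when its
    instantaneous fat content either never reaches the threshold or first
    reaches it after the late-night cut-off (default 75% of the night).
    Returns the per-night table; the overall rate is in
    ``result.attrs["compliance_rate"]``.
    """
    cfg = cfg or ComplianceConfig()
    rows = []
    for rec in records:
        if rec.torpid:
            if rec.fat_at_entry_pct is None:
                raise ValueError(f"torpid night {rec.bird_id}/{rec.date} "
                                 "lacks fat_at_entry_pct")
            compliant = abs(rec.fat_at_entry_pct - cfg.threshold_pct) \
                <= cfg.band_pct
            reason = ("entered_at_threshold" if compliant
                      else "entered_off_threshold")
        else:
            if rec.fat_content_series is None:
                raise ValueError(f"night {rec.bird_id}/{rec.date} lacks an "
                                 "instantaneous fat-content series")
            series = np.asarray(rec.fat_content_series, dtype=float)
            below = np.flatnonzero(series <= cfg.threshold_pct)
            if len(below) == 0:
                compliant, reason = True, "threshold_not_reached"
            else:
                cross_frac = below[0] / (rec.night_length_h * 60.0)
                compliant = cross_frac >= cfg.late_cutoff
                reason = ("crossed_late" if compliant else
                          "crossed_early_no_torpor")
        rows.append({"bird_id": rec.bird_id, "date": rec.date,
                     "period": rec.period, "torpid": rec.torpid,
                     "compliant": compliant, "reason": reason})
    out = pd.DataFrame(rows)
    out.attrs["compliance_rate"] = float(out["compliant"].mean()) if len(out) \
        else np.nan
    out.attrs["config"] = cfg
    return out
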