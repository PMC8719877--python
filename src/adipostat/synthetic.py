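"""Ground-truthed simulators for every pipeline stage.

The night simulator builds a true minute-level V̇O2 profile from a torpor
decision rule and a fat ledger (fat burn = energy/37 kJ·g⁻¹), optionally
expands it to a 1-s gas trace through the steady-state chamber balance, and
emits evening/morning body compositions consistent with the integrated
energy expenditure plus QMR replicate noise.

Default rates are anchored to the study conditions they emulate: a
normothermic bird at 20 °C burns ≈0.60 mL O2·min⁻¹ (≈11.8 J·min⁻¹ at
RER 0.71, ≈191 mg fat per 10-h night) and a torpid bird ≈10% of that, so
each hour of torpor spares ≈17 mg of fat.

The season simulator lays a breeding plateau → fattening ramp → migration
plateau mass trajectory per bird (plus non-fatteners), switches the torpor
decision rule from an adipostat threshold (breeding) to a fixed normothermic
period followed by torpor (fattening/migration), and stores full ground
truth alongside every emitted table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .config import (
    FICO2_DEFAULT,
    FIO2_DEFAULT,
    KJ_PER_G_FAT,
    OXYJOULE_INTERCEPT,
    OXYJOULE_SLOPE,
    STP_PRESSURE_KPA,
    STP_TEMP_C,
)
from .night_metrics import BodyComposition
from .respirometry import GasTrace

__all__ = [
    "NightSimConfig",
    "SeasonSimConfig",
    "chamber_fractions",
    "simulate_night",
    "simulate_season",
    "simulate_regression_cohort",
    "night_record_from_truth",
]


def chamber_fractions(vo2, vco2, fri, fio2: float = FIO2_DEFAULT,
                      fico2: float = FICO2_DEFAULT):
    """Forward steady-state chamber balance: rates → excurrent fractions.

    FR_e = FR_i − V̇O2 + V̇CO2; FeO2 = (FR_i·FiO2 − V̇O2)/FR_e;
    FeCO2 = (FR_i·FiCO2 + V̇CO2)/FR_e.  This is the independent oracle the
    analysis-side inversion is tested against.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    fre = fri - vo2 + vco2
    feo2 = (fri * fio2 - vo2) / fre
    feco2 = (fri * fico2 + vco2) / fre
    return feo2, feco2


@dataclass
class NightSimConfig:
    """One simulated overnight respirometry trial."""

    night_length_h: float = 10.0
    normo_vo2: float = 0.60            # mL·min⁻¹
    torpid_vo2: float = 0.06
    entry_ramp_min: int = 30
    arousal_ramp_min: int = 20
    arousal_peak_vo2: float = 0.90
    #: arousal completes this many minutes before lights-on
    arousal_lead_min: int = 40
    rer_start: float = 0.85            # declines linearly to rer_end ...
    rer_end: float = 0.71
    rer_decline_min: int = 120         # ... over this many minutes
    noise_frac: float = 0.02           # noise SD as a fraction of ...
    noise_mode: str = "proportional"   # ... instantaneous level, or of the
                                       # normothermic level ("absolute")
    decision: dict = field(default_factory=lambda: {
        "kind": "adipostat", "threshold_pct": 5.0, "late_cutoff": 0.75})
    evening_mass: float = 2.95         # g
    evening_fat: float = 0.25
    qmr_fat_sd: float = 0.01           # per-scan replicate SD, g
    qmr_lean_sd: float = 0.03
    #: body mass not resolved into fat or lean by the scan (g)
    qmr_residual_g: float = 0.05
    n_scans: int = 4
    flow_ml_min: float = 150.0         # STP-corrected incurrent flow
    tair_c: float = 20.0
    bp_kpa: float = 101.325
    wvp_kpa: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.torpid_vo2 >= self.normo_vo2:
            raise ValueError("torpid V̇O2 must be below normothermic")
        n = self.night_length_h * 60
        if self.entry_ramp_min >= n or self.arousal_ramp_min >= n:
            raise ValueError("transition ramps exceed night length")
        thr = self.decision.get("threshold_pct")
        if thr is not None and not 0 < thr < 50:
            raise ValueError("adipostat threshold must be in (0, 50)%")


def _rer_profile(cfg: NightSimConfig, n: int) -> np.ndarray:
    t = np.arange(n, dtype=float)
    frac = np.clip(t / max(cfg.rer_decline_min, 1), 0.0, 1.0)
    return cfg.rer_start + (cfg.rer_end - cfg.rer_start) * frac


def _decide_entry(cfg: NightSimConfig, n: int, rer: np.ndarray
                  ) -> tuple[int | None, dict]:
    """Minute of torpor entry under the configured decision rule."""
    rule = cfg.decision
    kind = rule["kind"]
    info: dict[str, Any] = {"rule": kind}
    if kind == "never":
        return None, info
    if kind == "always_at":
        return int(rule["t_h"] * 60), info
    if kind == "fixed_normo":
        t = int(rule["normo_h"] * 60)
        return (t if t < n - cfg.arousal_lead_min - cfg.arousal_ramp_min - 30
                else None), info
    if kind != "adipostat":
        raise ValueError(f"unknown decision rule {kind!r}")
    thr_pct = rule.get("threshold_pct", 5.0)
    late = rule.get("late_cutoff", 0.75)
    # fat trajectory under normothermy-until-entry; morning mass depends on
    # the night total, which depends on entry, so fixed-point iterate
    e_rate_n = (OXYJOULE_INTERCEPT + OXYJOULE_SLOPE * rer) * cfg.normo_vo2
    e_cum_n = np.cumsum(e_rate_n) / 1000.0            # kJ at each minute end
    fat_n = cfg.evening_fat - e_cum_n / KJ_PER_G_FAT
    morning_mass = cfg.evening_mass - 0.19            # initial guess
    entry: int | None = None
    for _ in range(3):
        thr_g = thr_pct / 100.0 * morning_mass
        below = np.flatnonzero(fat_n <= thr_g)
        entry = int(below[0]) if len(below) else None
        if entry is not None and entry >= late * n:
            entry = None
        # total burn given this decision (torpid tail burns ~10% of normo)
        if entry is None:
            total_kj = e_cum_n[-1]
        else:
            torpid_rate = e_rate_n[-1] * cfg.torpid_vo2 / cfg.normo_vo2
            total_kj = e_cum_n[entry] + torpid_rate * (n - entry) / 1000.0
        morning_mass = cfg.evening_mass - total_kj / KJ_PER_G_FAT
    info.update(threshold_pct=thr_pct, late_cutoff=late,
                morning_mass_est=morning_mass)
    return entry, info


def simulate_night(cfg: NightSimConfig, *, emit_gas: bool = True,
                   violate: bool = False, rng: np.random.Generator | None = None
                   ) -> tuple[GasTrace | None, BodyComposition, dict]:
    """Simulate one bird-night; returns (gas trace, composition, truth).

    ``truth`` carries the noiseless minute profile, a noisy minute V̇O2
    series (``vo2_minute``) for fast minute-level pipelines, state
    boundaries, the instantaneous fat ledger and the pre-noise compositions.
    ``violate=True`` flips the decision (used for compliance-rate studies).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = int(round(cfg.night_length_h * 60))
    rer = _rer_profile(cfg, n)
    entry, info = _decide_entry(cfg, n, rer)

    if violate:
        if entry is not None:
            entry = None                       # crossed early, refused torpor
            info["violation"] = "skipped_torpor"
        else:
            entry = int(rng.uniform(0.2, 0.5) * n)
            info["violation"] = "entered_high_fat"

    vo2 = np.full(n, cfg.normo_vo2)
    labels = np.array(["normo-pre"] * n, dtype=object)
    truth: dict[str, Any] = {"torpid": False, "decision": info,
                             "night_length_h": cfg.night_length_h}
    if entry is not None:
        torpor_start = min(entry + cfg.entry_ramp_min, n - 1)
        arousal_end = n - cfg.arousal_lead_min
        arousal_start = arousal_end - cfg.arousal_ramp_min
        if torpor_start + 10 < arousal_start:
            vo2[entry:torpor_start] = np.linspace(
                cfg.normo_vo2, cfg.torpid_vo2, torpor_start - entry)
            vo2[torpor_start:arousal_start] = cfg.torpid_vo2
            vo2[arousal_start:arousal_end] = np.linspace(
                cfg.torpid_vo2, cfg.arousal_peak_vo2,
                arousal_end - arousal_start)
            vo2[arousal_end:] = cfg.arousal_peak_vo2
            labels[entry:torpor_start] = "entry"
            labels[torpor_start:arousal_start] = "torpor"
            labels[arousal_start:arousal_end] = "arousal"
            labels[arousal_end:] = "normo-post"
            truth.update(torpid=True, entry_start=entry,
                         torpor_start=torpor_start,
                         arousal_start=arousal_start,
                         arousal_end=arousal_end - 1)

    vco2 = rer * vo2
    e_rate = (OXYJOULE_INTERCEPT + OXYJOULE_SLOPE * rer) * vo2   # J·min⁻¹
    e_cum = np.cumsum(e_rate) / 1000.0                           # kJ
    fat_inst = cfg.evening_fat - e_cum / KJ_PER_G_FAT
    if np.any(fat_inst < 0):
        truth["flags"] = ["fat_depleted"]
    morning_fat = float(fat_inst[-1])
    morning_mass = cfg.evening_mass - (cfg.evening_fat - morning_fat)
    evening_lean = cfg.evening_mass - cfg.evening_fat - cfg.qmr_residual_g

    truth.update(labels=labels, vo2_profile=vo2, rer=rer, e_rate=e_rate,
                 e_cum=e_cum, fat_inst=fat_inst,
                 fat_content_inst=100.0 * fat_inst / morning_mass,
                 evening_mass=cfg.evening_mass, evening_fat=cfg.evening_fat,
                 morning_mass=morning_mass, morning_fat=morning_fat)

    noise_level = vo2 if cfg.noise_mode == "proportional" \
        else np.full(n, cfg.normo_vo2)
    vo2_noisy = vo2 + cfg.noise_frac * noise_level * rng.standard_normal(n)
    truth["vo2_minute"] = np.clip(vo2_noisy, 0.0, None)

    def scan_mean(value: float, sd: float) -> float:
        return float(value + rng.normal(0.0, sd, cfg.n_scans).mean())

    comp = BodyComposition(
        evening_mass=scan_mean(cfg.evening_mass, cfg.qmr_fat_sd + cfg.qmr_lean_sd),
        evening_fat=scan_mean(cfg.evening_fat, cfg.qmr_fat_sd),
        evening_lean=scan_mean(evening_lean, cfg.qmr_lean_sd),
        morning_mass=scan_mean(morning_mass, cfg.qmr_fat_sd + cfg.qmr_lean_sd),
        morning_fat=scan_mean(morning_fat, cfg.qmr_fat_sd),
        morning_lean=scan_mean(evening_lean, cfg.qmr_lean_sd),
        n_scans=cfg.n_scans)

    gas = None
    if emit_gas:
        t_s = np.arange(n * 60, dtype=float)
        vo2_s = np.interp(t_s / 60.0, np.arange(n, dtype=float), vo2)
        vco2_s = np.interp(t_s / 60.0, np.arange(n, dtype=float), vco2)
        level_s = vo2_s if cfg.noise_mode == "proportional" \
            else np.full(len(t_s), cfg.normo_vo2)
        noise = cfg.noise_frac * level_s * rng.standard_normal(len(t_s))
        vo2_s = np.clip(vo2_s + noise, 0.0, None)
        vco2_s = np.clip(vco2_s + noise * (vco2_s / np.maximum(vo2_s, 1e-9)),
                         0.0, None)
        feo2, feco2 = chamber_fractions(vo2_s, vco2_s, cfg.flow_ml_min)
        # ambient metered flow chosen so that STP correction recovers the
        # configured dry-STP flow
        t_ref_k = STP_TEMP_C + 273.15
        factor = ((cfg.bp_kpa - cfg.wvp_kpa) / cfg.bp_kpa) \
            * (cfg.bp_kpa / STP_PRESSURE_KPA) \
            * (t_ref_k / (cfg.tair_c + 273.15))
        gas = GasTrace(
            bird_id="sim", date="", t=t_s, FeO2=feo2, FeCO2=feco2,
            flow=np.full(len(t_s), cfg.flow_ml_min / factor),
            wvp=np.full(len(t_s), cfg.wvp_kpa),
            bp=np.full(len(t_s), cfg.bp_kpa),
            tair=np.full(len(t_s), cfg.tair_c),
            lights_on_t=float(n * 60))
    return gas, comp, truth


# ---------------------------------------------------------------------------
# Season-scale simulation
# ---------------------------------------------------------------------------

@dataclass
class SeasonSimConfig:
    """A summer-long cohort: mass trajectories plus focal respirometry nights."""

    n_birds: int = 16
    n_fatteners: int = 13
    study_days: int = 120
    breeding_mass_mean: float = 2.77
    breeding_mass_sd: float = 0.15
    gain_range: tuple[float, float] = (0.34, 0.90)
    ramp_days_range: tuple[int, int] = (6, 18)
    fattening_start_range: tuple[int, int] = (72, 98)
    #: plateau noise is kept below half the slowest ramp slope so that the
    #: derivative-threshold segmentation operates in its designed regime
    daily_mass_sd: float = 0.008
    focal_interval_days: int = 7
    #: night length drifts from 9 h (day 0) to 12 h (last day)
    night_length_range_h: tuple[float, float] = (9.0, 12.0)
    breeding_fat_pct: tuple[float, float] = (9.0, 2.5)    # mean, sd
    migration_fat_pct: tuple[float, float] = (33.0, 3.0)
    #: fixed normothermic period before torpor outside breeding, hours
    fixed_normo_h: tuple[float, float] = (4.0, 0.5)
    #: night-to-night variation of the metabolic levels (SD, mL·min⁻¹)
    normo_vo2_sd: float = 0.04
    torpid_vo2_sd: float = 0.006
    #: migration propensity logit: intercept at mean fat/11-h night, slopes
    propensity_logit: tuple[float, float, float] = (0.62, 0.26, 0.9)
    violation_rate: float = 0.0
    seed: int = 0


def _night_cfg(base: NightSimConfig, **kw) -> NightSimConfig:
    return replace(base, **kw)


def simulate_season(cfg: SeasonSimConfig,
                    night_base: NightSimConfig | None = None,
                    *, emit_gas: bool = False) -> dict:
    """Simulate a cohort; returns masses table, per-night inputs and truth.

    Returns a dict with ``masses`` (bird_id, day, mass), ``nights`` (list of
    per-night dicts: bird_id, day, period, night config, composition, truth)
    and ``truth`` (per-bird period bounds and fattener status).
    """
    rng = np.random.default_rng(cfg.seed)
    night_base = night_base or NightSimConfig()
    nl0, nl1 = cfg.night_length_range_h

    mass_rows, nights, bird_truth = [], [], {}
    for b in range(cfg.n_birds):
        bird = f"bird{b:02d}"
        fattener = b < cfg.n_fatteners
        base = float(rng.normal(cfg.breeding_mass_mean, cfg.breeding_mass_sd))
        gain = float(rng.uniform(*cfg.gain_range)) if fattener else 0.0
        ramp = int(rng.integers(cfg.ramp_days_range[0],
                                cfg.ramp_days_range[1] + 1))
        start = int(rng.integers(*cfg.fattening_start_range))
        end = min(start + ramp, cfg.study_days - 16)
        days = np.arange(cfg.study_days)
        mass = np.full(cfg.study_days, base)
        if fattener:
            on_ramp = (days >= start) & (days <= end)
            mass[on_ramp] = base + gain * (days[on_ramp] - start) / (end - start)
            mass[days > end] = base + gain
        mass_obs = mass + rng.normal(0.0, cfg.daily_mass_sd, cfg.study_days)
        for d in days:
            mass_rows.append({"bird_id": bird, "day": int(d),
                              "mass": float(mass_obs[d])})
        bird_truth[bird] = {"fattener": fattener, "base_mass": base,
                            "gain": gain, "fattening_start": start if fattener else None,
                            "fattening_end": end if fattener else None}

        offset = int(rng.integers(0, cfg.focal_interval_days))
        for d in range(offset, cfg.study_days, cfg.focal_interval_days):
            period = ("breeding" if (not fattener or d < start) else
                      "fattening" if d <= end else "migration")
            night_h = nl0 + (nl1 - nl0) * d / (cfg.study_days - 1)
            ev_mass = float(mass[d] + rng.normal(0.15, 0.04))
            if period == "breeding":
                fat_pct = rng.normal(*cfg.breeding_fat_pct)
                fat_pct = float(np.clip(fat_pct, 5.5, 16.0))
                decision = {"kind": "adipostat", "threshold_pct": 5.0,
                            "late_cutoff": 0.75}
                violate = bool(rng.random() < cfg.violation_rate)
            else:
                mf, sf = cfg.migration_fat_pct
                if period == "fattening":
                    w = (d - start) / max(end - start, 1)
                    mf = cfg.breeding_fat_pct[0] * (1 - w) + mf * w
                fat_pct = float(np.clip(rng.normal(mf, sf), 8.0, 42.0))
                a0, a_fat, a_night = cfg.propensity_logit
                logit = a0 + a_fat * (fat_pct - mf) \
                    + a_night * (night_h - 11.0)
                if rng.random() < 1.0 / (1.0 + np.exp(-logit)):
                    normo_h = float(np.clip(rng.normal(*cfg.fixed_normo_h),
                                            1.5, night_h - 2.0))
                    decision = {"kind": "fixed_normo", "normo_h": normo_h}
                else:
                    decision = {"kind": "never"}
                violate = False
            normo = float(np.clip(
                rng.normal(night_base.normo_vo2, cfg.normo_vo2_sd), 0.4, 0.8))
            torpid = float(np.clip(
                rng.normal(night_base.torpid_vo2, cfg.torpid_vo2_sd),
                0.03, 0.25 * normo))
            ncfg = _night_cfg(
                night_base, night_length_h=round(night_h, 2),
                normo_vo2=normo, torpid_vo2=torpid,
                arousal_peak_vo2=1.5 * normo,
                evening_mass=ev_mass,
                evening_fat=float(fat_pct / 100.0 * ev_mass),
                decision=decision,
                seed=int(rng.integers(0, 2**31 - 1)))
            gas, comp, truth = simulate_night(ncfg, emit_gas=emit_gas,
                                              violate=violate, rng=rng)
            nights.append({"bird_id": bird, "day": int(d), "period": period,
                           "night_length_h": night_h, "config": ncfg,
                           "gas": gas, "composition": comp, "truth": truth})

    return {"masses": pd.DataFrame(mass_rows), "nights": nights,
            "truth": bird_truth}


# ---------------------------------------------------------------------------
# Regression-level cohorts for estimator calibration
# ---------------------------------------------------------------------------

def simulate_regression_cohort(kind: str, n_birds: int = 13,
                               nights_per_bird: int = 10,
                               seed: int = 0) -> pd.DataFrame:
    """Night-record tables with known regression structure.

    ``kind``:

    - ``"breeding_duration_fat"`` — torpor duration declines 0.63 h per
      percentage point of evening fat, with bird random intercepts.
    - ``"migration_duration_night"`` — duration rises 1.18 h per hour of
      night length; evening fat has no effect.
    - ``"fat_loss_duration"`` — overnight fat loss follows the mechanistic
      energy ledger (normothermic 0.708 kJ·h⁻¹ vs torpid 0.0708), giving a
      −17.2 mg·h⁻¹ slope against torpor duration.
    - ``"null"`` — no fixed effects; bird intercepts and noise only.
    """
    rng = np.random.default_rng(seed)
    m = n_birds * nights_per_bird
    bird = np.repeat([f"bird{i:02d}" for i in range(n_birds)], nights_per_bird)
    b = np.repeat(rng.normal(0.0, 0.5, n_birds), nights_per_bird)
    night_h = rng.uniform(9.0, 12.0, m)
    if kind == "breeding_duration_fat":
        fat = rng.normal(9.0, 2.5, m)
        dur = 10.5 - 0.63 * fat + b + rng.normal(0.0, 0.5, m)
        truth = {"evening_fat_content": -0.63}
    elif kind == "migration_duration_night":
        fat = rng.normal(33.0, 3.0, m)
        night_h = rng.uniform(10.0, 12.0, m)
        dur = -6.0 + 1.18 * night_h + b + rng.normal(0.0, 0.5, m)
        truth = {"night_length_h": 1.18, "evening_fat_content": 0.0}
    elif kind == "fat_loss_duration":
        fat = rng.normal(9.0, 2.5, m)
        dur = rng.uniform(2.0, 8.0, m)
        e_normo_kj_h = 0.708
        loss = (e_normo_kj_h * (night_h - dur) + 0.1 * e_normo_kj_h * dur) \
            / KJ_PER_G_FAT * 1000.0
        loss = loss + b * 5.0 + rng.normal(0.0, 5.0, m)
        truth = {"torpor_duration_h": -0.9 * e_normo_kj_h / KJ_PER_G_FAT * 1000.0}
        df = pd.DataFrame({"bird_id": bird, "evening_fat_content": fat,
                           "night_length_h": night_h, "torpor_duration_h": dur,
                           "overnight_fat_loss_mg": loss})
        df.attrs["truth"] = truth
        return df
    elif kind == "null":
        fat = rng.normal(9.0, 2.5, m)
        dur = 5.0 + b + rng.normal(0.0, 0.5, m)
        truth = {"evening_fat_content": 0.0}
    else:
        raise ValueError(f"unknown cohort kind {kind!r}")
    df = pd.DataFrame({"bird_id": bird, "evening_fat_content": fat,
                       "night_length_h": night_h, "torpor_duration_h": dur})
    df.attrs["truth"] = truth
    return df


def night_record_from_truth(truth: dict, bird_id: str = "sim",
                            date: str = "", period: str = "breeding"):
    """Build a noise-free :class:`NightRecord` straight from simulator truth.

    Used to evaluate decision-rule properties (e.g. adipostat compliance)
    without measurement error from the annotation/QMR chain.
    """
    from .night_metrics import NightRecord
    n = len(truth["fat_content_inst"])
    torpid = bool(truth["torpid"])
    rec = NightRecord(
        bird_id=bird_id, date=date, period=period,
        night_length_h=truth["night_length_h"],
        evening_fat_content=100.0 * truth["evening_fat"]
        / truth["evening_mass"],
        torpid=torpid,
        total_energy_kj=float(truth["e_cum"][-1]),
        overnight_fat_loss_mg=float(truth["e_cum"][-1]) / KJ_PER_G_FAT * 1e3,
        fat_content_series=truth["fat_content_inst"])
    if torpid:
        e = int(truth["entry_start"])
        rec.entry_time_h = e / 60.0
        rec.entry_fraction = e / n
        rec.torpor_duration_h = (truth["arousal_start"] - e) / 60.0
        rec.pre_torpor_energy_kj = float(truth["e_cum"][e])
        rec.fat_at_entry_pct = float(truth["fat_content_inst"][e])
    return rec
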