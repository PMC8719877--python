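"""Seeded recovery sweeps: how well does the analysis chain recover the
generator's ground truth?

Every sweep here is pure computation from a seed — these functions back both
the acceptance test-suite and ``scripts/acceptance.py``.  Problem sizes
default to a few hundred simulated nights/trajectories, which measures the
recovery rates to a couple of percentage points.
"""

from __future__ import annotations

import numpy as np

from .config import AnnotationConfig, ComplianceConfig, PeriodConfig
from .mass_periods import MassTrajectory, classify_periods, fattening_summary
from .night_metrics import adipostat_compliance
from .respirometry import GasTrace, compute_gas_exchange
from .state_annotation import annotate_states
from .stats_models import fit_mixed
from .synthetic import (
    NightSimConfig,
    SeasonSimConfig,
    chamber_fractions,
    night_record_from_truth,
    simulate_night,
    simulate_regression_cohort,
    simulate_season,
)

__all__ = [
    "gas_roundtrip_error",
    "annotation_recovery",
    "false_bout_rate",
    "period_recovery",
    "fattener_split_recovery",
    "compliance_rate",
    "slope_recovery",
    "type_one_error_rate",
]


def gas_roundtrip_error(n: int = 1000, seed: int = 0) -> float:
    """Max |error| of forward chamber oracle → mass-balance inversion."""
    rng = np.random.default_rng(seed)
    vo2 = rng.uniform(0.01, 2.0, n)
    vco2 = vo2 * rng.uniform(0.71, 1.0, n)
    fri = rng.uniform(100.0, 500.0, n)
    feo2, feco2 = chamber_fractions(vo2, vco2, fri)
    tr = GasTrace(bird_id="sweep", date="", t=np.arange(n, dtype=float),
                  FeO2=feo2, FeCO2=feco2, flow=fri, wvp=0.0, bp=101.325,
                  tair=0.0, lights_on_t=float(n), stp_corrected=True)
    mt = compute_gas_exchange(tr, bin_minutes=False)
    return float(max(np.max(np.abs(mt.vo2 - vo2)),
                     np.max(np.abs(mt.vco2 - vco2))))


def _random_bout_cfg(rng: np.random.Generator) -> NightSimConfig:
    night_h = rng.uniform(9.0, 12.0)
    normo = rng.uniform(0.5, 0.7)
    lead = int(rng.integers(35, 70))
    a_ramp = int(rng.integers(15, 31))
    entry_latest = night_h - (lead + a_ramp + 90) / 60.0
    return NightSimConfig(
        night_length_h=night_h,
        normo_vo2=normo,
        torpid_vo2=float(rng.uniform(0.05, 0.2) * normo),
        entry_ramp_min=int(rng.integers(20, 41)),
        arousal_ramp_min=a_ramp,
        arousal_lead_min=lead,
        arousal_peak_vo2=1.5 * normo,
        noise_frac=float(rng.uniform(0.01, 0.05)),
        noise_mode="absolute",
        decision={"kind": "always_at",
                  "t_h": float(rng.uniform(1.0, max(entry_latest, 1.5)))},
        seed=int(rng.integers(0, 2**31 - 1)))


def annotation_recovery(n_nights: int = 200, seed: int = 0,
                        tol_min: int = 3) -> dict:
    """Boundary and label recovery over randomized synthetic bouts
    (noise SD up to 5% of the normothermic level)."""
    rng = np.random.default_rng(seed)
    cfg = AnnotationConfig()
    entry_ok = arousal_ok = detected = 0
    agreement = []
    for _ in range(n_nights):
        _, _, truth = simulate_night(_random_bout_cfg(rng), emit_gas=False,
                                     rng=rng)
        ann = annotate_states(truth["vo2_minute"], cfg)
        if not ann.torpid:
            agreement.append(0.0)
            continue
        detected += 1
        entry_ok += abs(ann.entry_start - truth["entry_start"]) <= tol_min
        arousal_ok += abs(ann.arousal_start - truth["arousal_start"]) <= tol_min
        agreement.append(float(np.mean(ann.labels == truth["labels"])))
    return {"entry_recovery_pct": 100.0 * entry_ok / n_nights,
            "arousal_recovery_pct": 100.0 * arousal_ok / n_nights,
            "label_agreement_pct": 100.0 * float(np.mean(agreement)),
            "detected": detected, "n": n_nights}


def false_bout_rate(n_nights: int = 200, seed: int = 1) -> dict:
    """Fraction of torpor-free noisy nights on which a bout is reported."""
    rng = np.random.default_rng(seed)
    false = 0
    for _ in range(n_nights):
        cfg = _random_bout_cfg(rng)
        cfg.decision = {"kind": "never"}
        _, _, truth = simulate_night(cfg, emit_gas=False, rng=rng)
        false += annotate_states(truth["vo2_minute"]).torpid
    return {"false_bout_pct": 100.0 * false / n_nights, "n": n_nights}


def period_recovery(n_traj: int = 200, seed: int = 2,
                    tol_days: int = 2, tol_mag: float = 0.05) -> dict:
    """Fattening window/magnitude recovery on plateau-ramp-plateau
    trajectories with ramp slopes 2-10x the plateau noise SD."""
    rng = np.random.default_rng(seed)
    cfg = PeriodConfig()
    win_ok = mag_ok = missed = 0
    for _ in range(n_traj):
        pre = int(rng.integers(20, 41))
        ramp = int(rng.integers(6, 19))
        post = int(rng.integers(15, 31))
        base = rng.uniform(2.6, 3.0)
        gain = rng.uniform(0.34, 0.90)
        slope = gain / ramp
        noise = slope / rng.uniform(2.0, 10.0)
        day = np.arange(pre + ramp + post, dtype=float)
        mass = np.concatenate([np.full(pre, base),
                               base + np.arange(1, ramp + 1) * slope,
                               np.full(post, base + gain)])
        mass = mass + rng.normal(0.0, noise, len(mass))
        assign = classify_periods(MassTrajectory("sweep", day, mass), cfg)
        if not assign.fattener:
            missed += 1
            continue
        s = fattening_summary(assign)
        win_ok += (abs(assign.fattening_start - (pre - 1)) <= tol_days
                   and abs(assign.fattening_end - (pre + ramp - 1))
                   <= tol_days)
        mag_ok += abs(s.magnitude_g - gain) <= tol_mag
    return {"window_recovery_pct": 100.0 * win_ok / n_traj,
            "magnitude_recovery_pct": 100.0 * mag_ok / n_traj,
            "missed": missed, "n": n_traj}


def fattener_split_recovery(seed: int = 3) -> dict:
    """Classify the default 16-bird cohort (13 fatteners by construction)."""
    sim = simulate_season(SeasonSimConfig(seed=seed, focal_interval_days=60))
    cfg = PeriodConfig()
    n_fat = 0
    correct = 0
    for bird, grp in sim["masses"].groupby("bird_id"):
        assign = classify_periods(MassTrajectory(
            bird, grp["day"].to_numpy(), grp["mass"].to_numpy()), cfg)
        n_fat += assign.fattener
        correct += assign.fattener == sim["truth"][bird]["fattener"]
    return {"fatteners": n_fat,
            "non_fatteners": sim["masses"]["bird_id"].nunique() - n_fat,
            "correct": correct}


def compliance_rate(n_nights: int = 200, violation_rate: float = 0.0,
                    seed: int = 4) -> dict:
    """Adipostat-rule compliance over simulated breeding nights, evaluated
    on the generator's exact fat ledgers."""
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_nights):
        mass = float(rng.normal(2.95, 0.15))
        fat_pct = float(np.clip(rng.normal(9.0, 2.5), 5.5, 16.0))
        cfg = NightSimConfig(
            night_length_h=float(rng.uniform(9.0, 12.0)),
            evening_mass=mass, evening_fat=fat_pct / 100.0 * mass,
            seed=int(rng.integers(0, 2**31 - 1)))
        violate = bool(rng.random() < violation_rate)
        _, _, truth = simulate_night(cfg, emit_gas=False, violate=violate,
                                     rng=rng)
        records.append(night_record_from_truth(truth))
    table = adipostat_compliance(records, ComplianceConfig())
    return {"compliance_pct": 100.0 * table.attrs["compliance_rate"],
            "n": n_nights,
            "n_torpid": int(sum(r.torpid for r in records))}


def slope_recovery(seed: int = 5) -> dict:
    """Mixed-model recovery of the three anchored generator slopes."""
    out = {}
    df = simulate_regression_cohort("breeding_duration_fat", seed=seed)
    res = fit_mixed("torpor_duration_h ~ evening_fat_content", df)
    out["breeding_duration_vs_fat"] = {
        "estimate": float(res.params["evening_fat_content"]),
        "se": float(res.bse["evening_fat_content"]), "truth": -0.63}
    df = simulate_regression_cohort("migration_duration_night", seed=seed + 1)
    res = fit_mixed("torpor_duration_h ~ evening_fat_content + night_length_h",
                    df)
    out["migration_duration_vs_night_length"] = {
        "estimate": float(res.params["night_length_h"]),
        "se": float(res.bse["night_length_h"]), "truth": 1.18}
    out["migration_duration_vs_fat"] = {
        "estimate": float(res.params["evening_fat_content"]),
        "se": float(res.bse["evening_fat_content"]), "truth": 0.0}
    df = simulate_regression_cohort("fat_loss_duration", seed=seed + 2)
    res = fit_mixed(
        "overnight_fat_loss_mg ~ torpor_duration_h + night_length_h", df)
    out["fat_loss_vs_duration"] = {
        "estimate": float(res.params["torpor_duration_h"]),
        "se": float(res.bse["torpor_duration_h"]),
        "truth": float(df.attrs["truth"]["torpor_duration_h"])}
    return out


def type_one_error_rate(n_seeds: int = 100, seed: int = 6) -> dict:
    """Fraction of zero-effect cohorts where the fat slope is called
    significant at the 2-SE level (should sit near 5%)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_seeds):
        df = simulate_regression_cohort(
            "null", seed=int(rng.integers(0, 2**31 - 1)))
        res = fit_mixed("torpor_duration_h ~ evening_fat_content", df)
        est = res.params["evening_fat_content"]
        se = res.bse["evening_fat_content"]
        rejections += abs(est) > 2.0 * se
    return {"rejection_rate": rejections / n_seeds, "n_seeds": n_seeds}
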