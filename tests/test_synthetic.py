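import numpy as np
import pytest

from adipostat.config import KJ_PER_G_FAT
from adipostat.synthetic import (
    NightSimConfig,
    SeasonSimConfig,
    chamber_fractions,
    night_record_from_truth,
    simulate_night,
    simulate_regression_cohort,
    simulate_season,
)


def test_chamber_balance_self_consistency(rng):
    vo2 = rng.uniform(0.05, 1.5, 200)
    vco2 = vo2 * rng.uniform(0.71, 1.0, 200)
    fri = 150.0
    feo2, feco2 = chamber_fractions(vo2, vco2, fri)
    fre = fri - vo2 + vco2
    assert np.max(np.abs(feo2 * fre - (fri * 0.2095 - vo2))) < 1e-12
    assert np.max(np.abs(feco2 * fre - (fri * 0.0004 + vco2))) < 1e-12


def test_never_rule_no_bout_energy_conserved():
    _, comp, truth = simulate_night(
        NightSimConfig(decision={"kind": "never"}, seed=1), emit_gas=False)
    assert not truth["torpid"]
    # exact pre-noise conservation: morning fat = evening fat - burn/37
    assert truth["morning_fat"] == pytest.approx(
        truth["evening_fat"] - truth["e_cum"][-1] / KJ_PER_G_FAT, abs=1e-12)
    # QMR means sit within a few replicate SDs of the truth
    assert comp.morning_fat == pytest.approx(truth["morning_fat"], abs=0.03)


def test_adipostat_rule_enters_at_threshold():
    cfg = NightSimConfig(seed=2, evening_mass=2.95,
                         evening_fat=0.08 / 100 * 2.95 * 100)  # 8% fat
    cfg = NightSimConfig(seed=2, evening_fat=0.236)             # 8% of 2.95
    _, _, truth = simulate_night(cfg, emit_gas=False)
    assert truth["torpid"]
    e = truth["entry_start"]
    fat_pct = truth["fat_content_inst"]
    assert fat_pct[e] <= 5.0 + 0.1
    assert fat_pct[e - 1] > 5.0 - 0.1


def test_adipostat_rule_high_fat_no_bout():
    # 25% evening fat cannot burn down to 5% in a 10-h night
    cfg = NightSimConfig(seed=3, evening_fat=0.25 * 2.95)
    _, _, truth = simulate_night(cfg, emit_gas=False)
    assert not truth["torpid"]
    assert truth["fat_content_inst"].min() > 15.0


def test_fixed_normo_rule_sets_entry():
    cfg = NightSimConfig(seed=4, decision={"kind": "fixed_normo",
                                           "normo_h": 4.0})
    _, _, truth = simulate_night(cfg, emit_gas=False)
    assert truth["entry_start"] == 240


def test_truth_labels_partition(torpid_night):
    _, truth = torpid_night
    n = int(truth["night_length_h"] * 60)
    assert len(truth["labels"]) == n
    assert set(truth["labels"]) == {"normo-pre", "entry", "torpor",
                                    "arousal", "normo-post"}


def test_deterministic_given_seed():
    a = simulate_night(NightSimConfig(seed=9))
    b = simulate_night(NightSimConfig(seed=9))
    assert np.array_equal(a[0].FeO2, b[0].FeO2)
    assert np.array_equal(a[2]["vo2_minute"], b[2]["vo2_minute"])
    assert a[1].evening_fat == b[1].evening_fat


def test_gas_trace_roundtrips_through_analysis(torpid_night):
    from adipostat.respirometry import compute_gas_exchange, correct_to_stp
    gas, _, truth = simulate_night(NightSimConfig(seed=11))
    mt = compute_gas_exchange(correct_to_stp(gas))
    # minute-binned recovered V̇O2 tracks the true profile
    assert np.mean(np.abs(mt.vo2 - truth["vo2_profile"])) < 0.01


def test_truth_record_builder(torpid_night):
    _, truth = torpid_night
    rec = night_record_from_truth(truth)
    assert rec.torpid
    assert rec.fat_at_entry_pct == pytest.approx(5.0, abs=0.3)
    assert rec.overnight_fat_loss_mg == pytest.approx(
        truth["e_cum"][-1] / 37 * 1000)


def test_season_structure_and_truth():
    cfg = SeasonSimConfig(n_birds=6, n_fatteners=4, seed=21,
                          focal_interval_days=20)
    sim = simulate_season(cfg)
    assert sim["masses"]["bird_id"].nunique() == 6
    fat_flags = [t["fattener"] for t in sim["truth"].values()]
    assert sum(fat_flags) == 4
    for t in sim["truth"].values():
        if t["fattener"]:
            assert cfg.gain_range[0] <= t["gain"] <= cfg.gain_range[1]
    periods = {n["period"] for n in sim["nights"]}
    assert "breeding" in periods and "migration" in periods


def test_season_deterministic():
    a = simulate_season(SeasonSimConfig(n_birds=3, seed=5,
                                        focal_interval_days=30))
    b = simulate_season(SeasonSimConfig(n_birds=3, seed=5,
                                        focal_interval_days=30))
    assert a["masses"].equals(b["masses"])
    assert np.array_equal(a["nights"][0]["truth"]["vo2_minute"],
                          b["nights"][0]["truth"]["vo2_minute"])


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        NightSimConfig(torpid_vo2=0.7)
    with pytest.raises(ValueError):
        NightSimConfig(decision={"kind": "adipostat", "threshold_pct": 60})


def test_regression_cohorts_expose_truth():
    df = simulate_regression_cohort("fat_loss_duration", seed=1)
    slope = df.attrs["truth"]["torpor_duration_h"]
    assert slope == pytest.approx(-17.2, abs=0.2)
    with pytest.raises(ValueError):
        simulate_regression_cohort("nope")
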