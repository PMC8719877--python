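import numpy as np
import pandas as pd
import pytest

from adipostat.stats_models import (
    ModelSpec,
    fit_battery,
    fit_mixed,
    pairwise_contrasts,
    repeated_measures_corr,
    select_by_aic,
)
from adipostat.synthetic import simulate_regression_cohort


def test_rmcorr_perfect_within_subject():
    rng = np.random.default_rng(0)
    subj = np.repeat(np.arange(5), 8)
    x = rng.normal(0, 1, 40)
    y = x + np.repeat(rng.normal(0, 3, 5), 8)   # y = x within every subject
    df = pd.DataFrame({"s": subj, "x": x, "y": y})
    out = repeated_measures_corr(df, "x", "y", "s")
    assert out["r"] == pytest.approx(1.0, abs=1e-9)


def test_rmcorr_independent_near_zero():
    rng = np.random.default_rng(1)
    subj = np.repeat(np.arange(10), 12)
    df = pd.DataFrame({"s": subj, "x": rng.normal(0, 1, 120),
                       "y": rng.normal(0, 1, 120)})
    out = repeated_measures_corr(df, "x", "y", "s")
    assert out["ci95"][0] < 0.0 < out["ci95"][1]


def test_rmcorr_recovers_mass_fat_coupling():
    rng = np.random.default_rng(2)
    subj = np.repeat(np.arange(13), 9)
    fat = rng.normal(0.6, 0.1, 117)
    mass = np.repeat(rng.normal(2.4, 0.2, 13), 9) + fat \
        + rng.normal(0, 0.0363, 117)
    df = pd.DataFrame({"s": subj, "fat": fat, "mass": mass})
    out = repeated_measures_corr(df, "mass", "fat", "s")
    assert out["ci95"][0] <= 0.94 <= out["ci95"][1]


def test_rmcorr_requires_three_subjects():
    df = pd.DataFrame({"s": [0, 0, 1, 1], "x": [1, 2, 3, 4],
                       "y": [1, 2, 3, 4]})
    with pytest.raises(ValueError):
        repeated_measures_corr(df, "x", "y", "s")


def test_slope_recovery_breeding():
    df = simulate_regression_cohort("breeding_duration_fat", seed=5)
    res = fit_mixed("torpor_duration_h ~ evening_fat_content", df)
    est = res.params["evening_fat_content"]
    se = res.bse["evening_fat_content"]
    assert abs(est - (-0.63)) < 2 * se


def test_slope_recovery_migration_night_length():
    df = simulate_regression_cohort("migration_duration_night", seed=6)
    res = fit_mixed(
        "torpor_duration_h ~ evening_fat_content + night_length_h", df)
    assert abs(res.params["night_length_h"] - 1.18) \
        < 2 * res.bse["night_length_h"]
    # no fat effect was injected
    assert abs(res.params["evening_fat_content"]) \
        < 2 * res.bse["evening_fat_content"]


def test_aic_rule_retains_simpler_model():
    # pure-noise response: the richer model never wins by 2 points
    df = simulate_regression_cohort("null", seed=7)
    chosen, table = select_by_aic(
        ["torpor_duration_h ~ evening_fat_content + night_length_h",
         "torpor_duration_h ~ evening_fat_content",
         "torpor_duration_h ~ 1"], df)
    assert chosen == "torpor_duration_h ~ 1"
    assert table["selected"].sum() == 1
    sel = table[table.selected].iloc[0]
    others = table[~table.selected].dropna(subset=["aic"])
    assert np.all(others["aic"] > sel["aic"] - 2.0)


def test_aic_rule_picks_true_model_when_decisive():
    df = simulate_regression_cohort("breeding_duration_fat", seed=8)
    chosen, _ = select_by_aic(
        ["torpor_duration_h ~ evening_fat_content",
         "torpor_duration_h ~ 1"], df)
    assert chosen == "torpor_duration_h ~ evening_fat_content"


def _two_period_frame(delta, seed=0, n_birds=10, nights=8):
    rng = np.random.default_rng(seed)
    bird = np.repeat([f"b{i}" for i in range(n_birds)], nights * 2)
    period = np.tile(np.repeat(["breeding", "migration"], nights), n_birds)
    b = np.repeat(rng.normal(0, 0.05, n_birds), nights * 2)
    y = np.where(period == "migration", delta, 0.0) + 2.77 + b \
        + rng.normal(0, 0.1, n_birds * nights * 2)
    return pd.DataFrame({"bird_id": bird, "period": period, "mass": y})


def test_contrast_null_between_identical_periods():
    df = _two_period_frame(0.0, seed=3)
    rep = fit_battery(df, [ModelSpec("m", "mass ~ C(period)")])["m"]
    con = pairwise_contrasts(rep, df, "period")
    assert abs(con["estimate"].iloc[0]) < 0.1
    assert con["p_tukey"].iloc[0] > 0.05


def test_contrast_detects_mass_difference():
    # breeding 2.77 g vs migration 3.73 g
    df = _two_period_frame(0.96, seed=4)
    rep = fit_battery(df, [ModelSpec("m", "mass ~ C(period)")])["m"]
    con = pairwise_contrasts(rep, df, "period")
    assert con["estimate"].iloc[0] == pytest.approx(-0.96, abs=0.1)
    assert con["p_tukey"].iloc[0] < 0.001
    assert rep.emmeans["emmean"].tolist() == pytest.approx([2.77, 3.73],
                                                           abs=0.1)


def test_three_periods_give_three_contrasts():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({
        "bird_id": np.repeat([f"b{i}" for i in range(8)], 9),
        "period": np.tile(np.repeat(["breeding", "fattening", "migration"], 3),
                          8),
        "mass": rng.normal(3.0, 0.2, 72)})
    rep = fit_battery(df, [ModelSpec("m", "mass ~ C(period)")])["m"]
    assert len(pairwise_contrasts(rep, df, "period")) == 3


def test_contrast_requires_margin_in_model():
    df = _two_period_frame(0.5)
    rep = fit_battery(df, [ModelSpec("m", "mass ~ 1")])["m"]
    with pytest.raises(ValueError):
        pairwise_contrasts(rep, df, "period")


def test_binomial_family_recovers_sign():
    rng = np.random.default_rng(9)
    m = 13 * 12
    bird = np.repeat([f"b{i}" for i in range(13)], 12)
    fat = rng.normal(9, 2.5, m)
    b = np.repeat(rng.normal(0, 0.5, 13), 12)
    p = 1 / (1 + np.exp(-(-0.7 * (fat - 9) + b)))
    df = pd.DataFrame({"bird_id": bird, "evening_fat_content": fat,
                       "torpid": rng.random(m) < p})
    rep = fit_battery(df, [ModelSpec("occ", "torpid ~ evening_fat_content",
                                     family="binomial")])["occ"]
    est = rep.params["evening_fat_content"]
    assert est < 0
    assert rep.pvalues["evening_fat_content"] < 0.05


def test_row_order_invariance():
    df = simulate_regression_cohort("breeding_duration_fat", seed=10)
    r1 = fit_mixed("torpor_duration_h ~ evening_fat_content", df)
    shuffled = df.sample(frac=1.0, random_state=1)
    r2 = fit_mixed("torpor_duration_h ~ evening_fat_content", shuffled)
    assert r1.params["evening_fat_content"] == pytest.approx(
        r2.params["evening_fat_content"], abs=1e-8)
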