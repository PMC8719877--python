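import numpy as np
import pytest

from adipostat.config import ComplianceConfig
from adipostat.energetics import add_energy, build_energy_ledger
from adipostat.night_metrics import (
    BodyComposition,
    NightRecord,
    adipostat_compliance,
    build_night_record,
    records_to_frame,
    torpor_propensity,
)
from adipostat.respirometry import MetabolicTrace
from adipostat.state_annotation import annotate_states


def _record(**kw):
    base = dict(bird_id="b", date="", period="breeding", night_length_h=10.0,
                evening_fat_content=9.0, torpid=False, total_energy_kj=7.4,
                overnight_fat_loss_mg=200.0)
    base.update(kw)
    return NightRecord(**base)


def _comp():
    return BodyComposition(evening_mass=2.95, evening_fat=0.25,
                           evening_lean=2.60, morning_mass=2.77,
                           morning_fat=0.08, morning_lean=2.60)


def test_composition_invariant_checked():
    with pytest.raises(ValueError):
        BodyComposition(2.9, 1.5, 1.6, 2.7, 0.1, 2.5)


def test_non_torpid_record_fat_loss():
    vo2 = np.full(600, 0.6)
    mt = add_energy(MetabolicTrace("b", "", np.arange(600.0), vo2, vo2 * 0.71))
    ann = annotate_states(mt.vo2)
    led = build_energy_ledger(mt, 0.25, 2.77)
    rec = build_night_record(_comp(), ann, led,
                             {"bird_id": "b", "night_length_h": 10.0})
    assert not rec.torpid
    assert rec.torpor_duration_h is None and rec.fat_at_entry_pct is None
    assert rec.overnight_fat_loss_mg == pytest.approx(
        rec.total_energy_kj / 37.0 * 1000.0)


def test_fat_loss_scaling():
    # 7.4 kJ is exactly 200 mg of fat
    assert 7.4 / 37.0 * 1000.0 == pytest.approx(200.0)


def test_torpid_record_fields(standard_bout):
    y, _ = standard_bout
    mt = add_energy(MetabolicTrace("b", "", np.arange(len(y), dtype=float),
                                   y, y * 0.71))
    ann = annotate_states(mt.vo2)
    led = build_energy_ledger(mt, 0.25, 2.77)
    rec = build_night_record(_comp(), ann, led,
                             {"bird_id": "b", "night_length_h": 10.0})
    assert rec.torpid
    assert rec.entry_time_h == pytest.approx(2.0, abs=0.1)
    assert rec.torpor_duration_h == pytest.approx(5.5, abs=0.1)
    assert rec.pre_torpor_energy_kj == pytest.approx(
        led.e_cum[ann.entry_start], abs=1e-9)


def test_propensity_arithmetic():
    recs = [_record(torpid=i < 5) for i in range(8)]
    tab = torpor_propensity(recs)
    assert tab["propensity_pct"].iloc[0] == pytest.approx(62.5)
    recs0 = [_record(torpid=False) for _ in range(6)]
    assert torpor_propensity(recs0)["propensity_pct"].iloc[0] == 0.0


def test_propensity_invariant_to_order(rng):
    recs = [_record(bird_id=f"b{i % 4}", torpid=bool(i % 3)) for i in range(24)]
    t1 = torpor_propensity(recs)
    t2 = torpor_propensity(list(reversed(recs)))
    assert t1.equals(t2)


def test_compliance_constructed_cases():
    night = 600
    t = np.arange(night)

    def series(start, end):
        return start + (end - start) * t / night

    # A: enters torpor the minute fat reaches 5.2%, halfway through
    a = _record(torpid=True, fat_at_entry_pct=5.2, entry_time_h=5.0,
                fat_content_series=series(9, 3))
    # B: crosses 5% at 80% of the night and stays normothermic
    b = _record(torpid=False,
                fat_content_series=series(10.0, 10.0 - 6.25))
    # C: enters torpor at 30% fat
    c = _record(torpid=True, fat_at_entry_pct=30.0, entry_time_h=3.0,
                fat_content_series=series(33, 28))
    tab = adipostat_compliance([a, b, c])
    assert tab["compliant"].tolist() == [True, True, False]
    assert tab.attrs["compliance_rate"] == pytest.approx(2 / 3)


def test_compliance_threshold_never_reached():
    rec = _record(torpid=False,
                  fat_content_series=np.linspace(30, 25, 600))
    tab = adipostat_compliance([rec])
    assert tab["reason"].iloc[0] == "threshold_not_reached"
    assert tab["compliant"].iloc[0]


def test_compliance_band_configurable():
    rec = _record(torpid=True, fat_at_entry_pct=7.0,
                  fat_content_series=np.linspace(12, 5, 600))
    assert not adipostat_compliance([rec])["compliant"].iloc[0]
    wide = ComplianceConfig(band_pct=2.5)
    assert adipostat_compliance([rec], wide)["compliant"].iloc[0]


def test_records_frame_shape():
    df = records_to_frame([_record(), _record(torpid=True,
                                              fat_at_entry_pct=5.0)])
    assert len(df) == 2
    assert "evening_fat_content" in df.columns
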