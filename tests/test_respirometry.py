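import numpy as np
import pandas as pd
import pytest
from scipy.optimize import fsolve

from adipostat.config import FICO2_DEFAULT, FIO2_DEFAULT, StpReference
from adipostat.respirometry import (
    GasTrace,
    compute_gas_exchange,
    correct_to_stp,
    read_trace,
    write_trace,
)
from adipostat.synthetic import NightSimConfig, chamber_fractions, simulate_night


def _toy_trace(n=10 * 3600, **kw):
    defaults = dict(bird_id="b1", date="2019-07-01",
                    t=np.arange(n, dtype=float),
                    FeO2=0.2090, FeCO2=0.0009, flow=150.0, wvp=1.2,
                    bp=101.325, tair=20.0, lights_on_t=float(n))
    defaults.update(kw)
    return GasTrace(**defaults)


# ---------------------------------------------------------------------- I/O

def test_read_toy_file(tmp_path):
    df = pd.DataFrame({"t": np.arange(10), "FeO2": 0.209, "FeCO2": 0.001,
                       "flow": 150.0, "wvp": 1.0, "bp": 101.0, "tair": 20.0})
    path = tmp_path / "toy.csv"
    df.to_csv(path, index=False)
    with pytest.warns(UserWarning):  # 10-s trial is far below nominal span
        tr = read_trace(path, bird_id="b1", lights_on_t=10)
    assert len(tr) == 10
    assert tr.interpolated.sum() == 0


def test_missing_second_interpolated(tmp_path):
    t = np.r_[np.arange(5), np.arange(6, 11)]          # second 5 missing
    df = pd.DataFrame({"t": t, "FeO2": 0.209, "FeCO2": 0.001, "flow": 150.0,
                       "wvp": 1.0, "bp": 101.0, "tair": 20.0})
    path = tmp_path / "gap.csv"
    df.to_csv(path, index=False)
    with pytest.warns(UserWarning):
        tr = read_trace(path, lights_on_t=11)
    assert len(tr) == 11
    assert tr.interpolated.sum() == 1
    assert tr.interpolated[5]


def test_missing_channel_named_in_error(tmp_path):
    df = pd.DataFrame({"t": np.arange(10), "FeO2": 0.209})
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="FeCO2"):
        read_trace(path)


def test_non_monotone_time_rejected(tmp_path):
    df = pd.DataFrame({"t": [0, 1, 1, 2], "FeO2": 0.209, "FeCO2": 0.001,
                       "flow": 150.0, "wvp": 1.0, "bp": 101.0, "tair": 20.0})
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="monotone"):
        read_trace(path)


def test_simulated_trace_roundtrips(tmp_path):
    gas, _, _ = simulate_night(NightSimConfig(seed=3))
    path = tmp_path / "sim.csv"
    write_trace(gas, path)
    back = read_trace(path, bird_id=gas.bird_id, lights_on_t=gas.lights_on_t)
    for ch in ("FeO2", "FeCO2", "flow"):
        assert np.allclose(getattr(back, ch), getattr(gas, ch), atol=1e-12)


# --------------------------------------------------------- STP correction

def test_stp_identity_at_reference():
    tr = _toy_trace(wvp=0.0, tair=0.0, bp=101.325)
    out = correct_to_stp(tr)
    assert np.allclose(out.flow, tr.flow)


def test_water_vapor_dilution_halves_flow():
    tr = _toy_trace(wvp=101.325 / 2, tair=0.0, bp=101.325)
    out = correct_to_stp(tr)
    assert np.allclose(out.flow, tr.flow / 2)


def test_stp_matches_ideal_gas_oracle(rng):
    for _ in range(50):
        bp = rng.uniform(95, 105)
        tair = rng.uniform(5, 35)
        wvp = rng.uniform(0, 3)
        tr = _toy_trace(n=36000, bp=bp, tair=tair, wvp=wvp)
        out = correct_to_stp(tr)
        # independent ideal-gas bookkeeping: dry partial pressure over
        # reference pressure, reference kelvin over ambient kelvin
        expect = 150.0 * ((bp - wvp) / 101.325) * (273.15 / (273.15 + tair))
        assert np.allclose(out.flow, expect, atol=1e-9)


def test_impossible_humidity_rejected():
    tr = _toy_trace()
    tr.wvp[:] = tr.bp[0] + 1
    with pytest.raises(ValueError, match="vapor"):
        correct_to_stp(tr)


# -------------------------------------------------------- gas exchange

def _fsolve_oracle(feo2, feco2, fri, fio2=FIO2_DEFAULT, fico2=FICO2_DEFAULT):
    """Brute-force inversion of the steady-state balance, independent of the
    closed form used by compute_gas_exchange."""
    def eqs(v):
        vo2, vco2 = v
        fre = fri - vo2 + vco2
        return [(fri * fio2 - vo2) / fre - feo2,
                (fri * fico2 + vco2) / fre - feco2]
    return fsolve(eqs, [0.5, 0.4], full_output=False)


def test_no_animal_gives_zero_rates():
    tr = _toy_trace(FeO2=FIO2_DEFAULT, FeCO2=FICO2_DEFAULT, wvp=0.0,
                    tair=0.0)
    mt = compute_gas_exchange(correct_to_stp(tr))
    assert np.allclose(mt.vo2, 0.0, atol=1e-12)
    assert np.allclose(mt.vco2, 0.0, atol=1e-12)


def test_mass_balance_roundtrip_known_rates():
    feo2, feco2 = chamber_fractions(0.50, 0.45, 150.0)
    tr = _toy_trace(FeO2=float(feo2), FeCO2=float(feco2), wvp=0.0, tair=0.0)
    mt = compute_gas_exchange(correct_to_stp(tr), bin_minutes=False)
    assert abs(mt.vo2[0] - 0.50) < 1e-9
    assert abs(mt.vco2[0] - 0.45) < 1e-9
    # agreement with the brute-force numeric inversion
    vo2_bf, vco2_bf = _fsolve_oracle(float(feo2), float(feco2), 150.0)
    assert abs(vo2_bf - 0.50) < 1e-8 and abs(vco2_bf - 0.45) < 1e-8


def test_random_rate_sweep_roundtrip(rng):
    vo2 = rng.uniform(0.01, 2.0, 1000)
    vco2 = vo2 * rng.uniform(0.71, 1.0, 1000)
    fri = rng.uniform(100, 500, 1000)
    feo2, feco2 = chamber_fractions(vo2, vco2, fri)
    tr = _toy_trace(n=1000, FeO2=feo2, FeCO2=feco2, flow=fri, wvp=0.0,
                    tair=0.0)
    mt = compute_gas_exchange(correct_to_stp(tr), bin_minutes=False)
    assert np.max(np.abs(mt.vo2 - vo2)) < 1e-8
    assert np.max(np.abs(mt.vco2 - vco2)) < 1e-8


def test_constant_rate_minute_binning_exact():
    feo2, feco2 = chamber_fractions(0.6, 0.5, 150.0)
    tr = _toy_trace(n=600, FeO2=float(feo2), FeCO2=float(feco2), wvp=0.0,
                    tair=0.0)
    mt = compute_gas_exchange(correct_to_stp(tr))
    assert len(mt) == 10
    assert np.allclose(mt.vo2, 0.6, atol=1e-9)


def test_saturated_fractions_rejected():
    tr = _toy_trace(FeO2=0.7, FeCO2=0.3)
    with pytest.raises(ValueError, match="underflow"):
        compute_gas_exchange(correct_to_stp(tr))
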