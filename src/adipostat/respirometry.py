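"""Flow-through respirometry: raw gas traces to gas-exchange rates.

Implements the push-mode (upstream-metered flow) dual-gas mass balance.  At
steady state the chamber satisfies

    FR_e  = FR_i − V̇O2 + V̇CO2
    FeO2  = (FR_i·FiO2  − V̇O2)  / FR_e
    FeCO2 = (FR_i·FiCO2 + V̇CO2) / FR_e

where FR_i is the (dry, STP-corrected) incurrent flow and Fi/Fe are incurrent
and excurrent fractions.  Eliminating FR_e gives the closed-form inversion
used by :func:`compute_gas_exchange`:

    FR_e  = FR_i · (1 − FiO2 − FiCO2) / (1 − FeO2 − FeCO2)
    V̇O2  = FR_i·FiO2  − FeO2·FR_e
    V̇CO2 = FeCO2·FR_e − FR_i·FiCO2

All gas rates are mL·min⁻¹ at STP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import FICO2_DEFAULT, FIO2_DEFAULT, StpReference

__all__ = [
    "GasTrace",
    "MetabolicTrace",
    "read_trace",
    "write_trace",
    "correct_to_stp",
    "compute_gas_exchange",
]

#: required channels for :func:`read_trace`, in canonical order
REQUIRED_CHANNELS = ("t", "FeO2", "FeCO2", "flow", "wvp", "bp", "tair")


@dataclass
class GasTrace:
    """One overnight trial of per-second respirometry channels.

    ``t`` is seconds since lights-off on a uniform 1-s grid; fractions are
    dimensionless, ``flow`` is the metered incurrent flow in mL·min⁻¹,
    pressures in kPa, temperature in °C.
    """

    bird_id: str
    date: str
    t: np.ndarray
    FeO2: np.ndarray
    FeCO2: np.ndarray
    flow: np.ndarray
    wvp: np.ndarray
    bp: np.ndarray
    tair: np.ndarray
    lights_on_t: float
    FiO2: float = FIO2_DEFAULT
    FiCO2: float = FICO2_DEFAULT
    interpolated: np.ndarray | None = None
    stp_corrected: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("FeO2", "FeCO2", "flow", "wvp", "bp", "tair"):
            setattr(self, name, np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), self.t.shape).copy())
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time channel must be strictly increasing")
        for name in ("FeO2", "FeCO2"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any(self.flow <= 0):
            raise ValueError("flow must be positive")
        if self.lights_on_t <= 0:
            raise ValueError("lights_on_t must be positive")
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.t), dtype=bool)
        span_h = (self.t[-1] - self.t[0]) / 3600.0
        if not 9.0 <= span_h <= 12.0:
            warnings.warn(
                f"trial span {span_h:.2f} h outside the nominal 9-12 h range",
                stacklevel=2)

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "FeO2": self.FeO2, "FeCO2": self.FeCO2,
            "flow": self.flow, "wvp": self.wvp, "bp": self.bp,
            "tair": self.tair,
        })


@dataclass
class MetabolicTrace:
    """Per-minute gas exchange and (optionally) energy expenditure.

    ``t_min`` is minutes since lights-off; ``vo2``/``vco2`` in mL·min⁻¹ STP;
    ``e_rate`` in J·min⁻¹; ``e_cum`` in kJ since lights-off.  Energy fields
    are ``None`` until filled by :func:`adipostat.energetics.add_energy`.
    """

    bird_id: str
    date: str
    t_min: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    rer: np.ndarray | None = None
    e_rate: np.ndarray | None = None
    e_cum: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t_min)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_min": self.t_min, "vo2": self.vo2, "vco2": self.vco2}
        for name in ("rer", "e_rate", "e_cum"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)


def read_trace(
    path,
    channel_map: dict[str, str] | None = None,
    *,
    bird_id: str = "",
    date: str = "",
    lights_on_t: float | None = None,
    FiO2: float = FIO2_DEFAULT,
    FiCO2: float = FICO2_DEFAULT,
    sep: str = ",",
) -> GasTrace:
    """Read a delimited per-second trace into a :class:`GasTrace`.

    ``channel_map`` maps canonical channel names (``t``, ``FeO2``, ``FeCO2``,
    ``flow``, ``wvp``, ``bp``, ``tair``) to column names in the file; omitted
    entries default to the canonical name itself.  Missing seconds are
    restored by linear interpolation and flagged in ``interpolated``.
    """
    channel_map = {**{c: c for c in REQUIRED_CHANNELS}, **(channel_map or {})}
    df = pd.read_csv(path, sep=sep)
    missing = [channel_map[c] for c in REQUIRED_CHANNELS
               if channel_map[c] not in df.columns]
    if missing:
        raise ValueError(f"missing required channel column(s): {missing}")
    t = df[channel_map["t"]].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone time channel")
    t0, t1 = t[0], t[-1]
    grid = np.arange(round(t0), round(t1) + 1, dtype=float)
    channels = {}
    for c in REQUIRED_CHANNELS[1:]:
        channels[c] = np.interp(grid, t, df[channel_map[c]].to_numpy(dtype=float))
    interpolated = ~np.isin(grid, np.round(t))
    return GasTrace(
        bird_id=bird_id, date=date, t=grid,
        lights_on_t=float(lights_on_t if lights_on_t is not None else grid[-1]),
        FiO2=FiO2, FiCO2=FiCO2, interpolated=interpolated, **channels)


def write_trace(trace: GasTrace, path, sep: str = ",") -> None:
    """Write a trace in the same delimited dialect :func:`read_trace` reads."""
    trace.to_frame().to_csv(path, sep=sep, index=False)


def correct_to_stp(trace: GasTrace, stp: StpReference | None = None) -> GasTrace:
    """Convert metered flow to its dry-gas STP equivalent.

    Water vapor is removed by partial-pressure dilution, then the dry flow is
    scaled by ideal-gas temperature/pressure ratios to the reference
    conditions:

        flow_dry = flow · (bp − wvp) / bp
        flow_stp = flow_dry · (bp / P_ref) · (T_ref / T_air)

    with temperatures absolute.  The mean correction factor is recorded in
    ``meta["stp_correction_factor"]``.
    """
    stp = stp or StpReference()
    if np.any(~np.isfinite(trace.bp) | ~np.isfinite(trace.tair)
              | ~np.isfinite(trace.wvp)):
        raise ValueError("bp, tair and wvp must be finite")
    if np.any(trace.wvp >= trace.bp):
        raise ValueError("water-vapor pressure >= barometric pressure")
    t_ref_k = stp.temp_c + 273.15
    factor = ((trace.bp - trace.wvp) / trace.bp) \
        * (trace.bp / stp.pressure_kpa) \
        * (t_ref_k / (trace.tair + 273.15))
    out = replace(trace, flow=trace.flow * factor, stp_corrected=True)
    out.meta = {**trace.meta,
                "stp_correction_factor": float(np.mean(factor)),
                "stp_reference": {"temp_c": stp.temp_c,
                                  "pressure_kpa": stp.pressure_kpa}}
    return out


def compute_gas_exchange(trace: GasTrace, *, bin_minutes: bool = True,
                         baseline: tuple[float, float] | None = None
                         ) -> MetabolicTrace:
    """Invert the steady-state chamber balance to per-second V̇O2/V̇CO2,
    then average into 1-min bins.

    ``baseline``, if given, is an optional two-point linear drift correction:
    V̇O2 offsets measured at the trace start and end (animal-free baseline),
    removed by linear interpolation over the night.  Default off.
    """
    if not trace.stp_corrected:
        warnings.warn("trace has not been STP-corrected; rates are at "
                      "ambient conditions", stacklevel=2)
    denom = 1.0 - trace.FeO2 - trace.FeCO2
    if np.any(denom < 1e-6):
        raise ValueError("excurrent fractions sum to ~1; denominator underflow")
    fri = trace.flow
    fre = fri * (1.0 - trace.FiO2 - trace.FiCO2) / denom
    vo2 = fri * trace.FiO2 - trace.FeO2 * fre
    vco2 = trace.FeCO2 * fre - fri * trace.FiCO2
    if baseline is not None:
        b0, b1 = baseline
        vo2 = vo2 - np.linspace(b0, b1, len(vo2))
    vo2 = np.clip(vo2, 0.0, None)
    vco2 = np.clip(vco2, 0.0, None)
    if not bin_minutes:
        return MetabolicTrace(trace.bird_id, trace.date,
                              trace.t / 60.0, vo2, vco2, meta=dict(trace.meta))
    # arithmetic mean over whole clock minutes from lights-off; a partial
    # trailing minute is dropped
    rel = trace.t - trace.t[0]
    nmin = int((rel[-1] + 1) // 60)
    idx = (rel // 60).astype(int)
    keep = idx < nmin
    counts = np.bincount(idx[keep], minlength=nmin)
    vo2_m = np.bincount(idx[keep], weights=vo2[keep], minlength=nmin) / counts
    vco2_m = np.bincount(idx[keep], weights=vco2[keep], minlength=nmin) / counts
    return MetabolicTrace(trace.bird_id, trace.date,
                          np.arange(nmin, dtype=float), vo2_m, vco2_m,
                          meta=dict(trace.meta))
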