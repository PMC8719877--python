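"""Indirect calorimetry: gas exchange to energy expenditure and fat ledger.

Energy rate uses the oxyjoule equivalent E_rate = (16 + 5.164·RER)·V̇O2 in
J·min⁻¹, with RER clamped to the physiological [0.71, 1.0] range first.
Cumulative expenditure is converted to fat-mass equivalents at 37 kJ·g⁻¹,
which tracks the bird's instantaneous fat store through the night.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, trapezoid

from .config import (
    KJ_PER_G_FAT,
    OXYJOULE_INTERCEPT,
    OXYJOULE_SLOPE,
    RER_MAX,
    RER_MIN,
)
from .respirometry import MetabolicTrace

__all__ = [
    "EnergyLedger",
    "compute_rer",
    "energy_rate",
    "add_energy",
    "integrate_energy",
    "fat_content_at_entry",
    "build_energy_ledger",
]


def compute_rer(vo2, vco2, *, on_zero: str = "clamp"):
    """Respiratory exchange ratio V̇CO2/V̇O2, clamped to [0.71, 1.0].

    Scalar or array inputs.  Minutes with ``vo2 == 0`` have an undefined
    ratio; with ``on_zero="clamp"`` (default) they are filled with the lower
    bound, with ``on_zero="error"`` they raise.  Returns ``(rer, n_clamped)``
    where ``n_clamped`` counts out-of-bounds or undefined entries.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    zero = vo2 == 0
    if np.any(zero) and on_zero == "error":
        raise ValueError("RER undefined where vo2 == 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(zero, RER_MIN, vco2 / np.where(zero, 1.0, vo2))
    clamped = np.clip(raw, RER_MIN, RER_MAX)
    n_clamped = int(np.sum((raw < RER_MIN) | (raw > RER_MAX) | zero))
    if clamped.ndim == 0:
        return float(clamped), n_clamped
    return clamped, n_clamped


def energy_rate(vo2, rer):
    """Oxyjoule energy expenditure rate, J·min⁻¹: (16 + 5.164·RER)·V̇O2."""
    vo2 = np.asarray(vo2, dtype=float)
    rer = np.asarray(rer, dtype=float)
    if np.any(vo2 < 0):
        raise ValueError("vo2 must be non-negative")
    if np.any((rer < RER_MIN - 1e-12) | (rer > RER_MAX + 1e-12)):
        raise ValueError(f"rer outside [{RER_MIN}, {RER_MAX}]; clamp first")
    out = (OXYJOULE_INTERCEPT + OXYJOULE_SLOPE * rer) * vo2
    return float(out) if out.ndim == 0 else out


def add_energy(trace: MetabolicTrace) -> MetabolicTrace:
    """Fill ``rer``, ``e_rate`` and ``e_cum`` on a gas-exchange trace.

    The fraction of RER-clamped minutes is recorded in
    ``meta["rer_clamped_frac"]``; nights where it exceeds 20% are flagged as
    bookkeeping-suspect (the fat-equivalent ledger assumes fat oxidation).
    """
    rer, n_clamped = compute_rer(trace.vo2, trace.vco2)
    e_rate = energy_rate(trace.vo2, rer)
    e_cum = cumulative_trapezoid(e_rate, trace.t_min, initial=0.0) / 1000.0
    out = replace(trace, rer=rer, e_rate=e_rate, e_cum=e_cum)
    frac = n_clamped / max(len(trace), 1)
    out.meta = {**trace.meta, "rer_clamped_frac": frac,
                "rer_bookkeeping_suspect": frac > 0.20}
    return out


def integrate_energy(trace: MetabolicTrace,
                     window: tuple[float, float] | None = None) -> float:
    """Trapezoidal integral of ``e_rate`` over ``window`` (minutes), in kJ."""
    if trace.e_rate is None:
        raise ValueError("trace has no energy fields; call add_energy first")
    t, e = trace.t_min, trace.e_rate
    if window is not None:
        t0, t1 = window
        if t1 < t0:
            raise ValueError("window end before start")
        if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
            raise ValueError("window outside trace span")
        grid = np.unique(np.r_[t0, t[(t > t0) & (t < t1)], t1])
        e = np.interp(grid, t, e)
        t = grid
    if len(t) < 2:
        warnings.warn("empty integration window", stacklevel=2)
        return 0.0
    return float(trapezoid(e, t)) / 1000.0


def fat_content_at_entry(evening_fat: float, pre_entry_energy: float,
                         morning_mass: float) -> float:
    """Instantaneous fat content at torpor entry, % of morning body mass.

    ``100·(evening_fat − pre_entry_energy/37)/morning_mass``.  The result can
    be negative when measured expenditure exceeds the fat store; callers
    should flag, not clip.
    """
    if morning_mass <= 0:
        raise ValueError("morning_mass must be positive")
    if evening_fat < 0 or pre_entry_energy < 0:
        raise ValueError("inputs must be non-negative")
    return 100.0 * (evening_fat - pre_entry_energy / KJ_PER_G_FAT) / morning_mass


@dataclass
class EnergyLedger:
    """Per-minute energy and fat bookkeeping for one night.

    ``fat_used_cum = e_cum/37`` (g), ``fat_inst = evening_fat − fat_used_cum``
    (g, non-increasing), ``fat_content_inst = 100·fat_inst/morning_mass`` (%).
    """

    t_min: np.ndarray
    e_rate: np.ndarray
    e_cum: np.ndarray
    fat_used_cum: np.ndarray
    fat_inst: np.ndarray
    fat_content_inst: np.ndarray
    evening_fat: float
    morning_mass: float
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_min": self.t_min, "e_rate": self.e_rate, "e_cum": self.e_cum,
            "fat_used_cum": self.fat_used_cum, "fat_inst": self.fat_inst,
            "fat_content_inst": self.fat_content_inst,
        })


def build_energy_ledger(trace: MetabolicTrace, evening_fat: float,
                        morning_mass: float) -> EnergyLedger:
    """Track the fat store minute-by-minute from cumulative expenditure."""
    if trace.e_cum is None:
        trace = add_energy(trace)
    if morning_mass <= 0:
        raise ValueError("morning_mass must be positive")
    fat_used = trace.e_cum / KJ_PER_G_FAT
    fat_inst = evening_fat - fat_used
    flags = []
    if np.any(fat_inst < 0):
        flags.append("negative_instantaneous_fat")
    return EnergyLedger(
        t_min=trace.t_min, e_rate=trace.e_rate, e_cum=trace.e_cum,
        fat_used_cum=fat_used, fat_inst=fat_inst,
        fat_content_inst=100.0 * fat_inst / morning_mass,
        evening_fat=evening_fat, morning_mass=morning_mass, flags=flags)
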