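"""Physical constants and pipeline configuration.

Every numeric default used by the pipeline lives here so that a run can echo
its full configuration into output metadata.  Units follow flow-through
respirometry convention: gas rates in mL·min⁻¹ at STP, energy in J·min⁻¹ /
kJ, masses in g, times in minutes since lights-off unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

# ---------------------------------------------------------------------------
# Physical constants
# ---------------------------------------------------------------------------

#: Energy density of adipose fuel: 1 g of fat yields 37 kJ.
KJ_PER_G_FAT = 37.0

#: Oxyjoule equivalent coefficients: E_rate = (16 + 5.164·RER)·V̇O2 [J·mL⁻¹ O2].
OXYJOULE_INTERCEPT = 16.0
OXYJOULE_SLOPE = 5.164

#: Physiological bounds for the respiratory exchange ratio (pure fat → pure
#: carbohydrate oxidation).  Values outside are measurement artefacts and are
#: clamped before the oxyjoule conversion.
RER_MIN = 0.71
RER_MAX = 1.0

#: Standard temperature and pressure reference for gas-volume correction.
STP_TEMP_C = 0.0
STP_PRESSURE_KPA = 101.325

#: Default incurrent (ambient) gas fractions.
FIO2_DEFAULT = 0.2095
FICO2_DEFAULT = 0.0004


# ---------------------------------------------------------------------------
# Stage configuration blocks
# ---------------------------------------------------------------------------

@dataclass
class StpReference:
    """Reference conditions for STP correction of flow rates."""

    temp_c: float = STP_TEMP_C
    pressure_kpa: float = STP_PRESSURE_KPA


@dataclass
class AnnotationConfig:
    """Thresholds for the smoothed-derivative metabolic-state annotator.

    ``span_segment`` and ``span_preliminary`` are smoothing parameters in
    (0, 1] passed to the penalized-spline smoother (R ``smooth.spline`` spar
    convention).  Slope thresholds are in mL O2·min⁻¹ per minute.
    """

    span_segment: float = 0.6
    span_preliminary: float = 0.6
    arousal_cutoff: float = 0.005
    entry_demarcation: float = -0.003
    entry_k: float = 2.0
    arousal_k: float = 5.0
    #: stable-phase V̇O2 must fall below this fraction of the normothermic
    #: level for a bout to count as torpor (specificity gate).
    depth_frac: float = 0.5
    #: minimum normothermic reference window, minutes.
    min_normo_minutes: int = 10
    #: minimum night length the annotator will accept, minutes.
    min_night_minutes: int = 180

    def __post_init__(self) -> None:
        for name in ("span_segment", "span_preliminary"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.entry_k <= 0 or self.arousal_k <= 0:
            raise ValueError("SD multipliers must be positive")


@dataclass
class PeriodConfig:
    """Body-mass trajectory segmentation parameters."""

    span: float = 0.35
    cutoff_frac: float = 0.75          # fattening cutoff = frac · max slope
    slope_floor: float = 0.01          # g·day⁻¹; below → non-fattener
    magnitude_floor: float = 0.20      # g; candidate gain below → non-fattener
    bridge_frac: float = 0.5           # merge runs across gaps above this · cutoff
    contact_frac: float = 0.25         # extend bounds while slope above this · cutoff
    min_days: int = 15


@dataclass
class ComplianceConfig:
    """Adipostat two-clause compliance rule."""

    threshold_pct: float = 5.0         # fat content (% body mass) trigger level
    late_cutoff: float = 0.75          # fraction of night after which torpor is skipped
    band_pct: float = 1.5              # tolerance band around the threshold


@dataclass
class PipelineConfig:
    """Full-run configuration: paths, constants, exclusions, seeds."""

    out_dir: str = "runs/latest"
    seed: int = 0
    n_birds: int = 16
    n_fatteners: int = 13
    stp: StpReference = field(default_factory=StpReference)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    periods: PeriodConfig = field(default_factory=PeriodConfig)
    compliance: ComplianceConfig = field(default_factory=ComplianceConfig)
    #: bird ids excluded from seasonal statistical models (non-fatteners and
    #: the juvenile are excluded in the reference analysis).
    exclude_from_seasonal: list[str] = field(default_factory=list)
    constants: dict[str, float] = field(default_factory=lambda: {
        "kj_per_g_fat": KJ_PER_G_FAT,
        "oxyjoule_intercept": OXYJOULE_INTERCEPT,
        "oxyjoule_slope": OXYJOULE_SLOPE,
        "rer_min": RER_MIN,
        "rer_max": RER_MAX,
    })

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        kw = dict(raw)
        for key, sub in (("stp", StpReference), ("annotation", AnnotationConfig),
                         ("periods", PeriodConfig), ("compliance", ComplianceConfig)):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = sub(**kw[key])
        return cls(**kw)

    def echo(self) -> str:
        """Verbatim JSON echo of the configuration for run logs."""
        return json.dumps(self.to_dict(), indent=2, default=str)
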