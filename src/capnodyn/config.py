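"""Run-time configuration and physical conventions shared across the package.

All pressure/fraction conversions assume dry-gas partial pressures at body
temperature: PCO2 = fraction * (Pb - PH2O), with barometric pressure Pb and
saturated water-vapour pressure PH2O fixed here rather than measured.
Every artifact the package writes embeds the serialized :class:`RunConfig`
used to produce it, so results stay traceable to their conventions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Package version string embedded in every output artifact.
VERSION = "capnodyn-0.1.0"

#: Barometric pressure [mmHg] used for fraction <-> partial-pressure conversion.
PB_MMHG = 760.0
#: Water vapour pressure at 37 degC [mmHg] (BTPS convention).
PH2O_MMHG = 47.0


@dataclass
class RunConfig:
    """Package-wide tunables with their defaults.

    Parameters
    ----------
    pb_mmHg, ph2o_mmHg
        Barometric and water-vapour pressure; PCO2 = fco2 * (pb - ph2o).
    hold_s
        Duration added to the expiratory pause on hold breaths [s].
    fs_hz
        Waveform sampling rate [Hz].
    phase3_bounds
        Mid-portion of phase III as fractions of expired volume; the mean
        CO2 fraction over this band is the alveolar fraction FACO2.
    fit_error_threshold_mmHg
        RMS alveolar-fraction residual above which an estimate is flagged
        invalid (the noise gate applied to the continuous output).
    v_bounds_l, q_bounds_lpm, cvco2_bounds
        Physiological plausibility bounds for the fitted lung volume [L],
        effective pulmonary blood flow [L/min] and mixed-venous CO2 content
        [Lgas/Lblood]; engineering guards, not measured values.
    diff_sign
        Bland-Altman difference convention: ``"reference-method"`` makes a
        method that overestimates the reference produce a negative bias.
    seed
        Seed recorded with outputs when provided.
    """

    pb_mmHg: float = PB_MMHG
    ph2o_mmHg: float = PH2O_MMHG
    hold_s: float = 2.0
    fs_hz: float = 100.0
    phase3_bounds: tuple[float, float] = (0.55, 0.85)
    fit_error_threshold_mmHg: float = 0.3
    v_bounds_l: tuple[float, float] = (0.2, 6.0)
    q_bounds_lpm: tuple[float, float] = (0.5, 15.0)
    cvco2_bounds: tuple[float, float] = (0.3, 1.0)
    diff_sign: str = "reference-method"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pb_mmHg <= self.ph2o_mmHg:
            raise ValueError("pb_mmHg must exceed ph2o_mmHg")
        if not (0.0 <= self.phase3_bounds[0] < self.phase3_bounds[1] <= 1.0):
            raise ValueError("phase3_bounds must be an increasing pair in [0, 1]")
        for name in ("hold_s", "fs_hz", "fit_error_threshold_mmHg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.diff_sign not in ("reference-method", "method-reference"):
            raise ValueError("diff_sign must be 'reference-method' or 'method-reference'")

    @property
    def dry_pressure_mmHg(self) -> float:
        """Pb - PH2O [mmHg]: multiply a CO2 fraction by this to get PCO2."""
        return self.pb_mmHg - self.ph2o_mmHg

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["phase3_bounds"] = list(self.phase3_bounds)
        for k in ("v_bounds_l", "q_bounds_lpm", "cvco2_bounds"):
            d[k] = list(d[k])
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs = dict(d)
        for k in ("phase3_bounds", "v_bounds_l", "q_bounds_lpm", "cvco2_bounds"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d or {})


#: Default configuration instance used when none is passed explicitly.
DEFAULT_CONFIG = RunConfig()
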