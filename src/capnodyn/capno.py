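"""Volumetric capnography: breath segmentation and per-breath features.

Works on sampled airway traces (time [s], flow [L/s] with inspiration
positive, CO2 fraction at the airway opening) and produces the per-breath
scalars the capnodynamic solver consumes: the mean alveolar CO2 fraction
FACO2 from the mid-portion of phase III, the CO2 eliminated per breath
VTCO2, the Fowler airway dead space, and the end-tidal / mixed-expired
partial pressures that feed the Bohr and Enghoff dead-space ratios.

All integrals are taken in the expired-volume domain, so features are
invariant to how the signal is sampled in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .config import DEFAULT_CONFIG, RunConfig

FA_MAX = 0.15


class SegmentationError(ValueError):
    """No inspiration onsets could be found in the trace."""


class FeatureError(ValueError):
    """The breath lacks a usable expiratory phase."""


@dataclass
class BreathSignal:
    """Sampled intra-breath trace: time [s], flow [L/s] (inspiration
    positive), CO2 fraction at the airway opening."""

    t: np.ndarray
    flow: np.ndarray
    fco2: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.fco2 = np.asarray(self.fco2, dtype=float)
        if not (len(self.t) == len(self.flow) == len(self.fco2)):
            raise ValueError("t, flow, fco2 must have equal length")
        if len(self.t) >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.fco2 < 0) or np.any(self.fco2 >= FA_MAX):
            raise ValueError(f"fco2 must lie in [0, {FA_MAX})")

    @property
    def duration_s(self) -> float:
        dt = np.median(np.diff(self.t)) if len(self.t) > 1 else 0.0
        return float(self.t[-1] - self.t[0] + dt)


@dataclass
class BreathFeatures:
    """Per-breath scalars consumed by the capnodynamic solver.

    ``flags`` collects soft quality findings (e.g. a negative-slope plateau
    making PETCO2 exceed the alveolar estimate); ``valid`` is False when
    features could not be measured meaningfully (e.g. no expired CO2).
    """

    faco2: float  # mean alveolar CO2 fraction (mid phase III)
    vtco2: float  # CO2 eliminated [L]
    dt: float  # breath duration [min]
    vt_exp: float  # expired volume [L]
    vdaw: float  # Fowler airway dead space [L]
    petco2: float  # end-tidal PCO2 [mmHg]
    peco2: float  # mixed-expired PCO2 [mmHg]
    valid: bool = True
    flags: tuple[str, ...] = ()


def segment_breaths(
    signal: BreathSignal,
    threshold_lps: float = 0.02,
    debounce_s: float = 0.1,
) -> list[BreathSignal]:
    """Split a continuous trace into breaths at inspiration onsets.

    An onset is a rising crossing of ``threshold_lps`` whose following
    ``debounce_s`` of flow stays non-negative on average; crossings within
    the debounce window of an accepted onset are ignored. Samples before
    the first onset are discarded; each segment runs from its onset to the
    next (the final segment runs to the end of the trace).
    """
    flow, t = signal.flow, signal.t
    if len(t) < 4:
        raise SegmentationError("trace too short to segment")
    dt = float(np.median(np.diff(t)))
    win = max(int(round(debounce_s / dt)), 1)

    rising = np.nonzero((flow[1:] >= threshold_lps) & (flow[:-1] < threshold_lps))[0] + 1
    candidates = list(rising)
    if flow[0] >= threshold_lps:  # trace starts mid-onset
        candidates.insert(0, 0)
    onsets: list[int] = []
    for i in candidates:
        if onsets and (i - onsets[-1]) < win:
            continue
        if np.mean(flow[i : i + win]) < 0:
            continue
        onsets.append(i)
    if not onsets:
        raise SegmentationError("no inspiration onsets found")

    bounds = onsets + [len(t)]
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 4:
            continue
        segments.append(BreathSignal(t=t[a:b] - t[a], flow=flow[a:b], fco2=signal.fco2[a:b]))
    return segments


def _expired_volume_axis(breath: BreathSignal) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative expired volume [L] and the expiratory-flow magnitude."""
    exh = np.where(breath.flow < 0, -breath.flow, 0.0)
    dt = np.diff(breath.t)
    v = np.concatenate([[0.0], np.cumsum((exh[1:] + exh[:-1]) / 2.0 * dt)])
    return v, exh


def extract_features(
    breath: BreathSignal, config: RunConfig = DEFAULT_CONFIG
) -> BreathFeatures:
    """Compute per-breath capnodynamic features from a sampled breath.

    VTCO2 is the volume-domain integral of expired CO2; FACO2 the
    volume-weighted mean CO2 fraction over the configured mid-portion of
    phase III (default 55-85% of expired volume); the airway dead space is
    obtained by the Fowler equal-area construction: the back-extrapolated
    phase III line, truncated to a square front at VDaw, must eliminate the
    same CO2 volume as the measured capnogram.
    """
    v_exp, exh = _expired_volume_axis(breath)
    vt_exp = float(v_exp[-1])
    if vt_exp <= 0:
        raise FeatureError("no expired volume in breath")
    dt_s = np.diff(breath.t)
    mid = (breath.fco2[1:] + breath.fco2[:-1]) / 2.0
    exh_mid = (exh[1:] + exh[:-1]) / 2.0
    vtco2 = float(np.sum(mid * exh_mid * dt_s))
    dt_min = breath.duration_s / 60.0
    pdry = config.dry_pressure_mmHg
    peco2 = vtco2 / vt_exp * pdry

    flags: list[str] = []
    if vtco2 <= 0 or np.all(breath.fco2 <= 1e-9):
        return BreathFeatures(
            faco2=0.0, vtco2=max(vtco2, 0.0), dt=dt_min, vt_exp=vt_exp,
            vdaw=vt_exp, petco2=0.0, peco2=max(peco2, 0.0),
            valid=False, flags=("no_expired_co2",),
        )

    # resample the capnogram onto the expired-volume axis (dedupe pauses)
    keep = np.concatenate([[True], np.diff(v_exp) > 0])
    v_u, f_u = v_exp[keep], breath.fco2[keep]
    lo, hi = config.phase3_bounds
    grid = np.linspace(lo * vt_exp, hi * vt_exp, 64)
    faco2 = float(np.mean(np.interp(grid, v_u, f_u)))

    # end-tidal fraction at the end of active expiration
    petco2 = float(breath.fco2[int(np.argmax(v_exp))] * pdry)
    if petco2 > faco2 * pdry + 1e-9:
        flags.append("petco2_above_alveolar")

    # Fowler dead space: fit the phase III line on the mid-portion, then
    # solve  integral_{VD}^{VT} line(v) dv = VTCO2  for VD (equal areas).
    b, a = np.polyfit(grid, np.interp(grid, v_u, f_u), 1)

    def square_front_vtco2(vd: float) -> float:
        return a * (vt_exp - vd) + b / 2.0 * (vt_exp**2 - vd**2)

    g0, g1 = square_front_vtco2(0.0) - vtco2, square_front_vtco2(vt_exp) - vtco2
    if g0 <= 0.0:
        vdaw = 0.0
        flags.append("vdaw_at_lower_bound")
    elif g1 >= 0.0:
        vdaw = vt_exp
        flags.append("vdaw_at_upper_bound")
    else:
        vdaw = float(
            brentq(lambda vd: square_front_vtco2(vd) - vtco2, 0.0, vt_exp, xtol=1e-9)
        )

    return BreathFeatures(
        faco2=faco2, vtco2=vtco2, dt=dt_min, vt_exp=vt_exp, vdaw=vdaw,
        petco2=petco2, peco2=peco2, valid=True, flags=tuple(flags),
    )


def deadspace_ratio(
    features: BreathFeatures,
    paco2: float | None = None,
    mode: str = "bohr",
    config: RunConfig = DEFAULT_CONFIG,
) -> float:
    """Physiological dead-space fraction by Bohr or Enghoff.

    Bohr uses the alveolar PCO2 from the capnogram (PACO2 = FACO2*(Pb-PH2O));
    Enghoff substitutes the arterial PCO2 and therefore also captures the
    shunt effect, so Enghoff >= Bohr whenever PaCO2 >= PACO2.
    """
    if mode == "bohr":
        ref = features.faco2 * config.dry_pressure_mmHg
    elif mode == "enghoff":
        if paco2 is None:
            raise ValueError("mode='enghoff' requires an arterial PCO2")
        ref = paco2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if ref == 0:
        raise ZeroDivisionError("reference PCO2 is zero")
    return float((ref - features.peco2) / ref)
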