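"""Forward one-compartment lung model for expired CO2 kinetics.

The simulator advances a single well-mixed alveolar compartment breath by
breath under the modified capnodynamic breathing pattern (expiratory holds
on the final 3 of every 9 breaths). Each breath obeys the CO2 mole balance

    V_eff * (FA^n - FA^{n-1}) = Q * dt^n * (CvCO2 - CcCO2^n) - VTCO2^n

where FA is the end-expiratory alveolar CO2 fraction, Q the effective
(non-shunted) pulmonary blood flow, CvCO2 / CcCO2 mixed-venous and
end-capillary CO2 content, and VTCO2 the CO2 eliminated by the breath.
The buffering volume seen by CO2 is larger than the alveolar gas volume:

    V_eff = eelv_alv * (1 + store_fraction) + vdaw

The store term represents CO2 dissolved in lung tissue and capillary blood
that equilibrates with the alveolar fraction (store_fraction 0.25 puts the
stores at 20% of the total lung CO2 capacity), and the airway dead space
holds alveolar gas at end-expiration that is re-inspired into the
compartment, so the tracer "sees" it as well. This is exactly why an
estimator fitting V_eff overestimates the alveolar gas volume and why the
dead-space subtraction and the 0.8 store correction are applied downstream.

Ground truth is explicit (:class:`LungTruth`), making the simulator the
oracle for parameter-recovery tests of the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .blood import co2_content
from .capno import BreathSignal
from .config import DEFAULT_CONFIG, RunConfig

#: Upper bracket for the alveolar CO2 fraction; beyond this the state is
#: treated as non-physiological.
FA_MAX = 0.15
#: Absolute tolerance of the implicit per-breath solve (on the fraction).
FA_TOL = 1e-9


class NonPhysiologicalStateError(ValueError):
    """The per-breath mole balance has no root in the physiological band."""


class InsufficientDataError(ValueError):
    """Fewer breaths than the capnodynamic cycle requires."""


@dataclass(frozen=True)
class LungTruth:
    """Ground-truth physiological state of the simulated lung.

    Parameters
    ----------
    eelv_alv
        True alveolar end-expiratory gas volume [L].
    epbf
        Effective (non-shunted) pulmonary blood flow [L/min].
    cvco2
        Mixed-venous CO2 content [Lgas/Lblood].
    vdaw
        Airway dead space [L].
    hb
        Hemoglobin [g/dL], input to the dissociation curve.
    store_fraction
        Extra-alveolar CO2 store as a fraction of the alveolar CO2
        capacity; 0.25 makes the stores 20% of the total lung CO2.
    siii_slope
        Phase III slope of the synthetic capnogram [fraction per L].
    """

    eelv_alv: float = 1.5
    epbf: float = 4.0
    cvco2: float = 0.55
    vdaw: float = 0.15
    hb: float = 10.0
    store_fraction: float = 0.25
    siii_slope: float = 0.005

    def __post_init__(self) -> None:
        if self.eelv_alv <= 0:
            raise ValueError("eelv_alv must be positive")
        if self.epbf <= 0:
            raise ValueError("epbf must be positive")
        if not (0.0 < self.cvco2 < 1.0):
            raise ValueError("cvco2 must lie in (0, 1) Lgas/Lblood")
        if self.vdaw < 0:
            raise ValueError("vdaw must be non-negative")
        if self.store_fraction < 0:
            raise ValueError("store_fraction must be non-negative")

    @property
    def buffering_volume(self) -> float:
        """Effective CO2 buffering volume V_eff [L] (alveoli + stores + airway)."""
        return self.eelv_alv * (1.0 + self.store_fraction) + self.vdaw


@dataclass(frozen=True)
class BreathPattern:
    """Modified cyclic breathing pattern with expiratory holds.

    ``cycle`` holds 9 per-breath hold flags; by default the final 3 breaths
    of the cycle carry a hold, which extends the expiratory pause by
    ``hold_s`` seconds without adding expired volume.
    """

    rr: float = 20.0
    vt: float = 0.45
    cycle: tuple[bool, ...] = (False,) * 6 + (True,) * 3
    hold_s: float = 2.0
    fs_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.rr <= 0 or self.vt <= 0:
            raise ValueError("rr and vt must be positive")
        if len(self.cycle) != 9 or sum(self.cycle) != 3:
            raise ValueError("cycle must contain 9 flags with exactly 3 holds")
        if self.hold_s < 0 or self.fs_hz <= 0:
            raise ValueError("hold_s must be >= 0 and fs_hz > 0")

    def dt_min(self, index: int) -> float:
        """Cycle time of breath ``index`` [min], hold-extended when flagged."""
        base = 60.0 / self.rr
        if self.cycle[index % 9]:
            base += self.hold_s
        return base / 60.0

    def is_hold(self, index: int) -> bool:
        return bool(self.cycle[index % 9])


@dataclass
class BreathRecord:
    """Per-breath simulator output consumed by feature tables and the solver."""

    index: int
    dt: float  # cycle time [min]
    hold: bool
    faco2: float  # end-of-breath alveolar CO2 fraction
    vtco2: float  # CO2 eliminated this breath [L]
    signal: BreathSignal | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 < self.faco2 < FA_MAX):
            raise ValueError(f"faco2={self.faco2!r} outside (0, {FA_MAX})")
        if self.vtco2 < 0:
            raise ValueError("vtco2 must be non-negative")


def step_breath(
    state_faco2: float,
    truth: LungTruth,
    dt: float,
    vt: float,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[float, float]:
    """Advance the alveolar CO2 fraction by one breath.

    Solves the implicit per-breath mole balance for the new end-expiratory
    fraction FA^n, with CO2 elimination VTCO2 = FA^n * (vt - vdaw) and
    end-capillary content taken at the new alveolar PCO2. The root is
    bracketed in (0, 0.15) and found to 1e-9 on the fraction.

    Returns
    -------
    (new_faco2, vtco2)
    """
    if not (0.0 < state_faco2 < FA_MAX):
        raise NonPhysiologicalStateError(
            f"state_faco2={state_faco2!r} outside (0, {FA_MAX})"
        )
    veff = truth.buffering_volume
    vat = max(vt - truth.vdaw, 0.0)  # alveolar tidal volume
    pdry = config.dry_pressure_mmHg

    def balance(fa: float) -> float:
        cc = co2_content(fa * pdry, truth.hb)
        influx = truth.epbf * dt * (truth.cvco2 - cc)
        return veff * (fa - state_faco2) - (influx - fa * vat)

    lo, hi = 1e-12, FA_MAX - 1e-12
    if balance(lo) * balance(hi) > 0:
        raise NonPhysiologicalStateError(
            "per-breath mole balance has no root in (0, 0.15); "
            "check truth parameters"
        )
    fa_new = brentq(balance, lo, hi, xtol=FA_TOL)
    return float(fa_new), float(fa_new * vat)


def steady_state_faco2(
    truth: LungTruth,
    pattern: BreathPattern,
    config: RunConfig = DEFAULT_CONFIG,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> float:
    """Fixed point of a plain (no-hold) breath; used to seed simulations."""
    dt = 60.0 / pattern.rr / 60.0
    fa = 0.05
    for _ in range(max_iter):
        fa_next, _ = step_breath(fa, truth, dt, pattern.vt, config)
        if abs(fa_next - fa) < tol:
            return fa_next
        fa = fa_next
    return fa


def simulate_sequence(
    truth: LungTruth,
    pattern: BreathPattern,
    n_breaths: int,
    noise_sd_faco2: float | Sequence[float] = 0.0,
    seed: int | None = None,
    config: RunConfig = DEFAULT_CONFIG,
    truth_schedule: Sequence[LungTruth] | None = None,
) -> list[BreathRecord]:
    """Simulate ``n_breaths`` breaths under the 9-breath hold pattern.

    The compartment starts at the no-hold steady state so the recorded
    sequence settles into an exactly 9-periodic trajectory within a few
    cycles. Gaussian measurement noise (SD ``noise_sd_faco2``, scalar or
    per-breath) is added to the *recorded* alveolar fraction only; the
    state evolution itself is exact. ``truth_schedule`` optionally replaces
    the truth per breath (e.g. a step change in EELV).
    """
    if n_breaths < 9:
        raise InsufficientDataError("need at least one full 9-breath cycle")
    sd = np.broadcast_to(np.asarray(noise_sd_faco2, dtype=float), (n_breaths,))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n_breaths) * sd

    fa = steady_state_faco2(truth, pattern, config)
    records: list[BreathRecord] = []
    for n in range(n_breaths):
        tr = truth_schedule[n] if truth_schedule is not None else truth
        dt = pattern.dt_min(n)
        fa, vtco2 = step_breath(fa, tr, dt, pattern.vt, config)
        faco2_meas = float(np.clip(fa + noise[n], 1e-6, FA_MAX - 1e-6))
        records.append(
            BreathRecord(
                index=n, dt=dt, hold=pattern.is_hold(n), faco2=faco2_meas, vtco2=vtco2
            )
        )
    return records


# --------------------------------------------------------------------------
# Waveform synthesis
# --------------------------------------------------------------------------

def synthesize_waveform(
    record: BreathRecord,
    truth: LungTruth,
    pattern: BreathPattern,
    config: RunConfig = DEFAULT_CONFIG,
) -> BreathSignal:
    """Render a sampled flow / CO2-fraction trace for one breath.

    Flow is a half-sinusoid inspiration followed by an exponential
    expiration (time constant te/4), zero during the expiratory pause;
    the sampled inspired and expired volumes are normalized to ``vt``.
    The expired CO2 fraction follows the classic volumetric capnogram:
    phase I at zero over the airway dead space, a sigmoidal phase II front,
    and a linear phase III whose mid-portion mean equals ``record.faco2``.
    The phase II front position is solved so that the CO2 eliminated by the
    sampled trace equals ``record.vtco2`` exactly, which lands the Fowler
    dead space of the trace at the true ``vdaw`` up to the (small) slope
    asymmetry of the plateau.
    """
    fs = pattern.fs_hz
    total_s = record.dt * 60.0
    base_s = 60.0 / pattern.rr
    ti = base_s / 3.0  # inspiratory time, I:E = 1:2 of the plain breath
    te = base_s - ti  # active expiratory time; holds extend the pause
    n = max(int(round(total_s * fs)), 8)
    t = np.arange(n) / fs
    dt_s = 1.0 / fs

    flow = np.zeros(n)
    insp = t < ti
    flow[insp] = np.sin(np.pi * t[insp] / ti)
    exp_phase = (t >= ti) & (t < ti + te)
    tau = te / 4.0
    flow[exp_phase] = -np.exp(-(t[exp_phase] - ti) / tau)
    # normalize the *sampled* integrals to vt so conservation holds exactly
    vi = np.trapezoid(np.where(flow > 0, flow, 0.0), dx=dt_s)
    ve = np.trapezoid(np.where(flow < 0, -flow, 0.0), dx=dt_s)
    flow[flow > 0] *= pattern.vt / vi
    flow[flow < 0] *= pattern.vt / ve

    # expired volume axis (monotone during expiration, flat in the pause)
    exh = np.where(flow < 0, -flow, 0.0)
    v_exp = np.concatenate([[0.0], np.cumsum((exh[1:] + exh[:-1]) / 2.0 * dt_s)])

    vt = pattern.vt
    slope = truth.siii_slope
    v_mid = 0.5 * (config.phase3_bounds[0] + config.phase3_bounds[1]) * vt
    width = max(0.1 * truth.vdaw, 1e-3)

    def trace(front: float) -> np.ndarray:
        plateau = record.faco2 + slope * (v_exp - v_mid)
        fco2 = plateau / (1.0 + np.exp(-(v_exp - front) / width))
        return np.clip(fco2, 0.0, FA_MAX)

    def eliminated(front: float) -> float:
        y = trace(front) * exh
        return float(np.trapezoid(y, dx=dt_s))

    target = record.vtco2
    lo, hi = 1e-6, 0.95 * vt
    if eliminated(lo) < target:
        front = lo  # no dead space can absorb the mismatch; accept
    elif eliminated(hi) > target:
        front = hi
    else:
        front = brentq(lambda c: eliminated(c) - target, lo, hi, xtol=1e-9)

    fco2 = trace(front)
    # sensor sees static end-expiratory gas during the pause, inspired gas is CO2-free
    end_exp = np.argmax(v_exp)
    fco2[insp] = 0.0
    pause = t >= ti + te
    fco2[pause] = fco2[end_exp]
    return BreathSignal(t=t, flow=flow, fco2=fco2)


def attach_waveforms(
    records: list[BreathRecord],
    truth: LungTruth,
    pattern: BreathPattern,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[BreathRecord]:
    """Return records with synthesized waveforms attached."""
    return [
        replace(r, signal=synthesize_waveform(r, truth, pattern, config))
        for r in records
    ]


def concatenate_signals(records: list[BreathRecord]) -> BreathSignal:
    """Join per-breath waveforms into one continuous trace."""
    sigs = [r.signal for r in records]
    if any(s is None for s in sigs):
        raise ValueError("records must carry waveforms; call attach_waveforms first")
    t_parts, offset = [], 0.0
    for s in sigs:
        t_parts.append(s.t + offset)
        offset += s.t[-1] + (s.t[1] - s.t[0])
    return BreathSignal(
        t=np.concatenate(t_parts),
        flow=np.concatenate([s.flow for s in sigs]),
        fco2=np.concatenate([s.fco2 for s in sigs]),
    )
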