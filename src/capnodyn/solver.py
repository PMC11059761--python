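"""The capnodynamic estimator.

Over a sliding window of 9 consecutive breaths (plus the predecessor
breath, which supplies the first FA^{n-1}) each breath contributes one
mole-balance equation

    V * (FA^n - FA^{n-1}) = Q * dt^n * (CvCO2 - CcCO2^n) - VTCO2^n

in the three unknowns V (effective CO2 lung volume), Q (effective
pulmonary blood flow) and CvCO2 (mixed-venous CO2 content), assumed
constant within the window. With the substitution W = Q*CvCO2 the system
is linear and is solved by ordinary least squares; the linear estimate is
then refined by minimizing the RMS difference between the measured FA
sequence and the FA trajectory re-simulated from (V, Q, CvCO2) by the
one-compartment forward model, which is the quantity reported as the fit
error (in mmHg) and used to gate noisy periods.

The fitted V is the volume CO2 equilibrates with: alveolar gas plus
airway dead-space gas plus dissolved stores. Two corrections recover the
alveolar gas volume: the airway dead space is subtracted (eelv_raw), and
the store content is removed with the fixed factor eelv_corr = 0.8 *
eelv_raw, which exactly inverts a store capacity of 25% of the alveolar
capacity (stores = 20% of the total).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .blood import co2_content
from .capno import BreathFeatures
from .config import DEFAULT_CONFIG, RunConfig

WINDOW = 9
#: Store correction: alveolar gas / (gas + dissolved CO2 stores).
STORE_CORRECTION = 0.8
FA_MAX = 0.15


class SingularSystemError(ValueError):
    """The window carries no alveolar CO2 modulation; V is unidentifiable."""


class CorrectionError(ValueError):
    """Dead-space subtraction would leave a non-positive volume."""


class NoStablePeriodError(ValueError):
    """No contiguous run of valid estimates of the required length."""


@dataclass
class CapnoEstimate:
    """Solver output for one 9-breath window."""

    eelv_raw: float  # fitted volume minus airway dead space [L]
    eelv_corr: float  # store-corrected alveolar volume [L]
    epbf: float  # effective pulmonary blood flow [L/min]
    cvco2: float  # mixed-venous CO2 content [Lgas/Lblood]
    fit_error: float  # RMS FA residual [mmHg]
    valid: bool
    window_end_index: int
    diagnostic: str = ""

    def __post_init__(self) -> None:
        if self.fit_error < 0 or not np.isfinite(self.fit_error):
            raise ValueError("fit_error must be finite and non-negative")


@dataclass
class StablePeriod:
    """Mean estimate over the longest contiguous run of valid windows."""

    eelv_raw: float
    eelv_corr: float
    epbf: float
    cvco2: float
    sd_eelv_corr: float
    start_index: int
    end_index: int
    n: int


def build_system(
    window: Sequence[BreathFeatures],
    fa_prev: float,
    hb: float,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the 9x3 linear system A @ (V, Q, W) = b.

    Row n:  V*(FA^n - FA^{n-1}) + Q*(dt^n * Cc^n) - W*dt^n = -VTCO2^n,
    with Cc^n the end-capillary content at the measured alveolar PCO2 and
    ``fa_prev`` supplying FA^{n-1} for the first row.
    """
    if len(window) != WINDOW:
        raise SingularSystemError(f"window must contain exactly {WINDOW} breaths")
    fa = np.array([f.faco2 for f in window])
    dt = np.array([f.dt for f in window])
    vtco2 = np.array([f.vtco2 for f in window])
    dfa = np.diff(np.concatenate([[fa_prev], fa]))
    if np.allclose(dfa, 0.0):
        raise SingularSystemError(
            "alveolar CO2 fraction is constant across the window; "
            "no pattern modulation to identify the lung volume"
        )
    cc = co2_content(fa * config.dry_pressure_mmHg, hb)
    A = np.column_stack([dfa, dt * cc, -dt])
    b = -vtco2
    return A, b


def _forward_fa(
    params: np.ndarray,
    fa_prev: float,
    dt: np.ndarray,
    vtco2: np.ndarray,
    hb: float,
    pdry: float,
) -> np.ndarray:
    """Re-simulate the window's FA trajectory from (V, Q, CvCO2).

    The measured per-breath CO2 eliminations are taken as known, so each
    breath requires solving V*(FA - FA_prev) = Q*dt*(Cv - Cc(FA)) - VTCO2
    for FA (bracketed; monotone in FA)."""
    v, q, cv = params
    fa_model = np.empty(len(dt))
    fa = fa_prev
    for n in range(len(dt)):
        def bal(x: float) -> float:
            return v * (x - fa) - (q * dt[n] * (cv - co2_content(x * pdry, hb)) - vtco2[n])
        lo, hi = 1e-9, FA_MAX
        if bal(lo) * bal(hi) > 0:  # outside the physiological band
            fa = lo if bal(lo) > 0 else hi
        else:
            fa = brentq(bal, lo, hi, xtol=1e-12)
        fa_model[n] = fa
    return fa_model


def solve_window(
    window: Sequence[BreathFeatures],
    fa_prev: float,
    hb: float,
    config: RunConfig = DEFAULT_CONFIG,
    window_end_index: int = WINDOW,
) -> CapnoEstimate:
    """Estimate (EELV, EPBF, CvCO2) from one 9-breath window.

    Linear least squares on (V, Q, W=Q*CvCO2) seeds a bounded nonlinear
    refinement of the FA-trajectory fit; the estimate is flagged invalid
    (never raised) when the fit error exceeds the configured threshold,
    a parameter sits outside its physiological bounds, or the optimizer
    fails.
    """
    fa = np.array([f.faco2 for f in window])
    dt = np.array([f.dt for f in window])
    vtco2 = np.array([f.vtco2 for f in window])
    vdaw = float(np.mean([f.vdaw for f in window]))
    pdry = config.dry_pressure_mmHg

    A, b = build_system(window, fa_prev, hb, config)
    theta, *_ = np.linalg.lstsq(A, b, rcond=None)
    v0, q0, w0 = theta
    (v_lo, v_hi), (q_lo, q_hi) = config.v_bounds_l, config.q_bounds_lpm
    cv_lo, cv_hi = config.cvco2_bounds
    x0 = np.array([
        np.clip(v0, v_lo * 1.001, v_hi * 0.999),
        np.clip(q0, q_lo * 1.001, q_hi * 0.999),
        np.clip(w0 / q0 if q0 > 0 else 0.5, cv_lo * 1.001, cv_hi * 0.999),
    ])

    def residual(p: np.ndarray) -> np.ndarray:
        return (_forward_fa(p, fa_prev, dt, vtco2, hb, pdry) - fa) * pdry

    diagnostic = ""
    try:
        res = least_squares(
            residual, x0,
            bounds=([v_lo, q_lo, cv_lo], [v_hi, q_hi, cv_hi]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=200,
        )
        v, q, cv = res.x
        fit_error = float(np.sqrt(np.mean(res.fun**2)))
        if not res.success:
            diagnostic = f"optimizer: {res.message}"
    except Exception as exc:  # never crash the continuous stream
        v, q, cv = x0
        fit_error = float(np.sqrt(np.mean(residual(x0) ** 2)))
        diagnostic = f"refinement failed: {exc}"

    in_bounds = (v_lo < v < v_hi) and (q_lo < q < q_hi) and (cv_lo < cv < cv_hi)
    try:
        eelv_raw, eelv_corr = apply_corrections(v, vdaw)
    except CorrectionError as exc:
        eelv_raw, eelv_corr = float("nan"), float("nan")
        diagnostic = diagnostic or str(exc)
        in_bounds = False
    valid = (
        in_bounds
        and not diagnostic
        and fit_error < config.fit_error_threshold_mmHg
    )
    return CapnoEstimate(
        eelv_raw=eelv_raw, eelv_corr=eelv_corr, epbf=float(q), cvco2=float(cv),
        fit_error=fit_error, valid=valid,
        window_end_index=window_end_index, diagnostic=diagnostic,
    )


def apply_corrections(eelv_fit: float, vdaw: float) -> tuple[float, float]:
    """Airway dead-space subtraction and the 0.8 store correction.

    Returns (eelv_raw, eelv_corr) with eelv_raw = eelv_fit - vdaw and
    eelv_corr = 0.8 * eelv_raw, always exactly in that ratio.
    """
    if vdaw < 0:
        raise CorrectionError("vdaw must be non-negative")
    if eelv_fit <= vdaw:
        raise CorrectionError(
            f"fitted volume {eelv_fit:.3f} L does not exceed dead space {vdaw:.3f} L"
        )
    eelv_raw = eelv_fit - vdaw
    return eelv_raw, STORE_CORRECTION * eelv_raw


def stream_estimates(
    breaths: Sequence[BreathFeatures],
    hb: float,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[CapnoEstimate]:
    """Continuous breath-by-breath estimation over a sliding 9-breath window.

    Each new breath replaces the oldest one in the window; the first nine
    breaths (window fill plus the predecessor for the first equation) yield
    no output, so n breaths in give n - 9 estimates out. Invalid windows
    are flagged in place, keeping the series gap-free.
    """
    n = len(breaths)
    if n < WINDOW + 1:
        raise SingularSystemError(
            f"need at least {WINDOW + 1} breaths (9-window plus predecessor)"
        )
    out = []
    for end in range(WINDOW, n):
        window = breaths[end - WINDOW + 1 : end + 1]
        fa_prev = breaths[end - WINDOW].faco2
        out.append(
            solve_window(window, fa_prev, hb, config, window_end_index=end)
        )
    return out


def select_stable_period(
    estimates: Sequence[CapnoEstimate],
    min_duration_breaths: int = 10,
    error_threshold_mmHg: float | None = None,
) -> StablePeriod:
    """Summarize the longest contiguous run of low-error estimates.

    A window qualifies when it is valid and (optionally) its fit error is
    below ``error_threshold_mmHg``; the longest qualifying run of at least
    ``min_duration_breaths`` windows is averaged. Emulates picking a
    stable, representative period of a continuous recording for comparison
    against a one-shot reference measurement.
    """
    ok = [
        e.valid and (error_threshold_mmHg is None or e.fit_error < error_threshold_mmHg)
        for e in estimates
    ]
    best_len, best_start, run_start = 0, -1, None
    for i, flag in enumerate(ok + [False]):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len < min_duration_breaths:
        raise NoStablePeriodError(
            f"no contiguous valid run of >= {min_duration_breaths} estimates"
        )
    run = estimates[best_start : best_start + best_len]
    corr = np.array([e.eelv_corr for e in run])
    return StablePeriod(
        eelv_raw=float(np.mean([e.eelv_raw for e in run])),
        eelv_corr=float(np.mean(corr)),
        epbf=float(np.mean([e.epbf for e in run])),
        cvco2=float(np.mean([e.cvco2 for e in run])),
        sd_eelv_corr=float(np.std(corr, ddof=1)) if len(run) > 1 else 0.0,
        start_index=run[0].window_end_index,
        end_index=run[-1].window_end_index,
        n=len(run),
    )
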