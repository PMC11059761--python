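"""Method-agreement statistics and predicted-FRC reference values.

Bland-Altman agreement (bias = mean paired difference, limits of agreement
= bias +/- 1.96 * SD of the differences), squared Pearson correlation,
a Shapiro-Wilk normality gate, and the supine sex-specific predicted
functional residual capacity used to express measured lung volumes as a
fraction of the expected healthy value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .config import DEFAULT_CONFIG, RunConfig


@dataclass
class AgreementResult:
    """Bland-Altman summary of a paired method comparison."""

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    r2: float

    def __post_init__(self) -> None:
        if not np.isclose(self.loa_upper, self.bias + 1.96 * self.sd_diff):
            raise ValueError("loa_upper must equal bias + 1.96*sd_diff")
        if not np.isclose(self.loa_lower, self.bias - 1.96 * self.sd_diff):
            raise ValueError("loa_lower must equal bias - 1.96*sd_diff")

    def to_dict(self) -> dict:
        return {
            "n": self.n, "bias": self.bias, "sd_diff": self.sd_diff,
            "loa_lower": self.loa_lower, "loa_upper": self.loa_upper,
            "r2": self.r2,
        }


def bland_altman(
    method: np.ndarray,
    reference: np.ndarray,
    config: RunConfig = DEFAULT_CONFIG,
) -> AgreementResult:
    """Bland-Altman comparison of a method against a reference.

    With the default ``diff_sign`` convention the differences are
    reference - method, so a method that overestimates the reference shows
    a *negative* bias. ``r2`` is the squared Pearson correlation of the
    paired values; SD uses the n-1 (sample) denominator.
    """
    m = np.asarray(method, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError("method and reference must be equal-length 1-D series")
    if len(m) < 3:
        raise ValueError("need at least 3 pairs")
    diff = r - m if config.diff_sign == "reference-method" else m - r
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if np.std(m) == 0 or np.std(r) == 0:
        r2 = 1.0 if np.allclose(m - m.mean(), r - r.mean()) else 0.0
    else:
        r2 = float(sps.pearsonr(m, r).statistic ** 2)
    return AgreementResult(
        n=len(m), bias=bias, sd_diff=sd,
        loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd, r2=r2,
    )


#: Supine predicted FRC [L] as a function of height: slope, intercept per sex.
_FRC_COEF = {"male": (5.48, -7.05), "female": (1.39, -0.424)}


def predicted_frc(height_cm: float, sex: str) -> float:
    """Predicted supine functional residual capacity [L].

    FRC = 5.48 * (height_cm/100) - 7.05 for men and
    FRC = 1.39 * (height_cm/100) - 0.424 for women.
    """
    if sex not in _FRC_COEF:
        raise ValueError("sex must be 'male' or 'female'")
    if not (100.0 < height_cm < 230.0):
        raise ValueError(f"height_cm={height_cm!r} outside the supported range")
    slope, intercept = _FRC_COEF[sex]
    frc = slope * (height_cm * 0.01) + intercept
    if frc <= 0:
        raise ValueError(
            f"predicted FRC non-positive ({frc:.2f} L) at {height_cm} cm; "
            "formula outside its physiological domain"
        )
    return frc


def percent_difference(part: float, whole: float) -> float:
    """100 * part / whole."""
    if whole == 0:
        raise ZeroDivisionError("whole must be non-zero")
    return 100.0 * part / whole


def normality_check(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk test; returns (W, p, passed at alpha).

    Used as a reporting gate before Bland-Altman, not as an inference step.
    """
    x = np.asarray(values, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no defined normality statistic")
    w, p = sps.shapiro(x)
    return float(w), float(p), bool(p >= alpha)
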