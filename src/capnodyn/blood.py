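"""CO2 carriage in whole blood.

The capnodynamic mole balance needs the CO2 *content* of pulmonary
end-capillary blood given its partial pressure. We use the empirical
whole-blood CO2 content model of Douglas, Jones & Reed (J Appl Physiol 1988):

    pK   = 6.086 + 0.042*(7.40 - pH) + (38 - T)*(0.00472 + 0.00139*(7.40 - pH))
    sCO2 = 0.0307 + 0.00057*(37 - T) + 0.00002*(37 - T)^2        [mM/mmHg]
    Cpl  = sCO2 * PCO2 * (1 + 10^(pH - pK))                      [mmol/L plasma]
    Cb   = Cpl * (1 - 0.0289*Hb / ((3.352 - 0.456*SO2)*(8.142 - pH)))

with Hb in g/dL and SO2 the fractional O2 saturation (the Haldane effect).
pH, temperature and saturation are held at fixed physiological values
(7.40, 37 degC, 0.97): within a 9-breath window the 2-3 mmHg alveolar CO2
modulation perturbs blood pH negligibly, and holding them fixed makes the
curve a strictly increasing function of PCO2 alone for a given hemoglobin.
Content is converted to L gas (STPD) per L blood with 22.26 L/mol for CO2.

The *same* function is used by the forward simulator and by the estimator,
so parameter recovery does not depend on which published curve is adopted.
"""

from __future__ import annotations

import numpy as np

#: CO2 molar volume at STPD [L/mmol] (real-gas value).
_L_PER_MMOL = 0.02226

#: Fixed operating point for the dissociation curve.
_PH = 7.40
_TEMP_C = 37.0
_SO2 = 0.97


def co2_content(pco2_mmHg: float | np.ndarray, hb_g_dl: float) -> float | np.ndarray:
    """Whole-blood CO2 content [L gas / L blood] at a given PCO2.

    Parameters
    ----------
    pco2_mmHg
        CO2 partial pressure [mmHg]; must be non-negative.
    hb_g_dl
        Hemoglobin concentration [g/dL]; accepted on (3, 25).

    Returns
    -------
    Content in L gas (STPD) per L blood; strictly increasing in ``pco2_mmHg``.
    """
    pco2 = np.asarray(pco2_mmHg, dtype=float)
    if np.any(pco2 < 0):
        raise ValueError("pco2_mmHg must be non-negative")
    if not (3.0 < hb_g_dl < 25.0):
        raise ValueError(f"hb_g_dl={hb_g_dl!r} outside the supported range (3, 25) g/dL")

    pk = 6.086 + 0.042 * (7.40 - _PH) + (38.0 - _TEMP_C) * (
        0.00472 + 0.00139 * (7.40 - _PH)
    )
    solubility = 0.0307 + 0.00057 * (37.0 - _TEMP_C) + 0.00002 * (37.0 - _TEMP_C) ** 2
    c_plasma = solubility * pco2 * (1.0 + 10.0 ** (_PH - pk))  # mmol/L plasma
    cell_factor = 1.0 - (0.0289 * hb_g_dl) / (
        (3.352 - 0.456 * _SO2) * (8.142 - _PH)
    )
    out = c_plasma * cell_factor * _L_PER_MMOL
    return float(out) if np.isscalar(pco2_mmHg) else out


def co2_content_slope(hb_g_dl: float) -> float:
    """d(content)/d(PCO2) [Lgas/Lblood per mmHg].

    With pH, temperature and saturation fixed the Douglas curve is linear in
    PCO2, so the slope fully characterizes it; exposed for analytic checks.
    """
    return float(co2_content(1.0, hb_g_dl))
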