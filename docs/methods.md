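# Methods

## The capnodynamic model

A single well-mixed alveolar compartment exchanges CO2 with pulmonary
capillary blood and with the airway. Writing FA^n for the end-expiratory
alveolar CO2 fraction after breath n, the per-breath mole balance is

    V_eff (FA^n − FA^{n−1}) = Q Δt^n (CvCO2 − CcCO2^n) − VTCO2^n

with Q the effective (non-shunted) pulmonary blood flow [L/min], Δt^n the
breath cycle time [min], CvCO2 and CcCO2^n the mixed-venous and
end-capillary CO2 contents [Lgas/Lblood], and VTCO2^n the CO2 volume
eliminated by the breath [L]. The left side is the change in the lung's CO2
store; the right side is supply by blood minus removal by ventilation.

The volume CO2 equilibrates with is larger than the alveolar gas volume:

    V_eff = EELV_alv · (1 + store_fraction) + VDaw

* `store_fraction` models CO2 dissolved in lung tissue and capillary blood
  that tracks the alveolar fraction. The default 0.25 puts the stores at
  20% of the total lung CO2 capacity, which is why the downstream
  correction `EELV_corr = 0.8 · EELV_raw` exactly inverts it.
* `VDaw` (airway dead space) is included because at end-expiration the
  conducting airways are filled with alveolar gas that is re-inspired into
  the compartment on the next breath; the tracer therefore "sees" it, and
  the estimator subtracts it afterwards (`EELV_raw = V_fit − VDaw`).

End-capillary content follows the alveolar partial pressure through a CO2
dissociation curve. We use the Douglas–Jones–Reed whole-blood content
model with hemoglobin as input and pH, temperature and O2 saturation held
at 7.40 / 37 °C / 0.97; over the 2–3 mmHg intra-cycle modulation the pH
feedback is negligible, and fixing it makes content strictly increasing
(in fact linear) in PCO2. The same function is used on the simulate and
the solve side, so parameter recovery does not depend on which published
curve was adopted. Partial pressures use PCO2 = fraction × (Pb − PH2O)
with Pb = 760 and PH2O = 47 mmHg.

## Forward simulator

Breaths follow a 9-breath cycle at rate `rr` (default 20/min) and tidal
volume `vt` (default 0.45 L); the final 3 breaths carry an expiratory hold
that extends Δt by `hold_s` (default 2 s) without adding expired volume.
Each breath update is the implicit equation above with
VTCO2 = FA^n (vt − VDaw), solved by bracketed root finding on FA ∈
(0, 0.15) to 1e−9. Sequences start from the no-hold fixed point, so the
noiseless trajectory becomes exactly 9-periodic within a few cycles;
under the defaults the intra-cycle alveolar PCO2 swing is ≈2.1 mmHg.
Measurement noise is Gaussian on the recorded FACO2 only (the state
evolves exactly, and VTCO2 is treated as a separate, much less noisy
integral measurement); it emulates plateau-reading scatter, not sensor
drift or cardiogenic oscillations.

Waveform synthesis renders a half-sinusoid inspiration and exponential
expiration (time constant te/4) at 100 Hz, normalized so sampled inspired
and expired volumes equal `vt` exactly, and a capnogram that is zero in
phase I, a narrow sigmoid front in phase II and a linear phase III whose
mid-portion mean equals the breath's FACO2. The front position is solved
so the trace eliminates exactly the breath's VTCO2; this lands the Fowler
dead space of the trace at the true VDaw up to the small plateau-slope
asymmetry (≈1% under defaults).

## Feature extraction

All capnogram integrals are taken in the expired-volume domain, making
features invariant to time resampling. FACO2 is the volume-weighted mean
CO2 fraction over 55–85% of expired volume (configurable; the clinical
bounds are not published). The Fowler airway dead space uses the
equal-area construction in its square-front form: VDaw is the volume at
which an ideal front followed by the back-extrapolated phase III line
eliminates the same CO2 as the measured capnogram; plateau ties resolve
by the brentq midpoint of the bracketing interval. Breaths are segmented
at rising flow crossings of 0.02 L/s debounced over 100 ms; partial
leading samples are discarded and the final segment runs to the end of
the trace.

## Estimator

Each window of 9 breaths plus its predecessor gives 9 equations in
(V, Q, W = Q·CvCO2), solved by ordinary least squares; the result seeds a
bounded trust-region refinement (`scipy.optimize.least_squares`) of the
RMS difference between measured FACO2 and the trajectory re-simulated
from (V, Q, CvCO2) with the measured VTCO2 as inputs. That RMS, in mmHg,
is the fit error; an estimate is flagged invalid (never dropped — the
breath-by-breath series stays gap-free) when the fit error exceeds the
gate (default 0.3 mmHg, a configurable engineering default) or a
parameter leaves its plausibility bounds (V ∈ 0.2–6 L, Q ∈ 0.5–15 L/min,
CvCO2 ∈ 0.3–1.0; guards, not physiology). `select_stable_period` averages
the longest contiguous valid run, emulating the selection of a stable
recording period for comparison against a one-shot reference.

### Precision under noise

Noiseless, model-matched windows are recovered to numerical tolerance
(≲1e−10 relative) for any physiological truth. Under iid Gaussian FACO2
noise the per-window precision is limited by the information in 9 plateau
readings modulated by only ~2 mmHg: at 0.36 mmHg noise SD the Cramér–Rao
bound for the fitted volume under the default conditions is ≈41% SD
(≈28% median absolute error), and Monte-Carlo shows the implemented
estimator sits on that floor (27.5% median; the efficiency is asserted in
the tests). Per-window volume errors of this size are intrinsic to the
9-breath design at that noise level; usable precision comes from
averaging the continuous stream over a stable period, which is how the
method is used clinically. Passing tests therefore demonstrate correct
mechanics and statistical efficiency, not single-window clinical accuracy
on real, heterogeneous lungs (which also violate the one-compartment and
constant-CvCO2 assumptions in ways the simulator does not emulate).

## CT densitometry

Per-voxel gas fraction is |HU|/1000 clamped to [0, 1] (−1000 HU = gas,
0 HU = water-density tissue). Total gas is summed over masked voxels with
HU ∈ [−1000, 0], functional gas over [−1000, −200]; both intervals are
closed at both ends (edge handling is unspecified in the literature, so
the convention is fixed and tested, and compartment additivity holds
exactly with the complementary interval open at −200). Voxels outside
[−1000, 0] are excluded from sums but counted in the QC report. Airways
are removed by mask subtraction; no automatic segmentation is attempted.
The phantom generator fills an ellipsoidal mask with a normal mixture of
aeration modes (≈ −750 / −300 / −50 HU) and rescales gas fractions
iteratively to a prescribed analytic gas volume within one voxel's gas
content, making it a self-verifying reference.

## Agreement statistics

Bland–Altman bias is the mean paired difference with limits of agreement
bias ± 1.96 × sample SD (no CI-of-LoA computation); by default
differences are reference − method, so an overestimating method shows a
negative bias (the sign convention is a config flag). r² is the squared
Pearson correlation of the paired values. Shapiro–Wilk (scipy) gates
normality reporting. Predicted supine FRC is 5.48·h/100 − 7.05 L (men)
and 1.39·h/100 − 0.424 L (women) with height h in cm, refused outside
100–230 cm or when the formula yields a non-positive volume.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on simulator- and
phantom-generated inputs: 12–54-breath sequences, 50-truth recovery
sweeps, 100-window noise Monte-Carlo, 46-patient synthetic cohorts and
~5e4-voxel phantoms — sizes chosen so a full run completes in about a
minute on one core while keeping Monte-Carlo assertions stable. All
randomness flows through `numpy.random.default_rng` seeds; identical
seeds give bit-identical sequences, estimates and phantoms.

## Known limitations

* One compartment: no ventilation/perfusion heterogeneity, shunt, O2
  kinetics or ventilator mechanics; the equivalence of corrected EELV and
  alveolar EELV is exact only because the simulator and the correction
  share the same store model.
* The dissociation curve's fixed pH ignores acid-base status; hemoglobin
  is the only blood input.
* The 0.8 store correction is a population average; regional tissue-to-gas
  variation is not modeled.
* CT densitometry assumes tissue at water density and ignores
  overdistension subclassification, DICOM assembly and registration.
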