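"""Capnodynamic estimator: system assembly, recovery, corrections, gating."""

import numpy as np
import pytest

from capnodyn import (
    BreathPattern,
    LungTruth,
    apply_corrections,
    build_system,
    select_stable_period,
    simulate_sequence,
    solve_window,
    stream_estimates,
)
from capnodyn.solver import (
    WINDOW,
    CorrectionError,
    NoStablePeriodError,
    SingularSystemError,
)


def window_and_predecessor(records):
    """Last 9 records as the window plus the FA of the breath before it."""
    return records[-WINDOW:], records[-WINDOW - 1].faco2


class TestBuildSystem:
    def test_noiseless_window_is_consistent(self, truth, pattern, features_of,
                                            noiseless_records):
        feats = features_of(noiseless_records, pattern, truth)
        window, fa_prev = window_and_predecessor(feats)
        A, b = build_system(window, fa_prev, hb=truth.hb)
        theta_true = np.array(
            [truth.buffering_volume, truth.epbf, truth.epbf * truth.cvco2]
        )
        assert np.abs(A @ theta_true - b).max() < 1e-8

    def test_constant_faco2_is_singular(self, truth, pattern, features_of,
                                        noiseless_records):
        feats = features_of(noiseless_records, pattern, truth)[-WINDOW:]
        for f in feats:
            f.faco2 = 0.05
        with pytest.raises(SingularSystemError):
            build_system(feats, 0.05, hb=truth.hb)

    def test_wrong_window_length_rejected(self, truth, pattern, features_of,
                                          noiseless_records):
        feats = features_of(noiseless_records, pattern, truth)
        with pytest.raises(SingularSystemError):
            build_system(feats[:5], feats[0].faco2, hb=truth.hb)

    def test_dt_scaling_touches_only_flow_columns(self, truth, pattern,
                                                  features_of, noiseless_records):
        feats = features_of(noiseless_records, pattern, truth)
        window, fa_prev = window_and_predecessor(feats)
        A1, b1 = build_system(window, fa_prev, hb=truth.hb)
        for f in window:
            f.dt *= 2.0
        A2, b2 = build_system(window, fa_prev, hb=truth.hb)
        assert np.allclose(A2[:, 0], A1[:, 0])  # volume column untouched
        assert np.allclose(A2[:, 1], 2.0 * A1[:, 1])
        assert np.allclose(A2[:, 2], 2.0 * A1[:, 2])
        assert np.allclose(b2, b1)


class TestSolveWindow:
    def test_exact_recovery_without_stores(self, pattern, features_of):
        truth = LungTruth(eelv_alv=1.5, epbf=4.0, cvco2=0.55, vdaw=0.15,
                          hb=10.0, store_fraction=0.0)
        recs = simulate_sequence(truth, pattern, 12, seed=2)
        feats = features_of(recs, pattern, truth)
        est = solve_window(feats[-WINDOW:], feats[-WINDOW - 1].faco2, hb=truth.hb)
        assert est.valid
        assert est.eelv_raw == pytest.approx(truth.eelv_alv, rel=1e-5)
        assert est.epbf == pytest.approx(truth.epbf, rel=1e-5)
        assert est.cvco2 == pytest.approx(truth.cvco2, rel=1e-5)

    def test_store_inversion(self, truth, pattern, features_of):
        # store_fraction 0.25: raw overestimates by 25%, the 0.8 correction
        # lands back on the true alveolar volume
        recs = simulate_sequence(truth, pattern, 12, seed=2)
        feats = features_of(recs, pattern, truth)
        est = solve_window(feats[-WINDOW:], feats[-WINDOW - 1].faco2, hb=truth.hb)
        assert est.eelv_raw == pytest.approx(1.25 * truth.eelv_alv, rel=1e-4)
        assert est.eelv_corr == pytest.approx(truth.eelv_alv, rel=1e-4)

    def test_exact_recovery_over_random_truths(self, pattern, features_of):
        rng = np.random.default_rng(11)
        for _ in range(6):
            truth = LungTruth(
                eelv_alv=float(rng.uniform(0.8, 3.0)),
                epbf=float(rng.uniform(2.5, 8.0)),
                cvco2=float(rng.uniform(0.45, 0.68)),
                vdaw=float(rng.uniform(0.08, 0.2)),
                hb=float(rng.uniform(8.0, 14.0)),
                store_fraction=0.0,
            )
            recs = simulate_sequence(truth, pattern, 12, seed=int(rng.integers(2**31)))
            feats = features_of(recs, pattern, truth)
            est = solve_window(feats[-WINDOW:], feats[-WINDOW - 1].faco2, hb=truth.hb)
            assert est.eelv_raw == pytest.approx(truth.eelv_alv, rel=1e-4)
            assert est.epbf == pytest.approx(truth.epbf, rel=1e-4)
            assert est.cvco2 == pytest.approx(truth.cvco2, rel=1e-4)

    def test_volume_equivariance(self, pattern, features_of):
        # doubling every volume in the truth doubles the recovered volume
        # and leaves blood flow and venous content untouched
        k = 2.0
        base = dict(epbf=4.0, cvco2=0.55, hb=10.0, store_fraction=0.0)
        t1 = LungTruth(eelv_alv=1.2, vdaw=0.12, **base)
        t2 = LungTruth(eelv_alv=1.2 * k, vdaw=0.12 * k, **base)
        p2 = BreathPattern(vt=pattern.vt * k)
        f1 = features_of(simulate_sequence(t1, pattern, 12, seed=5), pattern, t1)
        f2 = features_of(simulate_sequence(t2, p2, 12, seed=5), p2, t2)
        e1 = solve_window(f1[-WINDOW:], f1[-WINDOW - 1].faco2, hb=10.0)
        e2 = solve_window(f2[-WINDOW:], f2[-WINDOW - 1].faco2, hb=10.0)
        assert e2.eelv_raw == pytest.approx(k * e1.eelv_raw, rel=1e-4)
        assert e2.epbf == pytest.approx(e1.epbf, rel=1e-4)
        assert e2.cvco2 == pytest.approx(e1.cvco2, rel=1e-4)

    def test_noiseless_fit_error_below_gate(self, truth, pattern, features_of,
                                            noiseless_records):
        feats = features_of(noiseless_records, pattern, truth)
        est = solve_window(feats[-WINDOW:], feats[-WINDOW - 1].faco2, hb=truth.hb)
        assert est.fit_error < 0.01  # mmHg

    def test_noise_raises_fit_error_monotonically(self, truth, pattern, features_of):
        def mean_fit_error(sd):
            errs = []
            for seed in range(12):
                recs = simulate_sequence(truth, pattern, 19,
                                         noise_sd_faco2=sd, seed=seed)
                feats = features_of(recs, pattern, truth)
                est = solve_window(feats[-WINDOW:], feats[-WINDOW - 1].faco2,
                                   hb=truth.hb)
                errs.append(est.fit_error)
            return np.mean(errs)

        assert mean_fit_error(0.0) < mean_fit_error(0.0005) < mean_fit_error(0.002)

    def test_estimator_attains_the_information_bound(self, truth, pattern,
                                                     features_of):
        # Monte-Carlo efficiency check: at faco2 noise SD 0.0005 the
        # Cramer-Rao bound for the fitted volume under the default pattern
        # is ~41% SD (median |error| ~28%); the estimator should sit near
        # the floor, not far above it.
        errs = []
        vref = truth.buffering_volume - truth.vdaw
        for seed in range(40):
            recs = simulate_sequence(truth, pattern, 19,
                                     noise_sd_faco2=0.0005, seed=seed)
            feats = features_of(recs, pattern, truth)
            est = solve_window(feats[-WINDOW:], feats[-WINDOW - 1].faco2,
                               hb=truth.hb)
            errs.append(abs(est.eelv_raw - vref) / vref)
        assert np.median(errs) < 0.40


class TestCorrections:
    @pytest.mark.parametrize(
        "raw_ml,corr_ml", [(1620.0, 1296.0), (1640.0, 1312.0)]
    )
    def test_store_correction_worked_examples(self, raw_ml, corr_ml):
        raw, corr = apply_corrections(raw_ml / 1000.0, 0.0)
        assert corr * 1000.0 == pytest.approx(corr_ml)

    def test_dead_space_subtraction(self):
        raw, corr = apply_corrections(1.0, 0.0)
        assert (raw, corr) == (1.0, 0.8)
        raw, corr = apply_corrections(2.0, 0.15)
        assert raw == pytest.approx(1.85)
        assert corr / raw == pytest.approx(0.8)

    def test_fit_below_dead_space_rejected(self):
        with pytest.raises(CorrectionError):
            apply_corrections(0.1, 0.15)


class TestStream:
    def test_output_length_contract(self, truth, pattern, features_of):
        recs = simulate_sequence(truth, pattern, 30, seed=0)
        ests = stream_estimates(features_of(recs, pattern, truth), hb=truth.hb)
        assert len(ests) == 21
        assert [e.window_end_index for e in ests] == list(range(9, 30))

    def test_stationary_truth_gives_constant_estimates(self, truth, pattern,
                                                       features_of):
        recs = simulate_sequence(truth, pattern, 30, seed=0)
        ests = stream_estimates(features_of(recs, pattern, truth), hb=truth.hb)
        raws = np.array([e.eelv_raw for e in ests])
        assert raws.max() - raws.min() < 1e-4

    def test_step_change_transitions_monotonically(self, pattern, features_of):
        lo = LungTruth(eelv_alv=1.2, store_fraction=0.0)
        hi = LungTruth(eelv_alv=1.8, store_fraction=0.0)
        schedule = [lo] * 18 + [hi] * 18
        recs = simulate_sequence(lo, pattern, 36, seed=0, truth_schedule=schedule)
        ests = stream_estimates(features_of(recs, pattern, lo), hb=lo.hb)
        raws = np.array([e.eelv_raw for e in ests])
        assert raws[3] == pytest.approx(1.2, rel=0.01)  # fully pre-step window
        assert raws[-1] == pytest.approx(1.8, rel=0.01)  # fully post-step window
        straddle = raws[8:19]  # windows containing the step breath
        assert np.all(np.diff(straddle) > -0.02)

    def test_too_short_stream_rejected(self, truth, pattern, features_of,
                                       noiseless_records):
        feats = features_of(noiseless_records, pattern, truth)[:9]
        with pytest.raises(SingularSystemError):
            stream_estimates(feats, hb=truth.hb)


class TestStablePeriod:
    def test_all_valid_means_mean_of_all(self, truth, pattern, features_of):
        recs = simulate_sequence(truth, pattern, 30, seed=0)
        ests = stream_estimates(features_of(recs, pattern, truth), hb=truth.hb)
        sp = select_stable_period(ests, min_duration_breaths=5)
        assert sp.n == len(ests)
        assert sp.eelv_corr == pytest.approx(
            np.mean([e.eelv_corr for e in ests])
        )

    def test_alternating_validity_has_no_stable_run(self, truth, pattern,
                                                    features_of):
        recs = simulate_sequence(truth, pattern, 30, seed=0)
        ests = stream_estimates(features_of(recs, pattern, truth), hb=truth.hb)
        for i, e in enumerate(ests):
            e.valid = bool(i % 2)
        with pytest.raises(NoStablePeriodError):
            select_stable_period(ests, min_duration_breaths=5)

    def test_quiet_segment_recovers_truth(self, truth, pattern, features_of):
        # noisy first half, quiet second half: the gate should find the quiet
        # run and its mean should sit near the true volume
        sd = np.concatenate([np.full(20, 0.002), np.zeros(25)])
        recs = simulate_sequence(truth, pattern, 45, noise_sd_faco2=sd, seed=3)
        ests = stream_estimates(features_of(recs, pattern, truth), hb=truth.hb)
        sp = select_stable_period(ests, min_duration_breaths=5)
        assert sp.start_index >= 20
        assert sp.eelv_corr == pytest.approx(truth.eelv_alv, rel=0.05)
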