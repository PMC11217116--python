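"""PIPR feature extraction: baseline, redilation fit, 6-s PIPR."""

import math

import numpy as np
import pytest

from pupilpress import (
    AreaTimeSeries,
    NoiseConfig,
    ProtocolConfig,
    PupilResponseParams,
    RedilationFitError,
    area_fraction_at,
    compute_baseline,
    compute_pipr6,
    extract_features,
    fit_redilation,
    redilation_tau,
    simulate_area_series,
)


def make_series(area_fn, protocol=None):
    """Series from an arbitrary area(t) function on the protocol grid."""
    protocol = protocol or ProtocolConfig()
    t = np.arange(protocol.n_samples) / protocol.fps
    return AreaTimeSeries(
        time_s=t,
        area_mm2=np.array([area_fn(tk) for tk in t]),
        phase=np.array([protocol.phase_of(tk) for tk in t], dtype=object),
        fps=protocol.fps,
        flash_on_s=protocol.flash_on_s,
        flash_off_s=protocol.flash_off_s,
    )


class TestBaseline:
    def test_constant_dark_area(self):
        s = make_series(lambda t: 30.0)
        assert compute_baseline(s) == 30.0

    def test_noiseless_series_recovers_params_baseline(self, params, noiseless_series):
        assert compute_baseline(noiseless_series) == params.baseline_area_mm2

    def test_short_dark_phase_rejected(self, params):
        proto = ProtocolConfig(dark_s=2.0)
        s = simulate_area_series(params, 16.0, proto)
        with pytest.raises(ValueError, match="dark phase"):
            compute_baseline(s)


class TestFitRedilation:
    def test_noiseless_exact_recovery(self, params, protocol):
        s = simulate_area_series(params, 16.0, protocol)
        tau, rmse = fit_redilation(s)
        assert tau == pytest.approx(redilation_tau(params, 16.0), rel=1e-6)
        assert rmse < 1e-9

    @pytest.mark.parametrize("tau_true", [0.5, 2.0, 8.0])
    def test_noiseless_recovery_across_taus(self, tau_true):
        p = PupilResponseParams(tau_ref=tau_true)
        s = simulate_area_series(p, p.iop_ref)
        tau, _ = fit_redilation(s)
        assert tau == pytest.approx(tau_true, rel=1e-6)

    def test_noisy_recovery_mean_error_under_5pct(self):
        tau_true = 2.0
        p = PupilResponseParams(tau_ref=tau_true)
        errs = [
            abs(fit_redilation(simulate_area_series(p, 16.0, noise=NoiseConfig(0.02, s)))[0] - tau_true)
            / tau_true
            for s in range(100)
        ]
        assert np.mean(errs) <= 0.05

    def test_parameter_recovery_grid(self):
        # median relative tau error <= 5 % over tau x noise, 100 seeds/cell
        for tau_true in (0.5, 1.0, 2.0, 4.0, 8.0):
            p = PupilResponseParams(tau_ref=tau_true)
            for noise_frac in (0.0, 0.01, 0.02):
                errs = []
                for seed in range(100):
                    s = simulate_area_series(
                        p, p.iop_ref, noise=NoiseConfig(noise_frac, seed)
                    )
                    tau, _ = fit_redilation(s)
                    errs.append(abs(tau - tau_true) / tau_true)
                assert np.median(errs) <= 0.05, (tau_true, noise_frac)

    def test_flat_recovery_at_baseline_rejected(self):
        s = make_series(lambda t: 30.0)
        with pytest.raises(RedilationFitError):
            fit_redilation(s)

    def test_short_recovery_rejected(self, params):
        proto = ProtocolConfig(recovery_s=4.0)
        s = simulate_area_series(params, 16.0, proto)
        with pytest.raises(ValueError, match="fit window"):
            fit_redilation(s)


class TestPipr6:
    def test_fast_recovery_returns_to_baseline(self):
        # tau_d = 0.5 s: 6 s after offset the deficit is ~ e^-12
        p = PupilResponseParams(tau_ref=0.5)
        s = simulate_area_series(p, p.iop_ref)
        assert compute_pipr6(s) == pytest.approx(100.0, abs=0.01)

    def test_slow_recovery_closed_form(self):
        # tau_d = 6 s with the pupil at half baseline at flash offset;
        # readout at the sample nearest t_off + 6 s on the 13 fps grid
        proto = ProtocolConfig()
        baseline, tau_d = 30.0, 6.0

        def area(t):
            if t < proto.flash_on_s:
                return baseline
            if t < proto.flash_off_s:
                frac = 0.5 + 0.5 * math.exp(
                    -(t - proto.flash_on_s) / 0.01
                )  # fast drop to 0.5
                return baseline * frac
            return baseline * (1 - 0.5 * math.exp(-(t - proto.flash_off_s) / tau_d))

        s = make_series(area, proto)
        t_near = s.time_s[np.argmin(np.abs(s.time_s - (proto.flash_off_s + 6.0)))]
        expected = 100.0 * (1 - 0.5 * math.exp(-(t_near - proto.flash_off_s) / tau_d))
        assert compute_pipr6(s) == pytest.approx(expected, rel=1e-12)
        assert compute_pipr6(s) == pytest.approx(81.6, abs=0.3)

    def test_short_recording_rejected(self, params):
        proto = ProtocolConfig(recovery_s=4.0)
        s = simulate_area_series(params, 16.0, proto)
        with pytest.raises(ValueError, match="too short"):
            compute_pipr6(s)


class TestExtractFeatures:
    def test_constriction_amplitude_from_generator(self, protocol):
        p = PupilResponseParams(min_frac=0.4, tau_c=0.3)
        s = simulate_area_series(p, 16.0, protocol)
        feats = extract_features(s)
        # amplitude equals the closed form at the deepest sample, ~60 %
        t_min = s.time_s[np.argmin(s.area_mm2)]
        expected = 100.0 * (1.0 - area_fraction_at(t_min, p, 16.0, protocol))
        assert feats.constriction_amp_pct == pytest.approx(expected, rel=1e-12)
        assert feats.constriction_amp_pct == pytest.approx(60.0, abs=1.0)

    def test_rate_is_reciprocal_of_tau(self, noiseless_series):
        feats = extract_features(noiseless_series)
        assert feats.redilation_rate_per_s * feats.tau_d_s == pytest.approx(
            1.0, abs=1e-15
        )

    def test_deterministic(self, noiseless_series):
        f1 = extract_features(noiseless_series)
        f2 = extract_features(noiseless_series)
        assert f1 == f2

    def test_unit_rescaling_scales_only_area_fields(self, params):
        s = simulate_area_series(params, 16.0)
        scaled = AreaTimeSeries(
            time_s=s.time_s,
            area_mm2=s.area_mm2 * 2.5,
            phase=s.phase,
            fps=s.fps,
            flash_on_s=s.flash_on_s,
            flash_off_s=s.flash_off_s,
        )
        f1, f2 = extract_features(s), extract_features(scaled)
        assert f2.baseline_area_mm2 == pytest.approx(2.5 * f1.baseline_area_mm2)
        assert f2.min_area_mm2 == pytest.approx(2.5 * f1.min_area_mm2)
        assert f2.tau_d_s == pytest.approx(f1.tau_d_s, rel=1e-9)
        assert f2.constriction_amp_pct == pytest.approx(
            f1.constriction_amp_pct, rel=1e-9
        )
        assert f2.pipr6_pct == pytest.approx(f1.pipr6_pct, rel=1e-9)

    def test_missing_phase_labels_rejected(self, params):
        s = simulate_area_series(params, 16.0)
        with pytest.raises(ValueError):
            AreaTimeSeries(
                time_s=s.time_s,
                area_mm2=s.area_mm2,
                phase=np.array(["unknown"] * len(s), dtype=object),
                fps=s.fps,
                flash_on_s=s.flash_on_s,
                flash_off_s=s.flash_off_s,
            )
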