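"""Synthetic session generator: waveforms, artifacts, behavior, determinism."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from stncc import (
    BehaviorParams, ComponentParams, NoiseModel, SessionConfig,
    component_template, inject_tms_artifact, powerlaw_noise,
    simulate_behavior, simulate_session,
)
from stncc.synth import gaussian_onset


FINE_AXIS = np.arange(-200.0, 500.0, 1.0)


class TestComponentTemplate:
    def test_posterior_van_peaks_at_stated_latency(self):
        p = ComponentParams(166.0, -3.0, 13.0, {})
        w = component_template("VAN_posterior", p, FINE_AXIS)
        assert w.min() == pytest.approx(-3.0)
        assert FINE_AXIS[np.argmin(w)] == 166.0

    def test_zero_amplitude_gives_flat_waveform(self, time_axis_250):
        p = ComponentParams(166.0, 0.0, 13.0, {})
        assert not component_template("VAN_posterior", p, time_axis_250).any()

    def test_lp_maximum_at_sample_nearest_peak(self, time_axis_250):
        # 350 ms falls between grid samples; the maximum sits at the nearest one
        p = ComponentParams(350.0, 4.0, 21.0, {})
        w = component_template("LP", p, time_axis_250)
        assert abs(time_axis_250[np.argmax(w)] - 350.0) <= 2.0
        assert w.max() == pytest.approx(4.0, rel=0.01)

    def test_zero_outside_three_widths(self, time_axis_250):
        p = ComponentParams(166.0, -3.0, 10.0, {})
        w = component_template("VAN_posterior", p, time_axis_250)
        far = np.abs(time_axis_250 - 166.0) > 30.0
        assert not w[far].any()

    def test_unknown_kind_names_valid_kinds(self, time_axis_250):
        with pytest.raises(ValueError, match="VAN_posterior"):
            component_template("N400", None, time_axis_250)


class TestTmsArtifact:
    def test_support_confined_to_two_ms(self):
        rate = 5000.0
        sig = np.zeros(1000)
        out = inject_tms_artifact(sig, rate, 100.0, amplitude_uv=2000.0)
        nz = np.flatnonzero(out)
        t = nz / rate * 1000.0
        assert t.min() >= 100.0 and t.max() <= 102.0
        assert np.abs(out).max() >= 1000.0      # >= 1 mV somewhere in the spike

    def test_zero_amplitude_is_identity(self, rng):
        sig = rng.standard_normal(500)
        out = inject_tms_artifact(sig, 1000.0, 50.0, amplitude_uv=0.0)
        np.testing.assert_array_equal(out, sig)

    def test_two_injections_add_linearly(self):
        sig = np.zeros(500)
        once = inject_tms_artifact(sig, 1000.0, 50.0, amplitude_uv=500.0)
        twice = inject_tms_artifact(once, 1000.0, 50.0, amplitude_uv=500.0)
        np.testing.assert_allclose(twice, 2 * once)

    def test_pulse_outside_span_raises(self):
        with pytest.raises(ValueError, match="outside"):
            inject_tms_artifact(np.zeros(100), 1000.0, 500.0)


class TestPowerlawNoise:
    def test_target_sd_and_zero_mean_spectrum(self, rng):
        x = powerlaw_noise(100000, 1.0, 10.0, rng)
        assert x.std() == pytest.approx(10.0, rel=1e-6)

    def test_zero_sd_gives_silence(self, rng):
        assert not powerlaw_noise(1000, 1.0, 0.0, rng).any()

    def test_spectrum_slope_is_one_over_f(self, rng):
        x = powerlaw_noise(2 ** 16, 1.0, 1.0, rng)
        f = np.fft.rfftfreq(len(x))
        p = np.abs(np.fft.rfft(x)) ** 2
        lo = p[(f > 0.001) & (f < 0.01)].mean()
        hi = p[(f > 0.1) & (f < 0.5)].mean()
        # 1/f power: ratio of band means tracks the frequency ratio
        assert lo / hi > 10


class TestBehavior:
    def test_rating_and_go_probabilities_recovered(self):
        cfg = SessionConfig(
            n_trials_per_condition={"vis_only": 500, "ipsi": 500,
                                    "contra": 500, "tms_only": 500},
            seed=11)
        t = simulate_behavior(cfg)
        bp = cfg.behavior_params
        for cond, probs in bp.p_rating.items():
            sub = t[t["condition"] == cond]
            for r, p in enumerate(probs):
                emp = (sub["rating"] == r).mean()
                se = np.sqrt(p * (1 - p) / len(sub))
                assert abs(emp - p) <= 3 * se + 1e-12, (cond, r)

    def test_contralateral_ratings_lower_than_ipsilateral(self):
        cfg = SessionConfig(seed=3)
        t = simulate_behavior(cfg)
        assert (t.loc[t["condition"] == "contra", "rating"].mean()
                < t.loc[t["condition"] == "ipsi", "rating"].mean())

    def test_rt_present_iff_go(self):
        t = simulate_behavior(SessionConfig(seed=5))
        assert (np.isfinite(t["rt_ms"]) == t["go"]).all()

    def test_sample_median_rt_within_order_statistic_interval(self):
        # all-rating-3, always-go config: RTs are iid lognormal(median 300)
        bp = BehaviorParams(
            p_rating={c: (0.0, 0.0, 0.0, 1.0) for c in
                      ("vis_only", "ipsi", "contra", "tms_only")},
            p_go_given_rating=(1.0, 1.0, 1.0, 1.0))
        cfg = SessionConfig(
            n_trials_per_condition={"vis_only": 192, "ipsi": 0,
                                    "contra": 0, "tms_only": 0},
            behavior_params=bp, seed=21)
        rts = simulate_behavior(cfg)["rt_ms"].to_numpy()
        n = len(rts)
        # 99% order-statistic interval for the population median
        k_lo, k_hi = scipy.stats.binom.interval(0.99, n, 0.5)
        dist = scipy.stats.lognorm(s=bp.rt_log_sd, scale=300.0)
        lo = dist.ppf(k_lo / n)
        hi = dist.ppf(k_hi / n)
        assert lo <= np.median(rts) <= hi


class TestSimulateSession:
    def test_same_seed_bit_identical(self, small_session):
        a = simulate_session(small_session)
        b = simulate_session(small_session)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_zero_noise_zero_components_no_tms_is_flat(self):
        cfg = SessionConfig(
            raw_rate=1000.0,
            n_trials_per_condition={"vis_only": 4, "ipsi": 0,
                                    "contra": 0, "tms_only": 0},
            noise_model=NoiseModel(sd_uv=0.0), seed=1)
        for comp in cfg.component_params.values():
            comp.peak_amplitude_uv = 0.0
            comp.amplitude_sd_uv = 0.0
        eeg, _, _ = simulate_session(cfg)
        assert not eeg.data.any()

    def test_ground_truth_consistency(self, small_session):
        _, table, truth = simulate_session(small_session)
        has_onset = np.isfinite(truth["true_van_onset_ms"])
        assert (truth.loc[has_onset, "van_amplitude_uv"] != 0).all()
        # unseen contralateral trials carry exactly zero conscious correlates
        contra0 = truth[(truth["condition"] == "contra") & (truth["rating"] == 0)]
        assert (contra0["van_amplitude_uv"] == 0).all()
        assert (contra0["lp_amplitude_uv"] == 0).all()
        # behavioral and event tables agree trial-for-trial
        assert (table["trial"] == truth["trial"]).all()

    def test_tms_artifact_present_and_confined(self):
        cfg = SessionConfig(
            raw_rate=1000.0,
            n_trials_per_condition={"vis_only": 0, "ipsi": 0,
                                    "contra": 0, "tms_only": 3},
            noise_model=NoiseModel(sd_uv=0.0), seed=2)
        for comp in cfg.component_params.values():
            comp.peak_amplitude_uv = 0.0
            comp.amplitude_sd_uv = 0.0
        eeg, table, _ = simulate_session(cfg)
        pz = eeg.get_channel("Pz")
        for onset in table["stim_onset_ms"]:
            i = int(round(onset))
            seg = pz[i + 90: i + 93]
            assert np.abs(seg).max() >= 1000.0
        assert np.abs(pz).max() == np.abs(pz[np.abs(pz) >= 1000.0]).max()

    def test_unknown_weight_channel_raises(self, small_session):
        small_session.component_params["LP"].scalp_weights["XX9"] = 1.0
        with pytest.raises(ValueError, match="XX9"):
            simulate_session(small_session)


class TestGaussianOnset:
    def test_onset_matches_closed_form(self):
        # -3 µV bump, width sigma: crossing of -1.5 µV at mu - sigma*sqrt(2 ln 2)
        on = gaussian_onset(-3.0, 166.0, 13.0)
        assert on == pytest.approx(166.0 - 13.0 * np.sqrt(2 * np.log(2.0)))

    def test_subthreshold_or_too_brief_is_absent(self):
        assert gaussian_onset(-1.0, 166.0, 13.0) is None
        assert gaussian_onset(-1.6, 166.0, 1.0) is None  # crosses but < 20 ms
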