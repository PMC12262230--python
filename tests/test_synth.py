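"""Generator: behavior statistics, rate templates, spike sampling, determinism."""
import numpy as np
import pytest
from scipy import stats

import scvigor
from scvigor import io as sio
from scvigor.errors import ConfigurationError, ScvigorError
from scvigor.synth import (GeneratorParams, RateTemplate, default_templates,
                           generate_session, main_sequence_pv, rate_function,
                           sample_behavior, sample_spike_train)


class TestReactionTimes:
    def test_condition_means_match_configured_distributions(self):
        """Sample mean RTs fall within 3 SE of the configured 186/211 ms."""
        params = GeneratorParams(seed=7, n_trials_good=50, n_trials_bad=50,
                                 rate_rt_coupling=0.0, latent_sd=0.0)
        b = generate_session(params)
        rts = np.array(b.truth["rt_ms"])
        conds = np.array([t.condition for t in b.trials])
        for cond, mean, sd in (("good", 186.0, 25.0), ("bad", 211.0, 36.0)):
            got = rts[conds == cond].mean()
            # truncation at the RT floor shifts the mean up slightly
            a = (params.rt_floor - mean) / sd
            expected = stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd)
            assert abs(got - expected) < 3 * sd / np.sqrt(50)

    def test_zero_effect_configuration_equalizes_conditions(self):
        """With equal RT params, no value gain and no coupling, good and bad
        RT distributions are statistically indistinguishable."""
        params = GeneratorParams(seed=11, rt_mean_bad=186.0, rt_sd_bad=25.0,
                                 value_gain=1.0, rate_rt_coupling=0.0,
                                 n_trials_good=80, n_trials_bad=80)
        b = generate_session(params)
        rts = np.array(b.truth["rt_ms"])
        conds = np.array([t.condition for t in b.trials])
        p = stats.mannwhitneyu(rts[conds == "good"], rts[conds == "bad"]).pvalue
        assert p > 0.01

    def test_all_rts_respect_floor(self, bundle):
        assert np.all(np.array(bundle.truth["rt_ms"]) >= 140.0)


class TestSessionStructure:
    def test_target_follows_fixation_by_300ms(self, bundle):
        for tr in bundle.trials:
            assert tr.target_on_ms >= tr.fix_on_ms + 300.0 - 1e-9

    def test_spike_times_sorted_and_nonnegative(self, bundle):
        for u in bundle.units:
            assert np.all(np.diff(u.spike_ms) >= 0)
            assert u.spike_ms.min() >= 0

    def test_truth_covers_every_unit(self, bundle, default_params):
        truth_ids = {u["unit_id"] for u in bundle.truth["units"]}
        assert truth_ids == {u.unit_id for u in bundle.units}
        n = default_params.n_units_per_subtype
        assert len(bundle.units) == 4 * n

    def test_tonic_value_signs_balanced(self, bundle):
        signs = [u["modulation_sign"] for u in bundle.truth["units"]
                 if u["subtype"] == "tonic"]
        assert abs(sum(1 for s in signs if s > 0)
                   - sum(1 for s in signs if s < 0)) <= 1

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorParams(n_trials_good=0)
        with pytest.raises(ConfigurationError):
            GeneratorParams(rt_sd_good=-1.0)
        with pytest.raises(ConfigurationError):
            GeneratorParams(amp_range=(10.0, 4.0))


class TestDeterminism:
    def test_same_seed_gives_byte_identical_session_files(self, tmp_path):
        for d in ("a", "b"):
            sio.write_session(generate_session(GeneratorParams(seed=7)),
                              tmp_path / d)
        for fname in ("manifest.json", "trials.csv", "spikes.csv",
                      "eye.csv", "truth.json"):
            assert ((tmp_path / "a" / fname).read_bytes()
                    == (tmp_path / "b" / fname).read_bytes()), fname


class TestRateFunction:
    def test_degenerate_template_is_constant_baseline(self):
        t, lam = rate_function(RateTemplate(baseline=20.0), "bad", 200.0,
                               GeneratorParams())
        assert np.allclose(lam, 20.0)

    def test_motor_component_peaks_at_rt_minus_lead(self):
        tpl = RateTemplate(baseline=0.0, motor_gain=50.0, motor_peak_lead=11.0)
        t, lam = rate_function(tpl, "bad", 200.0, GeneratorParams())
        assert t[np.argmax(lam)] == pytest.approx(189.0, abs=1.0)

    def test_visual_component_peaks_at_its_latency(self):
        tpl = RateTemplate(baseline=0.0, visual_gain=30.0,
                           visual_peak_latency=42.0)
        t, lam = rate_function(tpl, "bad", 200.0, GeneratorParams())
        assert t[np.argmax(lam)] == pytest.approx(42.0, abs=1.0)

    def test_rate_clipped_at_zero(self):
        tpl = RateTemplate(baseline=5.0, tonic_suppression=50.0)
        _, lam = rate_function(tpl, "bad", 200.0, GeneratorParams())
        assert lam.min() >= 0.0

    def test_tonic_trough_precedes_saccade_by_lead(self):
        tpl = RateTemplate(baseline=22.0, tonic_suppression=10.0,
                           tonic_trough_lead=33.0)
        t, lam = rate_function(tpl, "bad", 200.0, GeneratorParams())
        sel = (t > 0) & (t < 250)
        assert t[sel][np.argmin(lam[sel])] == pytest.approx(167.0, abs=2.0)


class TestSpikeSampling:
    def test_zero_rate_yields_no_spikes(self, rng):
        t = np.arange(0.0, 1000.0)
        assert sample_spike_train(t, np.zeros_like(t), rng).size == 0

    def test_constant_rate_matches_poisson_mean(self, rng):
        """1000 draws of a 20 Hz / 1 s train: mean count within 3 SE of 20."""
        t = np.arange(0.0, 1000.0)
        rate = np.full(t.size, 20.0)
        counts = [sample_spike_train(t, rate, rng).size for _ in range(1000)]
        se = np.sqrt(20.0 / 1000.0)
        assert abs(np.mean(counts) - 20.0) < 3 * se

    def test_piecewise_rate_matches_integral_per_piece(self, rng):
        """Empirical counts per piece agree with the rate integral (chi^2)."""
        t = np.arange(0.0, 900.0)
        rate = np.where(t < 300, 5.0, np.where(t < 600, 40.0, 15.0))
        edges = [(0, 300), (300, 600), (600, 900)]
        counts = np.zeros(3)
        n_rep = 400
        for _ in range(n_rep):
            st = sample_spike_train(t, rate, rng)
            for k, (lo, hi) in enumerate(edges):
                counts[k] += np.count_nonzero((st >= lo) & (st < hi))
        expected = np.array([5.0, 40.0, 15.0]) * 0.3 * n_rep
        chi2 = np.sum((counts - expected) ** 2 / expected)
        assert chi2 < stats.chi2.ppf(0.99, df=3)

    def test_spike_times_strictly_increasing(self, rng):
        t = np.arange(0.0, 2000.0)
        st = sample_spike_train(t, np.full(t.size, 80.0), rng)
        assert np.all(np.diff(st) > 0)

    def test_unbounded_rate_rejected(self, rng):
        t = np.arange(0.0, 100.0)
        bad = np.full(t.size, np.inf)
        with pytest.raises(ScvigorError):
            sample_spike_train(t, bad, rng)


class TestBehavior:
    def test_main_sequence_vanishes_at_zero_amplitude(self):
        assert main_sequence_pv(0.0, GeneratorParams()) == 0.0

    def test_main_sequence_monotone_in_amplitude(self):
        p = GeneratorParams()
        amps = np.linspace(1.0, 25.0, 50)
        pv = main_sequence_pv(amps, p)
        assert np.all(np.diff(pv) > 0)

    def test_good_condition_gets_velocity_bonus(self, rng):
        p = GeneratorParams(pv_noise_frac=0.0, amp_jitter_frac=0.0,
                            pv_latent_coupling=0.0)
        _, _, pv_g, _ = sample_behavior(p, "good", rng, target_amp=12.0)
        _, _, pv_b, _ = sample_behavior(p, "bad", rng, target_amp=12.0)
        assert pv_g == pytest.approx(pv_b * 1.05, rel=1e-9)

    def test_segment_velocity_peak_equals_drawn_pv(self, rng):
        """The minimum-jerk segment's numerical peak speed matches the drawn
        PV within 1%, and the 30 deg/s threshold is crossed once up, once
        down."""
        p = GeneratorParams(pv_noise_frac=0.0, amp_jitter_frac=0.0)
        rt, amp, pv, seg = sample_behavior(p, "bad", rng, target_amp=15.0)
        v = np.gradient(seg) * 1000.0
        assert v.max() == pytest.approx(pv, rel=0.01)
        above = v >= 30.0
        assert np.count_nonzero(np.diff(above.astype(int)) == 1) == 1
        assert np.count_nonzero(np.diff(above.astype(int)) == -1) == 1

    def test_unknown_condition_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            sample_behavior(GeneratorParams(), "neutral", rng)
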