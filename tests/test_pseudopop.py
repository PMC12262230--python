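"""RT-tertile splitting, pseudo-trial pooling, epoch extrema, bootstrap."""
import numpy as np
import pytest

from scvigor.errors import ConfigurationError, ScvigorError, TooFewTrialsError
from scvigor.pseudopop import (BootstrapConfig, UnitTraces,
                               bootstrap_population, epoch_extremum,
                               simulate_pseudo_trial, split_quantiles)


def toy_units(n_units=4, n_trials=30, n_t=200, value=None, seed=0):
    """Units whose single-trial 'SDFs' are deterministic copies of a bump."""
    rng = np.random.default_rng(seed)
    t = np.arange(-50.0, n_t - 50.0)
    units = []
    for u in range(n_units):
        base = np.exp(-0.5 * ((t - 60.0) / 10.0) ** 2) * 40.0 + 5.0
        mat = np.tile(base, (n_trials, 1))
        if value is not None:
            mat = mat * value[:, None]
        rts = rng.uniform(150, 250, n_trials)
        conds = np.array(["good", "bad"] * (n_trials // 2))
        units.append(UnitTraces(f"u{u}", "visual", t, mat, t, mat, rts, conds))
    return units


class TestSplitQuantiles:
    def test_one_to_nine_splits_in_thirds(self):
        s = split_quantiles(np.arange(1.0, 10.0))
        assert list(s.labels) == ["short"] * 3 + ["medium"] * 3 + ["long"] * 3

    def test_three_trials_one_each(self):
        s = split_quantiles(np.array([200.0, 150.0, 250.0]))
        assert sorted(s.labels) == ["long", "medium", "short"]
        assert s.labels[1] == "short"

    def test_hundred_random_rts_sizes_and_ordering(self, rng):
        rts = rng.normal(200, 30, 100)
        s = split_quantiles(rts)
        sizes = {q: np.count_nonzero(s.labels == q)
                 for q in ("short", "medium", "long")}
        assert sizes == {"short": 34, "medium": 33, "long": 33}
        assert rts[s.mask("short")].max() < rts[s.mask("long")].min()

    def test_ties_broken_by_original_order(self):
        s = split_quantiles(np.array([100.0, 100.0, 100.0, 100.0, 100.0, 100.0]))
        assert list(s.labels) == ["short", "short", "medium", "medium",
                                  "long", "long"]

    def test_fewer_than_three_trials_rejected(self):
        with pytest.raises(TooFewTrialsError):
            split_quantiles(np.array([100.0, 200.0]))


class TestSimulatePseudoTrial:
    def test_identical_units_reproduce_their_sdf(self, rng):
        units = toy_units()
        splits = [split_quantiles(u.rt_ms) for u in units]
        trace = simulate_pseudo_trial(units, "short", splits, n_pool=25, rng=rng)
        np.testing.assert_allclose(trace, units[0].sdf_target[0])

    def test_pool_of_one_returns_single_trial(self, rng):
        units = toy_units(n_units=1)
        splits = [split_quantiles(u.rt_ms) for u in units]
        trace = simulate_pseudo_trial(units, "long", splits, n_pool=1, rng=rng)
        np.testing.assert_allclose(trace, units[0].sdf_target[0])

    def test_pooled_variance_shrinks_like_one_over_npool(self):
        """Across draws, pooled-trace variance scales ~ 1/n_pool."""
        rng0 = np.random.default_rng(3)
        n_trials = 60
        scale = rng0.lognormal(0.0, 0.5, n_trials)
        units = toy_units(n_units=1, n_trials=n_trials, value=scale)
        splits = [split_quantiles(units[0].rt_ms)]
        def var_at(n_pool, reps=400):
            rng1 = np.random.default_rng(17)
            vals = [simulate_pseudo_trial(units, "medium", splits, n_pool,
                                          rng1)[110]
                    for _ in range(reps)]
            return np.var(vals)
        v1, v25 = var_at(1), var_at(25)
        assert v25 == pytest.approx(v1 / 25.0, rel=0.5)


class TestEpochExtremum:
    def test_monotone_trace_peaks_at_epoch_end(self):
        t = np.arange(0.0, 200.0)
        tm, _ = epoch_extremum(t, t * 0.1, (30.0, 80.0), "peak")
        assert tm == 80.0

    def test_bump_center_found(self):
        t = np.arange(0.0, 200.0)
        y = np.exp(-0.5 * ((t - 50.0) / 5.0) ** 2)
        tm, val = epoch_extremum(t, y, (30.0, 80.0), "peak")
        assert tm == 50.0 and val == 1.0

    def test_matches_bruteforce_scan(self, rng):
        t = np.arange(-100.0, 300.0)
        for _ in range(25):
            y = rng.normal(size=t.size)
            for kind in ("peak", "trough"):
                tm, val = epoch_extremum(t, y, (-40.0, 120.0), kind)
                m = (t >= -40.0) & (t <= 120.0)
                ref = np.argmax(y[m]) if kind == "peak" else np.argmin(y[m])
                assert tm == t[m][ref] and val == y[m][ref]

    def test_first_occurrence_wins_on_ties(self):
        t = np.arange(0.0, 100.0)
        y = np.zeros_like(t)
        y[[20, 40]] = 7.0
        tm, _ = epoch_extremum(t, y, (0.0, 99.0), "peak")
        assert tm == 20.0

    def test_epoch_outside_span_rejected(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ConfigurationError):
            epoch_extremum(t, t, (500.0, 600.0), "peak")


class TestBootstrapPopulation:
    def test_fixed_seed_reproduces_summary(self):
        units = toy_units(seed=5)
        cfg = BootstrapConfig(n_pool=5, n_pseudo_trials=5, n_repeats=20, seed=9)
        df1 = bootstrap_population(units, cfg)
        df2 = bootstrap_population(units, cfg)
        assert df1.equals(df2)

    def test_ci_bounds_bracket_mean(self):
        rng0 = np.random.default_rng(8)
        units = toy_units(n_trials=60,
                          value=rng0.lognormal(0.0, 0.3, 60), seed=8)
        cfg = BootstrapConfig(n_pool=5, n_pseudo_trials=5, n_repeats=50, seed=2)
        df = bootstrap_population(units, cfg)
        assert (df["time_lo"] <= df["time_mean"] + 1e-9).all()
        assert (df["time_mean"] <= df["time_hi"] + 1e-9).all()
        assert (df["rate_lo"] <= df["rate_hi"]).all()

    def test_extremum_times_stay_inside_epochs(self):
        units = toy_units(seed=6)
        cfg = BootstrapConfig(n_pool=3, n_pseudo_trials=3, n_repeats=10, seed=3)
        df = bootstrap_population(units, cfg)
        evis = df[(df.epoch == "E_VIS") & (df.alignment == "target")]
        assert (evis["time_mean"] >= 30.0).all()
        assert (evis["time_mean"] <= 80.0).all()

    def test_condition_split_produces_both_blocks(self):
        units = toy_units(n_trials=40, seed=7)
        cfg = BootstrapConfig(n_pool=3, n_pseudo_trials=3, n_repeats=10, seed=4)
        df = bootstrap_population(units, cfg, conditions=("good", "bad"))
        assert set(df["condition"]) == {"good", "bad"}

    def test_no_units_rejected(self):
        with pytest.raises(ScvigorError):
            bootstrap_population([], BootstrapConfig(n_repeats=1))

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            BootstrapConfig(n_pool=0)
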